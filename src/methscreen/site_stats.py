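"""Per-site variability (SD) and familiality (sibling Spearman correlation).

The screen treats every CpG site as a quantitative trait and summarises it
by two numbers per treatment phase: the sample standard deviation over all
phase individuals (variability) and the Spearman rank correlation between
the earlier-born and later-born members of full-sibling pairs
(familiality, "scor").  Twice the sibling correlation bounds the narrow
sense heritability from above, so large scor flags potentially heritable
methylation.  SDs are deliberately not adjusted for family structure: every
site is estimated on the same sample and only the ranks of the estimates
are consumed downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import MethylationMatrix
from .pedigree import Pedigree, SiblingPair, extract_sibling_pairs, restrict_pairs

__all__ = [
    "site_sd",
    "sibling_spearman",
    "heritability_upper_bound",
    "build_site_stat_table",
    "write_site_stats",
    "read_site_stats",
    "SITE_STAT_COLUMNS",
]

SITE_STAT_COLUMNS = [
    "sd_pre",
    "sd_post",
    "scor_pre",
    "scor_post",
    "n_pre",
    "n_post",
    "npairs_pre",
    "npairs_post",
    "rank_sd_pre",
    "rank_sd_post",
    "rank_scor_pre",
    "rank_scor_post",
]


def site_sd(m: MethylationMatrix) -> pd.Series:
    """Sample SD (n-1 denominator) per site over non-missing values.

    Sites with fewer than two non-missing values get NaN.
    """
    counts = m.values.notna().sum(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    sd[counts < 2] = np.nan
    sd.name = "sd"
    return sd


def _pair_value_matrices(
    m: MethylationMatrix, pairs: list[SiblingPair]
) -> tuple[np.ndarray, np.ndarray]:
    sample_pos = {s: i for i, s in enumerate(m.values.index)}
    fi = np.array([sample_pos[p.first] for p in pairs], dtype=int)
    si = np.array([sample_pos[p.second] for p in pairs], dtype=int)
    v = m.values.to_numpy(dtype=float)
    return v[fi, :], v[si, :]


def sibling_spearman(
    m: MethylationMatrix, pairs: list[SiblingPair], min_pairs: int = 10
) -> pd.Series:
    """Per-site Spearman correlation between ordered sibling pairs.

    For each site, x holds the earlier-born member's beta value and y the
    later-born member's, over pairs with both values present.  Ties receive
    average ranks.  Sites with fewer than ``min_pairs`` complete pairs get
    NaN.  Pairs whose members are absent from the matrix are dropped first
    (the phase restriction).
    """
    if min_pairs < 3:
        raise ValueError("min_pairs must be >= 3")
    present = set(m.values.index)
    pairs = restrict_pairs(pairs, present)
    n_sites = m.values.shape[1]
    out = pd.Series(np.full(n_sites, np.nan), index=m.values.columns, name="scor")
    if not pairs:
        return out
    x, y = _pair_value_matrices(m, pairs)
    complete = ~(np.isnan(x) | np.isnan(y))
    counts = complete.sum(axis=0)

    full = counts == len(pairs)
    if np.any(full):
        # vectorised path: rank each column, Pearson on ranks
        xr = stats.rankdata(x[:, full], axis=0)
        yr = stats.rankdata(y[:, full], axis=0)
        xr = xr - xr.mean(axis=0)
        yr = yr - yr.mean(axis=0)
        denom = np.sqrt((xr**2).sum(axis=0) * (yr**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (xr * yr).sum(axis=0) / denom
        vals = np.full(full.sum(), np.nan)
        ok = denom > 0
        vals[ok] = rho[ok]
        out.iloc[np.flatnonzero(full)] = vals

    for j in np.flatnonzero(~full):
        if counts[j] < min_pairs:
            continue
        mask = complete[:, j]
        res = stats.spearmanr(x[mask, j], y[mask, j])
        out.iloc[j] = res.statistic

    out[counts < min_pairs] = np.nan
    return out


def heritability_upper_bound(scor: float) -> float:
    """Upper bound on heritability implied by a sibling correlation.

    Twice the sibling correlation bounds h2 from above; the result is
    clipped into [0, 1] since negative or super-unit heritability is
    meaningless.
    """
    if not -1.0 <= scor <= 1.0:
        raise ValueError(f"sibling correlation must be in [-1, 1], got {scor}")
    return float(min(max(2.0 * scor, 0.0), 1.0))


def build_site_stat_table(
    pre: MethylationMatrix,
    post: MethylationMatrix,
    ped: Pedigree,
    min_pairs: int = 10,
    one_pair_per_sibship: bool = False,
) -> pd.DataFrame:
    """Assemble the full per-site statistic table for both phases.

    Returns a DataFrame indexed by site id with SDs, scors, sample/pair
    counts and descending ranks (1 = largest) for all four distributions.
    """
    from .outliers import rank_descending  # ranks defined with the outlier rule

    if list(pre.site_ids) != list(post.site_ids):
        raise ValueError("pre and post matrices must share identical site_ids")

    all_pairs = extract_sibling_pairs(ped, one_pair_per_sibship=one_pair_per_sibship)
    pairs_pre = restrict_pairs(all_pairs, set(pre.sample_ids))
    pairs_post = restrict_pairs(all_pairs, set(post.sample_ids))

    table = pd.DataFrame(index=pd.Index(pre.site_ids, name="site_id"))
    table["sd_pre"] = site_sd(pre)
    table["sd_post"] = site_sd(post)
    table["scor_pre"] = sibling_spearman(pre, pairs_pre, min_pairs=min_pairs)
    table["scor_post"] = sibling_spearman(post, pairs_post, min_pairs=min_pairs)
    table["n_pre"] = pre.values.notna().sum(axis=0)
    table["n_post"] = post.values.notna().sum(axis=0)
    table["npairs_pre"] = len(pairs_pre)
    table["npairs_post"] = len(pairs_post)
    for col in ("sd_pre", "sd_post", "scor_pre", "scor_post"):
        table[f"rank_{col}"] = rank_descending(table[col])
    return table


def write_site_stats(stats_table: pd.DataFrame, path: str) -> None:
    stats_table[SITE_STAT_COLUMNS].to_csv(path, sep="\t", index_label="site_id", float_format="%.6g")


def read_site_stats(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    return table
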