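"""Rank-threshold outlier selection and the candidate-site concordance rule.

A treatment-responsive CpG under genetic control should become both highly
variable (SD) and highly familial (sibling correlation) after treatment,
while looking unremarkable before.  The screen therefore:

1. ranks each of the four distributions (SD and scor, pre and post)
   descending, rank 1 = largest;
2. calls the top ``round(fraction * N)`` sites of each distribution its
   outliers (0.1% by default — 450 sites out of 450,000);
3. intersects the two post-treatment outlier sets (concordant outliers);
4. drops any concordant site that was already a pre-treatment SD or scor
   outlier, leaving the candidate responsive sites.

If the primary threshold yields no candidates the pipeline retries with
progressively more permissive fallback fractions (0.5%, then 1%).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OutlierReport",
    "rank_descending",
    "threshold_count_from_fraction",
    "select_outliers",
    "concordant_outliers",
    "candidate_responsive_sites",
    "outlier_turnover",
    "run_outlier_pipeline",
    "write_outlier_report",
]


def rank_descending(values: pd.Series) -> pd.Series:
    """Descending integer ranks, 1 = largest; a permutation of 1..N.

    Ties are broken by site id (lexicographic) so ranking is deterministic;
    missing values rank after all non-missing ones, also in id order.
    """
    ids = values.index.astype(str).to_numpy()
    v = values.to_numpy(dtype=float)
    key = np.where(np.isnan(v), -np.inf, v)
    # lexsort uses the last key as primary: sort by -value, then id
    order = np.lexsort((ids, -key))
    ranks = np.empty(len(v), dtype=int)
    ranks[order] = np.arange(1, len(v) + 1)
    return pd.Series(ranks, index=values.index, name=f"rank_{values.name}" if values.name else "rank")


def threshold_count_from_fraction(fraction: float, n_sites: int) -> int:
    """Outlier count implied by a tail fraction: round(fraction * N)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"threshold fraction must be in (0, 1], got {fraction}")
    count = int(round(fraction * n_sites))
    return max(count, 1)


def select_outliers(ranks: pd.Series, threshold_count: int) -> set[str]:
    """Site ids with rank <= threshold_count (the upper tail)."""
    n = len(ranks)
    if not 1 <= threshold_count <= n:
        raise ValueError(f"threshold_count must be in [1, {n}], got {threshold_count}")
    return set(ranks.index[ranks <= threshold_count].astype(str))


def concordant_outliers(set_a: set[str], set_b: set[str]) -> set[str]:
    """Sites that are outliers in both distributions."""
    return set(set_a) & set(set_b)


def candidate_responsive_sites(
    post_concordant: set[str], sd_pre: set[str], scor_pre: set[str]
) -> set[str]:
    """Concordant post-treatment outliers that were not pre-treatment outliers."""
    return set(post_concordant) - (set(sd_pre) | set(scor_pre))


def outlier_turnover(pre_set: set[str], post_set: set[str]) -> tuple[int, float]:
    """How many post-treatment outliers are new, and what fraction.

    Denominator is the post-treatment set size (e.g. 449/450 scor outliers
    differing between phases).
    """
    if not post_set:
        raise ValueError("turnover undefined for an empty post-treatment outlier set")
    count = len(set(post_set) - set(pre_set))
    return count, count / len(post_set)


@dataclass
class OutlierReport:
    """Outcome of the outlier-concordance screen at one (possibly fallen-back) threshold."""

    threshold_fraction: float
    threshold_count: int
    sd_pre: set[str]
    sd_post: set[str]
    scor_pre: set[str]
    scor_post: set[str]
    post_concordant: set[str]
    candidates: set[str]
    turnover_sd: tuple[int, float]
    turnover_scor: tuple[int, float]
    table_rows: pd.DataFrame = field(repr=False)
    thresholds_tried: list[float] = field(default_factory=list)
    fallback_used: bool = False
    exhausted: bool = False

    def summary(self) -> dict:
        return {
            "threshold_fraction": self.threshold_fraction,
            "threshold_count": self.threshold_count,
            "thresholds_tried": self.thresholds_tried,
            "fallback_used": self.fallback_used,
            "exhausted": self.exhausted,
            "n_sd_pre": len(self.sd_pre),
            "n_sd_post": len(self.sd_post),
            "n_scor_pre": len(self.scor_pre),
            "n_scor_post": len(self.scor_post),
            "n_post_concordant": len(self.post_concordant),
            "n_candidates": len(self.candidates),
            "turnover_sd": {"count": self.turnover_sd[0], "fraction": self.turnover_sd[1]},
            "turnover_scor": {"count": self.turnover_scor[0], "fraction": self.turnover_scor[1]},
        }


def _apply_threshold(stats: pd.DataFrame, fraction: float) -> dict:
    count = threshold_count_from_fraction(fraction, len(stats))
    sets = {
        name: select_outliers(stats[f"rank_{name}"], count)
        for name in ("sd_pre", "sd_post", "scor_pre", "scor_post")
    }
    post_concordant = concordant_outliers(sets["sd_post"], sets["scor_post"])
    candidates = candidate_responsive_sites(post_concordant, sets["sd_pre"], sets["scor_pre"])
    return {
        "count": count,
        "sets": sets,
        "post_concordant": post_concordant,
        "candidates": candidates,
    }


def _table_rows(
    stats: pd.DataFrame,
    post_concordant: set[str],
    candidates: set[str],
    site_annotation: pd.DataFrame | None,
    gene_map: dict[str, str] | None,
) -> pd.DataFrame:
    rows = []
    for site in sorted(post_concordant):
        s = stats.loc[site]
        rows.append(
            {
                "site_id": site,
                "chrom": site_annotation.at[site, "chrom"] if site_annotation is not None and site in site_annotation.index else "",
                "gene": (gene_map or {}).get(site, ""),
                "post_sd_rank": int(s["rank_sd_post"]),
                "post_sd_est": s["sd_post"],
                "pre_sd_rank": int(s["rank_sd_pre"]),
                "pre_sd_est": s["sd_pre"],
                "post_scor_rank": int(s["rank_scor_post"]),
                "post_scor_est": s["scor_post"],
                "pre_scor_rank": int(s["rank_scor_pre"]),
                "pre_scor_est": s["scor_pre"],
                "bold": site in candidates,
            }
        )
    cols = [
        "site_id", "chrom", "gene",
        "post_sd_rank", "post_sd_est", "pre_sd_rank", "pre_sd_est",
        "post_scor_rank", "post_scor_est", "pre_scor_rank", "pre_scor_est",
        "bold",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_outlier_pipeline(
    stats: pd.DataFrame,
    threshold_fraction: float = 0.001,
    fallback_fractions: tuple[float, ...] = (0.005, 0.01),
    site_annotation: pd.DataFrame | None = None,
    gene_map: dict[str, str] | None = None,
) -> OutlierReport:
    """Run the full outlier-concordance screen with threshold fallback.

    ``stats`` is a site-statistics table as produced by
    :func:`methscreen.site_stats.build_site_stat_table`.  The primary
    threshold is applied first; if it yields no candidate sites, each
    fallback fraction is tried in order and the report records which level
    finally produced candidates (or that all levels were exhausted).
    """
    tried: list[float] = []
    chosen = None
    result = None
    for frac in (threshold_fraction, *fallback_fractions):
        tried.append(frac)
        result = _apply_threshold(stats, frac)
        chosen = frac
        if result["candidates"]:
            break
    assert result is not None and chosen is not None
    exhausted = not result["candidates"]

    turnover_sd = outlier_turnover(result["sets"]["sd_pre"], result["sets"]["sd_post"])
    turnover_scor = outlier_turnover(result["sets"]["scor_pre"], result["sets"]["scor_post"])
    rows = _table_rows(stats, result["post_concordant"], result["candidates"], site_annotation, gene_map)
    return OutlierReport(
        threshold_fraction=chosen,
        threshold_count=result["count"],
        sd_pre=result["sets"]["sd_pre"],
        sd_post=result["sets"]["sd_post"],
        scor_pre=result["sets"]["scor_pre"],
        scor_post=result["sets"]["scor_post"],
        post_concordant=result["post_concordant"],
        candidates=result["candidates"],
        turnover_sd=turnover_sd,
        turnover_scor=turnover_scor,
        table_rows=rows,
        thresholds_tried=tried,
        fallback_used=len(tried) > 1,
        exhausted=exhausted,
    )


def write_outlier_report(report: OutlierReport, out_dir: str) -> None:
    """Write one TSV per outlier set, the concordance table and a JSON summary."""
    os.makedirs(out_dir, exist_ok=True)
    for name in ("sd_pre", "sd_post", "scor_pre", "scor_post"):
        sites = sorted(getattr(report, name))
        pd.Series(sites, name="site_id").to_csv(
            os.path.join(out_dir, f"outliers_{name}.tsv"), sep="\t", index=False
        )
    for name in ("post_concordant", "candidates"):
        sites = sorted(getattr(report, name))
        pd.Series(sites, name="site_id").to_csv(
            os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False
        )
    report.table_rows.to_csv(
        os.path.join(out_dir, "concordant_sites_table.tsv"),
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    with open(os.path.join(out_dir, "outlier_summary.json"), "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")
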