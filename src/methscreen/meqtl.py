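"""Cis-window meQTL scan over candidate CpG sites.

For each site the scan restricts to samples with observed methylation,
applies the MAF filter and the +/- 1 Mb cis window, fits the null mixed
model once (the eigendecomposition of the relatedness matrix is the
expensive step) and then Wald-tests every window SNP at the null
variance-ratio estimate.  The lead SNP per site is the smallest p-value,
ties broken by genomic position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, cis_window, maf_filter
from .lmm import LMMError, fit_null_lmm, test_snp
from .methylation import MethylationMatrix
from .pedigree import KinshipMatrix, Pedigree, compute_kinship

__all__ = ["MeQTLConfig", "meqtl_scan", "write_meqtl_results"]

logger = logging.getLogger(__name__)


@dataclass
class MeQTLConfig:
    """Scan parameters: cis half-window (bp), MAF cutoff, model options."""

    half_width_bp: int = 1_000_000
    min_maf: float = 0.01
    reml: bool = False
    refit_per_snp: bool = False
    bonferroni_within_window: bool = False


def _relatedness(ped_or_kin: Pedigree | KinshipMatrix | None, sample_ids: list[str]) -> np.ndarray:
    """Relatedness (2*phi) over sample_ids; identity when no pedigree given."""
    if ped_or_kin is None:
        return np.eye(len(sample_ids))
    kin = ped_or_kin if isinstance(ped_or_kin, KinshipMatrix) else compute_kinship(ped_or_kin)
    return kin.subset(sample_ids).relatedness()


def meqtl_scan(
    m: MethylationMatrix,
    sites: list[str],
    g: GenotypeMatrix,
    ped: Pedigree | KinshipMatrix | None,
    config: MeQTLConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan cis SNPs against methylation at each requested site.

    Returns ``(results, leads)``: all SNP tests, and the lead SNP per site
    (minimum p, ties broken by position).  Sites whose cis window is empty
    after filtering are skipped with a logged warning.

    ``ped`` may be a Pedigree, a precomputed KinshipMatrix, or None for
    unrelated samples (identity relatedness).  ``covariates`` (indexed by
    sample id) are added to the intercept-only design.
    """
    config = config or MeQTLConfig()
    shared = [s for s in m.sample_ids if s in set(g.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between methylation and genotype matrices")
    g_shared = g.restrict_samples(shared)
    filtered = maf_filter(g_shared, config.min_maf)

    records: list[dict] = []
    lead_records: list[dict] = []
    window_cache: dict[tuple, GenotypeMatrix] = {}

    for site in sites:
        if site not in m.sites.index or site not in m.values.columns:
            logger.warning("site %s absent from methylation matrix; skipped", site)
            continue
        chrom = str(m.sites.at[site, "chrom"])
        pos = int(m.sites.at[site, "pos"])
        key = (chrom, pos // 1, config.half_width_bp)
        if key not in window_cache:
            window_cache[key] = cis_window(chrom, pos, filtered, config.half_width_bp)
        window = window_cache[key]
        if window.n_snps == 0:
            logger.warning("site %s: empty cis window after filters; skipped", site)
            continue

        yfull = m.values[site].reindex(shared)
        complete = yfull.notna().to_numpy()
        case_ids = [s for s, ok in zip(shared, complete) if ok]
        y = yfull.to_numpy(dtype=float)[complete]
        if len(y) < 3 or np.std(y) == 0:
            logger.warning("site %s: degenerate trait after complete-case restriction; skipped", site)
            continue
        X = np.ones((len(y), 1))
        if covariates is not None:
            cov = covariates.reindex(case_ids).to_numpy(dtype=float)
            if np.isnan(cov).any():
                raise ValueError("covariates contain missing values for analysis samples")
            X = np.column_stack([X, cov])
        R = _relatedness(ped, case_ids)
        try:
            fit = fit_null_lmm(y, X, R, reml=config.reml)
        except LMMError as exc:
            logger.warning("site %s: null fit failed (%s); skipped", site, exc)
            continue

        dosage = window.restrict_samples(case_ids).dosages
        site_rows = []
        for j, snp_id in enumerate(window.snp_ids):
            try:
                if config.refit_per_snp:
                    res = test_snp(fit, dosage[:, j], refit_per_snp=True, y=y, X=X, R=R)
                else:
                    res = test_snp(fit, dosage[:, j])
            except LMMError as exc:
                logger.warning("site %s snp %s: %s; skipped", site, snp_id, exc)
                continue
            snp_pos = int(window.snps.at[snp_id, "pos"])
            site_rows.append(
                {
                    "cpg_site_id": site,
                    "snp_id": snp_id,
                    "chrom": chrom,
                    "pos": snp_pos,
                    "distance_bp": snp_pos - pos,
                    "n": res["n"],
                    "beta": res["beta"],
                    "se": res["se"],
                    "stat": res["stat"],
                    "p": res["p"],
                }
            )
        if not site_rows:
            logger.warning("site %s: no testable SNPs in window; skipped", site)
            continue
        if config.bonferroni_within_window:
            m_tests = len(site_rows)
            for r in site_rows:
                r["p_bonf"] = min(1.0, r["p"] * m_tests)
        records.extend(site_rows)
        lead = min(site_rows, key=lambda r: (r["p"], r["pos"]))
        lead_records.append(lead)

    results = pd.DataFrame(records)
    leads = pd.DataFrame(lead_records)
    return results, leads


def write_meqtl_results(results: pd.DataFrame, leads: pd.DataFrame, results_path: str, leads_path: str) -> None:
    results.to_csv(results_path, sep="\t", index=False, float_format="%.6g")
    leads.to_csv(leads_path, sep="\t", index=False, float_format="%.6g")
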