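"""Reference validation experiments for the screen and the mixed model.

These functions package the simulation studies used to validate the
implementation: null calibration of the association test, closed-form
checks of the sibling Spearman correlation and the logistic-link SD
approximation, planted-signal recovery of the outlier screen, and causal
lead-SNP localization of the cis-meQTL scan.  Each takes an integer seed
and returns plain numbers, so the same experiment can back a test and a
report.  Problem sizes are chosen so that each experiment runs in seconds
to a few minutes on one core; the methods note documents the choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import fit_null_lmm, test_snp
from .meqtl import meqtl_scan
from .methylation import MethylationMatrix
from .outliers import run_outlier_pipeline
from .pedigree import compute_kinship, extract_sibling_pairs
from .simulate import (
    SimulationConfig,
    draw_family_effects,
    generate_study,
    simulate_methylation,
    simulate_pedigrees,
)
from .site_stats import sibling_spearman, site_sd

__all__ = [
    "spearman_of_bivariate_normal",
    "lmm_null_calibration",
    "recovery_experiment",
    "localization_experiment",
    "spearman_closed_form_experiment",
    "sd_delta_method_experiment",
]


def spearman_of_bivariate_normal(rho: float) -> float:
    """Population Spearman correlation of a bivariate normal with Pearson rho.

    The classical identity rho_s = (6/pi) * asin(rho/2); it is invariant
    under strictly monotone marginal transforms such as the logistic link.
    """
    return float(6.0 / np.pi * np.arcsin(rho / 2.0))


def lmm_null_calibration(
    seed: int, n_replicates: int = 2000, n_pedigrees: int = 50
) -> np.ndarray:
    """Null p-values of the association test on pedigree-simulated traits.

    Each replicate draws a trait with genuine polygenic variance
    (sigma_g2 = sigma_e2 = 0.5) on sib-pair pedigrees (n = 4 * n_pedigrees)
    and tests a permuted SNP, so the SNP effect is exactly null while the
    trait retains family structure.  Returns the p-value array.
    """
    cfg = SimulationConfig(n_pedigrees=n_pedigrees, sibship_size_probs={2: 1.0}, seed=seed)
    ped = simulate_pedigrees(cfg)
    R = compute_kinship(ped).relatedness()
    n = R.shape[0]
    L = np.linalg.cholesky(R + 1e-10 * np.eye(n))
    X = np.ones((n, 1))
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        y = L @ rng.normal(size=n) * np.sqrt(0.5) + rng.normal(size=n) * np.sqrt(0.5)
        g = rng.permutation(rng.binomial(2, 0.3, size=n).astype(float))
        fit = fit_null_lmm(y, X, R)
        pvals[i] = test_snp(fit, g)["p"]
    return pvals


def recovery_config(seed: int) -> SimulationConfig:
    """The planted-signal recovery study: 5,000 sites, 150 sib-pair/trio
    pedigrees, 20 treatment-responsive sites whose causal cis-SNPs explain
    most of the post-treatment latent variance (~80-90% at the default
    allele effect of 4 latent units and causal MAF 0.3-0.5)."""
    return SimulationConfig(
        n_pedigrees=150,
        sibship_size_probs={2: 0.3, 3: 0.7},
        n_sites=5000,
        site_class_fractions={
            "null": 4980 / 5000,
            "constitutive_meqtl": 0.0,
            "responsive": 20 / 5000,
        },
        seed=seed,
    )


def recovery_experiment(seed: int, threshold_fraction: float = 0.005) -> dict:
    """Run the outlier screen on one recovery study and score it vs truth."""
    study = generate_study(recovery_config(seed))
    from .site_stats import build_site_stat_table

    stats = build_site_stat_table(study.pre, study.post, study.ped)
    report = run_outlier_pipeline(stats, threshold_fraction=threshold_fraction, fallback_fractions=())
    responsive = set(study.truth.index[study.truth["class"] == "responsive"])
    recall = len(report.candidates & responsive) / len(responsive)
    null_candidates = len(report.candidates - responsive)
    return {
        "recall": recall,
        "n_null_candidates": null_candidates,
        "n_candidates": len(report.candidates),
        "n_responsive": len(responsive),
    }


def localization_experiment(seed: int, n_replicates: int = 50) -> float:
    """Fraction of scans whose lead SNP is the planted causal SNP.

    Each replicate is a 400-individual sib-pair study with one site whose
    causal SNP explains roughly 30% of the latent variance (allele effect
    1.0, background variance 1.0) among 19 independent decoy SNPs.
    """
    hits = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(
            n_pedigrees=100,
            sibship_size_probs={2: 1.0},
            n_sites=1,
            site_class_fractions={"null": 0.0, "constitutive_meqtl": 1.0, "responsive": 0.0},
            beta_constitutive=1.0,
            post_retention=1.0,
            seed=seed * 1000 + rep,
        )
        study = generate_study(cfg)
        site = study.truth.index[0]
        _, leads = meqtl_scan(study.post, [site], study.genotypes, study.ped)
        if not leads.empty and leads.iloc[0]["snp_id"] == study.truth.at[site, "causal_snp"]:
            hits += 1
    return hits / n_replicates


def spearman_closed_form_experiment(
    seed: int, n_pairs: int = 2000, n_sites: int = 200
) -> tuple[float, float]:
    """Mean null-site sibling Spearman vs its bivariate-normal closed form.

    With sigma_a2 = sigma_e2 = 1 and no shared environment, full siblings
    have latent correlation 0.25, so the expected Spearman correlation is
    (6/pi) * asin(0.125).  Returns (simulated mean over sites, expected).
    """
    cfg = SimulationConfig(
        n_pedigrees=n_pairs,
        sibship_size_probs={2: 1.0},
        n_sites=n_sites,
        site_class_fractions={"null": 1.0},
        sigma_a2=1.0,
        sigma_c2=0.0,
        sigma_e2=1.0,
        post_retention=1.0,
        seed=seed,
    )
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigrees(cfg, rng)
    from .simulate import make_truth
    from .genotypes import GenotypeMatrix

    sites, truth = make_truth(cfg, rng)
    g = GenotypeMatrix(ped.individual_ids, pd.DataFrame(columns=["chrom", "pos"]), np.empty((ped.n_individuals, 0)))
    fam = draw_family_effects(ped, cfg, rng)
    m = simulate_methylation(ped, g, truth, sites, cfg, "pre", rng, family_effects=fam)
    pairs = extract_sibling_pairs(ped)
    scors = sibling_spearman(m, pairs)
    rho_latent = 0.5 * cfg.sigma_a2 / (cfg.sigma_a2 + cfg.sigma_e2)
    return float(scors.mean()), spearman_of_bivariate_normal(rho_latent)


def sd_delta_method_experiment(
    seed: int,
    latent_sd: float = 0.3,
    n_pedigrees: int = 1200,
    mus=(-1.0, 0.0, 1.0),
    sites_per_mu: int = 40,
) -> list[tuple[float, float, float]]:
    """Beta-value SD at sigma-known sites vs the delta-method prediction.

    Sites are generated with known baseline mu and pure residual latent
    variance sigma^2; for small sigma the logistic link gives
    SD(beta) ~= p(1-p) * sigma with p = expit(mu).  Returns
    (mu, mean simulated SD over sites, predicted SD) rows.
    """
    from scipy.special import expit

    from .genotypes import GenotypeMatrix
    from .simulate import make_truth

    n_sites = len(mus) * sites_per_mu
    cfg = SimulationConfig(
        n_pedigrees=n_pedigrees,
        sibship_size_probs={1: 1.0},
        n_sites=n_sites,
        site_class_fractions={"null": 1.0},
        sigma_a2=0.0,
        sigma_c2=0.0,
        sigma_e2=latent_sd**2,
        mu_sd=0.0,
        post_retention=1.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    ped = simulate_pedigrees(cfg, rng)
    sites, truth = make_truth(cfg, rng)
    truth["mu"] = np.repeat(np.asarray(mus, dtype=float), sites_per_mu)
    g = GenotypeMatrix(
        ped.individual_ids, pd.DataFrame(columns=["chrom", "pos"]), np.empty((ped.n_individuals, 0))
    )
    m = simulate_methylation(ped, g, truth, sites, cfg, "pre", rng)
    sd = site_sd(m)
    out = []
    for i, mu in enumerate(mus):
        group = sd.iloc[i * sites_per_mu : (i + 1) * sites_per_mu]
        p = expit(mu)
        out.append((float(mu), float(group.mean()), float(p * (1 - p) * latent_sd)))
    return out
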