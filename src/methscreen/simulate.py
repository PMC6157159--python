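"""Synthetic pedigree methylation studies with planted treatment effects.

The generator realises the generative model the screen is designed to
detect.  Per individual i, site j and treatment phase, a latent trait

    z_ij = mu_j + beta_phase,j * dosage_ij + a_ij + c_fj
           + 1[phase = post] * batch_shift + e_ij

is pushed through the logistic function to give a bounded beta value.
Components:

* ``mu_j``          per-site baseline, N(0, mu_sd^2), shared across phases;
* ``a_ij``          additive polygenic effect, MVN(0, sigma_a2 * 2*Phi) within
                    each pedigree, shared across phases (it is genetic);
* ``c_fj``          environment shared by a full sibship, N(0, sigma_c2),
                    shared across phases;
* ``e_ij``          residual, N(0, sigma_e2), drawn independently per phase;
* ``batch_shift``   a location shift applied to every site post-treatment,
                    emulating the treatment-confounded batch effect that
                    motivates the indirect screen;
* ``beta_phase,j``  the per-allele effect of the site's causal cis-SNP,
                    applied to the mean-centred dosage so ``mu_j`` remains
                    the site's baseline level: zero at null sites, equal
                    pre/post at constitutive meQTL sites, and post-only at
                    treatment-responsive sites.

Genotypes are produced by Mendelian gene dropping: founder alleles are
Bernoulli(MAF) under Hardy-Weinberg and each child receives one uniformly
chosen allele per parent.  Each non-null site gets a causal SNP within
+/- 50 kb plus independent neighbour SNPs filling its +/- 1 Mb cis window.
Because the logistic map is strictly increasing, rank statistics (sibling
Spearman, SD ranks) computed on beta values coincide with those on the
latent scale.

Post-treatment attrition drops whole pedigrees at random, so surviving
sibling pairs remain intact (the pair count, not the individual count, is
what the familiality screen consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .genotypes import GenotypeMatrix, write_genotypes_tsv, write_genotypes_vcf
from .methylation import MethylationMatrix, write_methylation
from .pedigree import Pedigree, compute_kinship, write_pedigree

__all__ = [
    "SimulationConfig",
    "StudyData",
    "simulate_pedigrees",
    "simulate_genotypes",
    "simulate_methylation",
    "make_truth",
    "draw_family_effects",
    "generate_study",
    "write_study",
    "load_config",
]

SITE_CLASSES = ("null", "constitutive_meqtl", "responsive")


@dataclass
class SimulationConfig:
    """Study-generation parameters.

    Defaults emulate the screen's target study: 182 pedigrees whose sibship
    size distribution yields ~163 expected full-sib pairs, post-treatment
    whole-pedigree retention mirroring the 119/163 pair attrition, and a
    latent background variance of 1.0 split into additive-genetic, shared
    sibship-environment and residual parts.
    """

    n_pedigrees: int = 182
    sibship_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.45, 3: 0.15}
    )
    n_sites: int = 1000
    site_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"null": 0.98, "constitutive_meqtl": 0.01, "responsive": 0.01}
    )
    # latent-scale variance components (background total 1.0)
    sigma_a2: float = 0.2
    sigma_c2: float = 0.05
    sigma_e2: float = 0.75
    mu_sd: float = 1.0
    # causal-SNP allele effects on the latent scale
    beta_responsive: float = 4.0   # post-treatment only
    beta_constitutive: float = 4.0  # both phases
    batch_shift: float = 0.5
    snp_maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] = (0.3, 0.5)
    snps_per_window: int = 20
    causal_offset_bp: int = 50_000
    window_bp: int = 1_000_000
    post_retention: float = 0.73
    seed: int = 0

    def validate(self) -> None:
        fr = self.site_class_fractions
        if set(fr) - set(SITE_CLASSES):
            raise ValueError(f"unknown site classes: {set(fr) - set(SITE_CLASSES)}")
        if abs(sum(fr.values()) - 1.0) > 1e-12:
            raise ValueError("site_class_fractions must sum to 1")
        if abs(sum(self.sibship_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("sibship_size_probs must sum to 1")
        if any(k < 1 for k in self.sibship_size_probs):
            raise ValueError("sibship sizes must be >= 1")
        for name in ("sigma_a2", "sigma_c2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.post_retention <= 1:
            raise ValueError("post_retention must be in (0, 1]")
        if self.n_pedigrees < 1 or self.n_sites < 1 or self.snps_per_window < 1:
            raise ValueError("n_pedigrees, n_sites and snps_per_window must be >= 1")


def load_config(path: str) -> SimulationConfig:
    """Load a SimulationConfig from YAML (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "site_class_fractions" in raw:
        # YAML reads a bare `null` key as None
        raw["site_class_fractions"] = {
            ("null" if k is None else str(k)): float(v)
            for k, v in raw["site_class_fractions"].items()
        }
    if "sibship_size_probs" in raw:
        raw["sibship_size_probs"] = {int(k): float(v) for k, v in raw["sibship_size_probs"].items()}
    if "snp_maf_range" in raw:
        raw["snp_maf_range"] = tuple(raw["snp_maf_range"])
    if "causal_maf_range" in raw:
        raw["causal_maf_range"] = tuple(raw["causal_maf_range"])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class StudyData:
    """A complete simulated study: inputs for every pipeline stage plus truth."""

    ped: Pedigree
    genotypes: GenotypeMatrix
    pre: MethylationMatrix
    post: MethylationMatrix
    truth: pd.DataFrame = field(repr=False)
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# Pedigrees


def simulate_pedigrees(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Nuclear families: two founders plus a sibship of sampled size."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    sizes = np.array(sorted(cfg.sibship_size_probs), dtype=int)
    probs = np.array([cfg.sibship_size_probs[int(k)] for k in sizes])
    sampled = rng.choice(sizes, size=cfg.n_pedigrees, p=probs)
    rows = []
    for i, k in enumerate(sampled, start=1):
        pid = f"P{i:04d}"
        fa, mo = f"{pid}_F", f"{pid}_M"
        rows.append({"pedigree_id": pid, "individual_id": fa, "father_id": None, "mother_id": None, "sex": "male", "birth_order": None})
        rows.append({"pedigree_id": pid, "individual_id": mo, "father_id": None, "mother_id": None, "sex": "female", "birth_order": None})
        child_sex = rng.integers(0, 2, size=k)
        for b in range(1, int(k) + 1):
            rows.append(
                {
                    "pedigree_id": pid,
                    "individual_id": f"{pid}_S{b}",
                    "father_id": fa,
                    "mother_id": mo,
                    "sex": "male" if child_sex[b - 1] == 0 else "female",
                    "birth_order": b,
                }
            )
    table = pd.DataFrame(rows)
    table["birth_order"] = table["birth_order"].astype("Int64")
    return Pedigree(table)


# ---------------------------------------------------------------------------
# Site layout and truth

_N_CHROMS = 22
_SITE_SPACING_BP = 3_000_000  # > 2 * window so cis windows never overlap
_FIRST_POS = 2_000_000


def make_truth(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site coordinates and per-site ground truth (class, effects, baseline).

    Returns ``(sites, truth)``; sites round-robin over chromosomes 1..22 at
    non-overlapping spacing, class labels assigned by seeded permutation to
    match the configured fractions.
    """
    n = cfg.n_sites
    site_ids = [f"cg{i:07d}" for i in range(1, n + 1)]
    chrom = [(i % _N_CHROMS) + 1 for i in range(n)]
    pos = [_FIRST_POS + (i // _N_CHROMS) * _SITE_SPACING_BP for i in range(n)]
    sites = pd.DataFrame({"chrom": [str(c) for c in chrom], "pos": pos}, index=pd.Index(site_ids, name="site_id"))

    counts = {cls: int(round(cfg.site_class_fractions.get(cls, 0.0) * n)) for cls in SITE_CLASSES}
    counts["null"] = n - counts["constitutive_meqtl"] - counts["responsive"]
    labels = np.array(
        ["null"] * counts["null"]
        + ["constitutive_meqtl"] * counts["constitutive_meqtl"]
        + ["responsive"] * counts["responsive"],
        dtype=object,
    )
    labels = labels[rng.permutation(n)]
    beta_pre = np.where(labels == "constitutive_meqtl", cfg.beta_constitutive, 0.0)
    beta_post = np.where(
        labels == "responsive",
        cfg.beta_responsive,
        np.where(labels == "constitutive_meqtl", cfg.beta_constitutive, 0.0),
    )
    truth = pd.DataFrame(
        {
            "class": labels,
            "causal_snp": "",
            "beta_pre": beta_pre,
            "beta_post": beta_post,
            "mu": rng.normal(0.0, cfg.mu_sd, size=n),
        },
        index=sites.index,
    )
    return sites, truth


# ---------------------------------------------------------------------------
# Genotypes (gene dropping)


def simulate_genotypes(
    ped: Pedigree,
    sites: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Gene-dropped genotypes for every non-null site's cis window.

    Each responsive/constitutive site receives one causal SNP within
    +/- causal_offset_bp of the CpG and ``snps_per_window - 1`` independent
    neighbour SNPs uniform in the +/- 1 Mb window.  Founder alleles are
    Bernoulli(MAF); children inherit one uniformly chosen allele per
    parent.  Returns the genotype matrix and the truth table updated with
    causal SNP ids.
    """
    truth = truth.copy()
    snp_rows = []
    mafs = []
    signal_sites = truth.index[truth["class"] != "null"]
    for site in signal_sites:
        chrom = sites.at[site, "chrom"]
        cpg_pos = int(sites.at[site, "pos"])
        causal_id = f"rs_{site}_causal"
        causal_pos = cpg_pos + int(rng.integers(-cfg.causal_offset_bp, cfg.causal_offset_bp + 1))
        snp_rows.append({"snp_id": causal_id, "chrom": chrom, "pos": max(1, causal_pos)})
        mafs.append(rng.uniform(*cfg.causal_maf_range))
        truth.at[site, "causal_snp"] = causal_id
        for k in range(1, cfg.snps_per_window):
            off = int(rng.integers(-cfg.window_bp, cfg.window_bp + 1))
            snp_rows.append({"snp_id": f"rs_{site}_n{k}", "chrom": chrom, "pos": max(1, cpg_pos + off)})
            mafs.append(rng.uniform(*cfg.snp_maf_range))

    snps = pd.DataFrame(snp_rows).set_index("snp_id") if snp_rows else pd.DataFrame(columns=["chrom", "pos"])
    n_snp = len(snps)
    order = ped.topological_order()
    t = ped.table.set_index("individual_id")
    pos_of = {iid: i for i, iid in enumerate(ped.individual_ids)}
    n_ind = len(pos_of)

    maf_arr = np.asarray(mafs)
    a1 = np.zeros((n_ind, n_snp), dtype=np.int8)
    a2 = np.zeros((n_ind, n_snp), dtype=np.int8)
    for iid in order:
        i = pos_of[iid]
        fa, mo = t.at[iid, "father_id"], t.at[iid, "mother_id"]
        if fa is None or pd.isna(fa):
            a1[i] = rng.random(n_snp) < maf_arr
            a2[i] = rng.random(n_snp) < maf_arr
        else:
            fi, mi = pos_of[fa], pos_of[mo]
            pick_f = rng.integers(0, 2, size=n_snp)
            pick_m = rng.integers(0, 2, size=n_snp)
            a1[i] = np.where(pick_f == 0, a1[fi], a2[fi])
            a2[i] = np.where(pick_m == 0, a1[mi], a2[mi])
    dosages = (a1 + a2).astype(float)
    return GenotypeMatrix(ped.individual_ids, snps, dosages), truth


# ---------------------------------------------------------------------------
# Methylation


def draw_family_effects(
    ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-shared random effects: polygenic ``a`` and sibship-shared ``c``.

    ``a`` is MVN(0, sigma_a2 * 2*Phi) per pedigree (Cholesky of the
    relatedness block); ``c`` gives every full sibship one shared draw per
    site and each founder an independent draw, so marginal variances agree.
    Both are (n_individuals, n_sites) arrays.
    """
    n_ind, n_sites = ped.n_individuals, cfg.n_sites
    pos_of = {iid: i for i, iid in enumerate(ped.individual_ids)}
    a = np.zeros((n_ind, n_sites))
    if cfg.sigma_a2 > 0:
        kin = compute_kinship(ped)
        for pid in ped.pedigree_ids:
            members = [
                iid
                for iid, p in zip(ped.table["individual_id"], ped.table["pedigree_id"])
                if p == pid
            ]
            idx = np.array([pos_of[iid] for iid in members])
            block = kin.values[np.ix_(idx, idx)] * 2.0
            L = np.linalg.cholesky(block + 1e-10 * np.eye(len(idx)))
            a[idx, :] = np.sqrt(cfg.sigma_a2) * (L @ rng.standard_normal((len(idx), n_sites)))

    c = np.zeros((n_ind, n_sites))
    if cfg.sigma_c2 > 0:
        t = ped.table
        group_of: dict[str, int] = {}
        n_groups = 0
        sib_key: dict[tuple, int] = {}
        for _, r in t.iterrows():
            if r["father_id"] is None or pd.isna(r["father_id"]):
                group_of[r["individual_id"]] = n_groups
                n_groups += 1
            else:
                key = (r["pedigree_id"], r["father_id"], r["mother_id"])
                if key not in sib_key:
                    sib_key[key] = n_groups
                    n_groups += 1
                group_of[r["individual_id"]] = sib_key[key]
        draws = rng.normal(0.0, np.sqrt(cfg.sigma_c2), size=(n_groups, n_sites))
        for iid, grp in group_of.items():
            c[pos_of[iid], :] = draws[grp]
    return a, c


def simulate_methylation(
    ped: Pedigree,
    g: GenotypeMatrix,
    truth: pd.DataFrame,
    sites: pd.DataFrame,
    cfg: SimulationConfig,
    phase: str,
    rng: np.random.Generator,
    family_effects: tuple[np.ndarray, np.ndarray] | None = None,
    sample_ids: list[str] | None = None,
) -> MethylationMatrix:
    """One phase's beta-value matrix from the latent variance-component model.

    ``family_effects`` (from :func:`draw_family_effects`) should be passed
    when generating both phases of one study so the genetic and shared
    environment components are identical pre and post; only the residual,
    the batch shift and the phase-specific SNP effects differ.
    """
    if phase not in {"pre", "post"}:
        raise ValueError("phase must be 'pre' or 'post'")
    if family_effects is None:
        family_effects = draw_family_effects(ped, cfg, rng)
    a, c = family_effects

    n_ind, n_sites = ped.n_individuals, cfg.n_sites
    beta_col = truth[f"beta_{phase}"].to_numpy(dtype=float)
    z = truth["mu"].to_numpy(dtype=float)[None, :] + a + c
    if phase == "post":
        z = z + cfg.batch_shift
    snp_pos = {s: j for j, s in enumerate(g.snp_ids)}
    for j, site in enumerate(truth.index):
        b = beta_col[j]
        causal = truth.at[site, "causal_snp"]
        if b != 0.0 and causal:
            # centre on the mean dosage so mu stays the site's baseline level
            d = g.dosages[:, snp_pos[causal]]
            z[:, j] = z[:, j] + b * (d - d.mean())
    z = z + rng.normal(0.0, np.sqrt(cfg.sigma_e2), size=(n_ind, n_sites))

    values = pd.DataFrame(expit(z), index=ped.individual_ids, columns=truth.index)
    if sample_ids is not None:
        values = values.loc[[s for s in ped.individual_ids if s in set(sample_ids)]]
    return MethylationMatrix(values, sites, phase)


def _post_sample(ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Whole-pedigree post-treatment retention (pairs stay intact)."""
    pids = ped.pedigree_ids
    n_keep = max(1, int(round(cfg.post_retention * len(pids))))
    keep = set(rng.choice(np.array(pids, dtype=object), size=n_keep, replace=False))
    t = ped.table
    return [iid for iid, p in zip(t["individual_id"], t["pedigree_id"]) if p in keep]


def generate_study(cfg: SimulationConfig) -> StudyData:
    """One-call, fully seeded end-to-end study generation."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigrees(cfg, rng)
    sites, truth = make_truth(cfg, rng)
    genotypes, truth = simulate_genotypes(ped, sites, truth, cfg, rng)
    fam = draw_family_effects(ped, cfg, rng)
    pre = simulate_methylation(ped, genotypes, truth, sites, cfg, "pre", rng, family_effects=fam)
    post_ids = _post_sample(ped, cfg, rng)
    post = simulate_methylation(
        ped, genotypes, truth, sites, cfg, "post", rng, family_effects=fam, sample_ids=post_ids
    )
    return StudyData(ped=ped, genotypes=genotypes, pre=pre, post=post, truth=truth, config=cfg)


def write_study(study: StudyData, out_dir: str) -> dict[str, str]:
    """Write every artefact in the formats the analysis modules read."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "pedigree": os.path.join(out_dir, "pedigree.fam"),
        "genotypes_vcf": os.path.join(out_dir, "genotypes.vcf"),
        "dosages": os.path.join(out_dir, "dosages.tsv"),
        "snps": os.path.join(out_dir, "snps.tsv"),
        "pre": os.path.join(out_dir, "methylation_pre.tsv"),
        "post": os.path.join(out_dir, "methylation_post.tsv"),
        "sites": os.path.join(out_dir, "sites.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "config": os.path.join(out_dir, "sim_config.yaml"),
    }
    write_pedigree(study.ped, paths["pedigree"])
    write_genotypes_vcf(study.genotypes, paths["genotypes_vcf"])
    write_genotypes_tsv(study.genotypes, paths["dosages"], paths["snps"])
    write_methylation(study.pre, paths["pre"], paths["sites"])
    write_methylation(study.post, paths["post"], os.path.join(out_dir, "sites_post.tsv"))
    study.truth.to_csv(paths["truth"], sep="\t", index_label="site_id", float_format="%.6g")
    if study.config is not None:
        cfg_dict = asdict(study.config)
        cfg_dict["snp_maf_range"] = list(study.config.snp_maf_range)
        cfg_dict["causal_maf_range"] = list(study.config.causal_maf_range)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)
    return paths
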