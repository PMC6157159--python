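"""End-to-end orchestration: data -> site statistics -> outlier screen -> meQTL.

``run_pipeline`` chains the stages on either a simulated study or files on
disk, writes every artefact into a run directory and records a manifest
(config hash, seed, thresholds used, sample and pair counts) so a run is
fully reproducible and auditable.  ``sample_mode='common'`` restricts both
phases to the individuals (and hence sibling pairs) present in both — the
reduced consistent-sample variant of the analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .meqtl import MeQTLConfig, meqtl_scan, write_meqtl_results
from .methylation import MethylationMatrix, read_methylation
from .outliers import run_outlier_pipeline, write_outlier_report, OutlierReport
from .pedigree import Pedigree, extract_sibling_pairs, read_pedigree, restrict_pairs
from .site_stats import build_site_stat_table, write_site_stats
from .simulate import SimulationConfig, StudyData, generate_study

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; either a simulation config or input paths."""

    out_dir: str
    sim: SimulationConfig | None = None
    pedigree_path: str | None = None
    pre_path: str | None = None
    post_path: str | None = None
    sites_path: str | None = None
    dosages_path: str | None = None
    snps_path: str | None = None
    threshold_fraction: float = 0.001
    fallback_fractions: tuple[float, ...] = (0.005, 0.01)
    min_pairs: int = 10
    one_pair_per_sibship: bool = False
    meqtl: MeQTLConfig = field(default_factory=MeQTLConfig)
    run_meqtl: bool = True
    sample_mode: str = "full"  # or "common"
    seed: int = 0

    def validate(self) -> None:
        if self.sample_mode not in {"full", "common"}:
            raise ValueError("sample_mode must be 'full' or 'common'")
        if self.sim is None and not (self.pedigree_path and self.pre_path and self.post_path and self.sites_path):
            raise ValueError("either a simulation config or pedigree/pre/post/sites paths are required")


@dataclass
class PipelineResult:
    stats: pd.DataFrame = field(repr=False)
    report: OutlierReport = field(repr=False)
    meqtl_results: pd.DataFrame | None = field(repr=False, default=None)
    meqtl_leads: pd.DataFrame | None = field(repr=False, default=None)
    manifest: dict = field(default_factory=dict)


def _config_hash(cfg: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return {k: getattr(o, k) for k in o.__dataclass_fields__}
        return str(o)

    blob = json.dumps(cfg, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig) -> tuple[Pedigree, MethylationMatrix, MethylationMatrix, StudyData | None]:
    if cfg.sim is not None:
        sim_cfg = cfg.sim
        if sim_cfg.seed != cfg.seed:
            sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": cfg.seed})
        study = generate_study(sim_cfg)
        return study.ped, study.pre, study.post, study
    ped = read_pedigree(cfg.pedigree_path, dialect="fam_birthorder")
    pre = read_methylation(cfg.pre_path, cfg.sites_path, "pre")
    post = read_methylation(cfg.post_path, cfg.sites_path, "post")
    return ped, pre, post, None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run statistics -> outlier screen -> (optionally) the cis-meQTL scan."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    stage = "load"
    try:
        ped, pre, post, study = _load_inputs(cfg)

        if cfg.sample_mode == "common":
            common = [s for s in pre.sample_ids if s in set(post.sample_ids)]
            if not common:
                raise ValueError("sample_mode='common' but the phases share no samples")
            pre = pre.restrict_samples(common)
            post = post.restrict_samples(common)
            logger.info("common-sample mode: %d shared individuals", len(common))

        stage = "site_statistics"
        stats = build_site_stat_table(
            pre, post, ped, min_pairs=cfg.min_pairs, one_pair_per_sibship=cfg.one_pair_per_sibship
        )
        write_site_stats(stats, os.path.join(cfg.out_dir, "site_stats.tsv"))

        stage = "outlier_screen"
        report = run_outlier_pipeline(
            stats,
            threshold_fraction=cfg.threshold_fraction,
            fallback_fractions=cfg.fallback_fractions,
            site_annotation=pre.sites,
        )
        write_outlier_report(report, cfg.out_dir)
        logger.info(
            "outlier screen: %d candidates at fraction %g (fallback_used=%s)",
            len(report.candidates),
            report.threshold_fraction,
            report.fallback_used,
        )

        meqtl_results = meqtl_leads = None
        if cfg.run_meqtl and report.candidates:
            stage = "meqtl"
            if study is not None:
                genotypes = study.genotypes
            elif cfg.dosages_path and cfg.snps_path:
                from .genotypes import read_genotypes_tsv

                genotypes = read_genotypes_tsv(cfg.dosages_path, cfg.snps_path)
            else:
                genotypes = None
            if genotypes is not None:
                meqtl_results, meqtl_leads = meqtl_scan(
                    post, sorted(report.candidates), genotypes, ped, cfg.meqtl
                )
                write_meqtl_results(
                    meqtl_results,
                    meqtl_leads,
                    os.path.join(cfg.out_dir, "meqtl_results.tsv"),
                    os.path.join(cfg.out_dir, "meqtl_leads.tsv"),
                )
            else:
                logger.warning("no genotypes available; meQTL stage skipped")

        stage = "manifest"
        all_pairs = extract_sibling_pairs(ped, one_pair_per_sibship=cfg.one_pair_per_sibship)
        pre_ids, post_ids = set(pre.sample_ids), set(post.sample_ids)
        manifest = {
            "version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
            "sample_mode": cfg.sample_mode,
            "n_samples_pre": len(pre_ids),
            "n_samples_post": len(post_ids),
            "n_samples_common": len(pre_ids & post_ids),
            "n_pairs_pre": len(restrict_pairs(all_pairs, pre_ids)),
            "n_pairs_post": len(restrict_pairs(all_pairs, post_ids)),
            "n_pairs_common": len(restrict_pairs(all_pairs, pre_ids & post_ids)),
            "n_sites": len(stats),
            "threshold_fraction_used": report.threshold_fraction,
            "thresholds_tried": report.thresholds_tried,
            "fallback_used": report.fallback_used,
            "exhausted": report.exhausted,
            "n_candidates": len(report.candidates),
            "candidates": sorted(report.candidates),
        }
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
    return PipelineResult(
        stats=stats,
        report=report,
        meqtl_results=meqtl_results,
        meqtl_leads=meqtl_leads,
        manifest=manifest,
    )
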