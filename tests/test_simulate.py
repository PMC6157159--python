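import numpy as np
import pandas as pd
import pytest
from scipy import stats as st
from scipy.special import logit

from methscreen.genotypes import GenotypeMatrix
from methscreen.methylation import MethylationMatrix
from methscreen.pedigree import extract_sibling_pairs
from methscreen.site_stats import sibling_spearman, site_sd
from methscreen.simulate import (
    SimulationConfig,
    generate_study,
    load_config,
    make_truth,
    simulate_genotypes,
    simulate_methylation,
    simulate_pedigrees,
    write_study,
)


class TestConfig:
    def test_fraction_sum_validated(self):
        cfg = SimulationConfig(site_class_fractions={"null": 0.5, "responsive": 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_pedigrees: 10\nn_sites: 50\nseed: 7\nsibship_size_probs: {2: 1.0}\n")
        cfg = load_config(str(path))
        assert cfg.n_pedigrees == 10 and cfg.seed == 7

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("n_pedigree: 10\n")
        with pytest.raises(ValueError, match="unknown config"):
            load_config(str(path))


class TestPedigreeSimulation:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_pedigrees=30, seed=5)
        p1 = simulate_pedigrees(cfg)
        p2 = simulate_pedigrees(cfg)
        pd.testing.assert_frame_equal(p1.table, p2.table)

    def test_singleton_sibships_give_no_pairs(self):
        cfg = SimulationConfig(n_pedigrees=20, sibship_size_probs={1: 1.0}, seed=1)
        ped = simulate_pedigrees(cfg)
        assert extract_sibling_pairs(ped) == []

    def test_default_distribution_targets_pair_count(self):
        # expected all-pairs count per pedigree: p2 + 3*p3 = 0.9 -> ~163 pairs
        cfg = SimulationConfig(seed=11)
        counts = [len(extract_sibling_pairs(simulate_pedigrees(SimulationConfig(seed=s)))) for s in range(5)]
        assert 130 < np.mean(counts) < 200


class TestGenotypeSimulation:
    def test_mendelian_transmission_consistency(self, small_study):
        g = small_study.genotypes
        t = small_study.ped.table.set_index("individual_id")
        pos = {s: i for i, s in enumerate(g.sample_ids)}
        compatible = {
            (0, 0): {0},
            (0, 1): {0, 1},
            (1, 0): {0, 1},
            (0, 2): {1},
            (2, 0): {1},
            (1, 1): {0, 1, 2},
            (1, 2): {1, 2},
            (2, 1): {1, 2},
            (2, 2): {2},
        }
        children = t[t["father_id"].notna()]
        for iid, row in children.iloc[:50].iterrows():
            child = g.dosages[pos[iid]]
            fa = g.dosages[pos[row["father_id"]]]
            mo = g.dosages[pos[row["mother_id"]]]
            for c, f, m in zip(child, fa, mo):
                assert int(c) in compatible[(int(f), int(m))]

    def test_founder_allele_frequency(self):
        cfg = SimulationConfig(
            n_pedigrees=5000,
            sibship_size_probs={1: 1.0},
            n_sites=2,
            site_class_fractions={"null": 0.0, "constitutive_meqtl": 1.0, "responsive": 0.0},
            snps_per_window=2,
            snp_maf_range=(0.3, 0.3),
            causal_maf_range=(0.3, 0.3),
            seed=3,
        )
        rng = np.random.default_rng(3)
        ped = simulate_pedigrees(cfg, rng)
        sites, truth = make_truth(cfg, rng)
        g, _ = simulate_genotypes(ped, sites, truth, cfg, rng)
        founders = set(ped.founders())
        mask = np.array([s in founders for s in g.sample_ids])
        means = g.dosages[mask].mean(axis=0)
        assert np.abs(means - 0.6).max() < 0.02

    def test_sibling_dosage_correlation_near_half(self):
        cfg = SimulationConfig(
            n_pedigrees=1000,
            sibship_size_probs={2: 1.0},
            n_sites=2,
            site_class_fractions={"null": 0.0, "constitutive_meqtl": 1.0, "responsive": 0.0},
            snps_per_window=10,
            seed=4,
        )
        rng = np.random.default_rng(4)
        ped = simulate_pedigrees(cfg, rng)
        sites, truth = make_truth(cfg, rng)
        g, _ = simulate_genotypes(ped, sites, truth, cfg, rng)
        pairs = extract_sibling_pairs(ped)
        pos = {s: i for i, s in enumerate(g.sample_ids)}
        a = np.stack([g.dosages[pos[p.first]] for p in pairs])
        b = np.stack([g.dosages[pos[p.second]] for p in pairs])
        # per-SNP correlation (pooling SNPs of different frequency inflates it)
        per_snp = [np.corrcoef(a[:, j], b[:, j])[0, 1] for j in range(a.shape[1])]
        assert np.mean(per_snp) == pytest.approx(0.5, abs=0.05)


class TestMethylationSimulation:
    def test_degenerate_config_gives_exactly_half(self):
        cfg = SimulationConfig(
            n_pedigrees=5,
            n_sites=10,
            site_class_fractions={"null": 1.0},
            sigma_a2=0.0,
            sigma_c2=0.0,
            sigma_e2=0.0,
            mu_sd=0.0,
            batch_shift=0.0,
            seed=0,
        )
        study = generate_study(cfg)
        assert np.all(study.pre.values.to_numpy() == 0.5)
        assert np.all(study.post.values.to_numpy() == 0.5)

    def test_beta_ranks_equal_latent_ranks(self, small_study):
        # logistic link is strictly monotone, so Spearman statistics are
        # identical computed from beta values or their logits
        pairs = extract_sibling_pairs(small_study.ped)
        m = small_study.pre
        latent_vals = np.clip(logit(m.values), -40, 40) / 80 + 0.5  # affine logit, still monotone
        latent = MethylationMatrix(latent_vals, m.sites, m.phase)
        s1 = sibling_spearman(m, pairs)
        s2 = sibling_spearman(latent, pairs)
        pd.testing.assert_series_equal(s1, s2, atol=1e-12)

    def test_responsive_sites_gain_post_sd(self):
        cfg = SimulationConfig(
            n_pedigrees=120,
            sibship_size_probs={2: 0.5, 3: 0.5},
            n_sites=200,
            site_class_fractions={"null": 0.0, "constitutive_meqtl": 0.0, "responsive": 1.0},
            post_retention=1.0,
            seed=8,
        )
        study = generate_study(cfg)
        sd_pre = site_sd(study.pre)
        sd_post = site_sd(study.post)
        res = st.wilcoxon(sd_post - sd_pre, alternative="greater")
        assert res.pvalue < 0.01

    def test_batch_shift_leaves_familiality_untouched_and_sd_ranks_correlated(self):
        # a constant latent shift preserves the within-site ordering of
        # individuals, so sibling Spearman correlations are *identical*;
        # beta-scale SD ranks are perturbed by the bounded link but remain
        # strongly correlated with the unshifted run
        base = dict(
            n_pedigrees=150,
            sibship_size_probs={2: 0.5, 3: 0.5},
            n_sites=500,
            site_class_fractions={"null": 1.0},
            post_retention=1.0,
            seed=9,
        )
        shifted = generate_study(SimulationConfig(batch_shift=0.5, **base))
        flat = generate_study(SimulationConfig(batch_shift=0.0, **base))
        pairs = extract_sibling_pairs(shifted.ped)
        s_shift = sibling_spearman(shifted.post, pairs)
        s_flat = sibling_spearman(flat.post, pairs)
        pd.testing.assert_series_equal(s_shift, s_flat, atol=1e-12)
        # SD(beta) ~ p(1-p)*sigma peaks at latent 0, so a 0.5 shift reorders
        # sites whose baselines straddle the peak; correlation stays clearly
        # positive but is far from perfect -- a documented limitation of
        # variability screening on a bounded scale
        rho = st.spearmanr(site_sd(shifted.post), site_sd(flat.post)).statistic
        assert rho > 0.5

    def test_all_null_fraction_gives_all_null_truth(self):
        cfg = SimulationConfig(n_pedigrees=5, n_sites=20, site_class_fractions={"null": 1.0}, seed=2)
        study = generate_study(cfg)
        assert (study.truth["class"] == "null").all()
        assert study.genotypes.n_snps == 0


class TestGenerateStudy:
    def test_written_files_are_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(
            n_pedigrees=12,
            n_sites=30,
            site_class_fractions={"null": 0.9, "constitutive_meqtl": 0.1, "responsive": 0.0},
            seed=21,
        )
        p1 = write_study(generate_study(cfg), str(tmp_path / "a"))
        p2 = write_study(generate_study(cfg), str(tmp_path / "b"))
        for name in ("pedigree", "genotypes_vcf", "dosages", "pre", "post", "truth"):
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()

    def test_round_trip_through_standard_formats(self, tmp_path):
        from methscreen.genotypes import read_genotypes_vcf
        from methscreen.methylation import read_methylation
        from methscreen.pedigree import read_pedigree

        cfg = SimulationConfig(
            n_pedigrees=10,
            n_sites=20,
            site_class_fractions={"null": 0.9, "constitutive_meqtl": 0.05, "responsive": 0.05},
            seed=13,
        )
        study = generate_study(cfg)
        paths = write_study(study, str(tmp_path))
        ped = read_pedigree(paths["pedigree"], dialect="fam_birthorder")
        assert ped.individual_ids == study.ped.individual_ids
        pre = read_methylation(paths["pre"], paths["sites"], "pre")
        np.testing.assert_allclose(
            pre.values.to_numpy(), study.pre.values.to_numpy(), atol=1e-5
        )
        g = read_genotypes_vcf(paths["genotypes_vcf"])
        assert set(g.snp_ids) == set(study.genotypes.snp_ids)

    def test_post_sample_keeps_whole_pedigrees(self, small_study):
        t = small_study.ped.table.set_index("individual_id")
        post_ids = set(small_study.post.sample_ids)
        post_peds = {t.at[s, "pedigree_id"] for s in post_ids}
        for pid in post_peds:
            members = set(t.index[t["pedigree_id"] == pid])
            assert members <= post_ids
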