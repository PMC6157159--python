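import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methscreen.outliers import (
    candidate_responsive_sites,
    concordant_outliers,
    outlier_turnover,
    rank_descending,
    run_outlier_pipeline,
    select_outliers,
    threshold_count_from_fraction,
    write_outlier_report,
)


def stats_table(sd_pre, sd_post, scor_pre, scor_post, ids=None):
    n = len(sd_pre)
    ids = ids or [f"cg{i:04d}" for i in range(n)]
    from methscreen.outliers import rank_descending as rd

    t = pd.DataFrame(
        {
            "sd_pre": sd_pre,
            "sd_post": sd_post,
            "scor_pre": scor_pre,
            "scor_post": scor_post,
            "n_pre": n,
            "n_post": n,
            "npairs_pre": 50,
            "npairs_post": 40,
        },
        index=pd.Index(ids, name="site_id"),
        dtype=float,
    )
    for col in ("sd_pre", "sd_post", "scor_pre", "scor_post"):
        t[f"rank_{col}"] = rd(t[col])
    return t


class TestRankDescending:
    def test_largest_gets_rank_one(self):
        r = rank_descending(pd.Series([0.3, 0.1, 0.2], index=["a", "b", "c"]))
        assert list(r) == [1, 3, 2]

    def test_ties_broken_by_site_id(self):
        r = rank_descending(pd.Series([0.2, 0.2, 0.1], index=["a", "b", "c"]))
        assert list(r) == [1, 2, 3]
        r2 = rank_descending(pd.Series([0.2, 0.2, 0.1], index=["b", "a", "c"]))
        assert list(r2) == [2, 1, 3]

    def test_missing_ranked_last(self):
        r = rank_descending(pd.Series([np.nan, 0.5, np.nan], index=["a", "b", "c"]))
        assert r["b"] == 1
        assert {r["a"], r["c"]} == {2, 3}
        assert r["a"] < r["c"]  # deterministic id order among missing

    @given(
        st.lists(
            st.one_of(st.floats(0, 1, allow_nan=False), st.just(float("nan"))),
            min_size=1,
            max_size=60,
        )
    )
    def test_always_a_permutation(self, values):
        s = pd.Series(values, index=[f"s{i:03d}" for i in range(len(values))])
        r = rank_descending(s)
        assert sorted(r) == list(range(1, len(values) + 1))


class TestSelectOutliers:
    def test_paper_scale_threshold(self):
        assert threshold_count_from_fraction(0.001, 450_000) == 450

    def test_top_two_selected(self):
        r = rank_descending(pd.Series(np.linspace(1, 0, 10), index=[f"s{i}" for i in range(10)]))
        assert select_outliers(r, 2) == {"s0", "s1"}

    def test_count_equal_to_n_selects_everything(self):
        r = rank_descending(pd.Series([0.1, 0.2], index=["a", "b"]))
        assert select_outliers(r, 2) == {"a", "b"}

    def test_out_of_range_count_rejected(self):
        r = rank_descending(pd.Series([0.1, 0.2], index=["a", "b"]))
        with pytest.raises(ValueError):
            select_outliers(r, 0)
        with pytest.raises(ValueError):
            select_outliers(r, 3)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False, width=16), min_size=3, max_size=50),
        st.integers(1, 50),
    )
    def test_cardinality_is_exactly_threshold_count(self, values, count):
        count = min(count, len(values))
        s = pd.Series(values, index=[f"s{i:03d}" for i in range(len(values))])
        assert len(select_outliers(rank_descending(s), count)) == count


class TestSetOperations:
    def test_concordance_is_intersection(self):
        assert concordant_outliers({"s1", "s2", "s3"}, {"s2", "s3", "s4"}) == {"s2", "s3"}
        assert concordant_outliers({"a"}, {"b"}) == set()

    def test_pre_outlier_concordant_site_excluded(self):
        # a site concordant post-treatment but already a pre-treatment SD
        # outlier gives no evidence of a treatment response
        cands = candidate_responsive_sites({"sA", "sB"}, sd_pre={"sA"}, scor_pre=set())
        assert cands == {"sB"}

    def test_turnover_examples(self):
        assert outlier_turnover({"a", "x", "y", "z"}, {"a", "b", "c", "d"}) == (3, 0.75)
        same = {f"s{i}" for i in range(450)}
        assert outlier_turnover(same, same) == (0, 0.0)

    def test_turnover_empty_post_set_rejected(self):
        with pytest.raises(ValueError):
            outlier_turnover({"a"}, set())

    @given(
        pre=st.sets(st.integers(0, 30)),
        post=st.sets(st.integers(0, 30), min_size=1),
    )
    def test_turnover_matches_set_arithmetic(self, pre, post):
        count, frac = outlier_turnover(pre, post)
        brute = len([s for s in post if s not in pre])
        assert count == brute
        assert frac == pytest.approx(brute / len(post))


class TestRunOutlierPipeline:
    def planted_stats(self, n=1000, signal_rank_frac=0.0):
        """One site leading (or at signal_rank_frac depth) in both post distributions."""
        rng = np.random.default_rng(0)
        sd_pre = rng.uniform(0.1, 0.2, n)
        sd_post = rng.uniform(0.1, 0.2, n)
        scor_pre = rng.uniform(-0.2, 0.2, n)
        scor_post = rng.uniform(-0.2, 0.2, n)
        k = int(signal_rank_frac * n)
        # place the planted site just below the top-k sites in both post distributions
        order_sd = np.argsort(sd_post)[::-1]
        order_sc = np.argsort(scor_post)[::-1]
        j = order_sd[0]
        sd_post[j] = np.sort(sd_post)[::-1][k] + 1e-6 if k else 0.5
        scor_post[j] = np.sort(scor_post)[::-1][k] + 1e-6 if k else 0.9
        # ensure it is mid-pack pre-treatment
        sd_pre[j] = np.median(sd_pre)
        scor_pre[j] = np.median(scor_pre)
        # make sure no other site is concordant at the top
        scor_post[order_sd[1 : k + 2]] = -0.5
        sd_post[order_sc[order_sc != j][: k + 2]] = 0.05
        ids = [f"cg{i:04d}" for i in range(n)]
        return stats_table(sd_pre, sd_post, scor_pre, scor_post, ids), ids[j]

    def test_planted_post_only_signal_is_sole_candidate(self):
        stats, planted = self.planted_stats()
        report = run_outlier_pipeline(stats, threshold_fraction=0.001)
        assert report.candidates == {planted}
        assert not report.fallback_used

    def test_no_signal_exhausts_all_thresholds(self):
        rng = np.random.default_rng(1)
        n = 400
        # anti-concordant by construction: post SD and scor tails disjoint
        sd_post = np.arange(n, dtype=float)
        scor_post = -np.arange(n, dtype=float)
        stats = stats_table(
            rng.uniform(size=n), sd_post, rng.uniform(size=n), scor_post
        )
        report = run_outlier_pipeline(stats, 0.001, (0.005, 0.01))
        assert report.exhausted
        assert report.thresholds_tried == [0.001, 0.005, 0.01]
        assert report.candidates == set()

    def test_fallback_level_recorded_when_needed(self):
        # signal detectable at 0.5% but not 0.1% of 1000 sites (rank ~3)
        stats, planted = self.planted_stats(signal_rank_frac=0.003)
        report = run_outlier_pipeline(stats, 0.001, (0.005, 0.01))
        assert report.fallback_used
        assert report.threshold_fraction == 0.005
        assert planted in report.candidates

    def test_candidates_never_include_pre_outliers(self, small_study):
        from methscreen.site_stats import build_site_stat_table

        stats = build_site_stat_table(small_study.pre, small_study.post, small_study.ped)
        report = run_outlier_pipeline(stats, 0.01, (0.05,))
        assert report.candidates <= report.post_concordant
        assert not report.candidates & (report.sd_pre | report.scor_pre)

    def test_post_concordant_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        n = 500
        stats = stats_table(
            rng.uniform(size=n), rng.uniform(size=n), rng.uniform(size=n), rng.uniform(size=n)
        )
        prev = set()
        for frac in (0.01, 0.02, 0.05, 0.1):
            rep = run_outlier_pipeline(stats, frac, ())
            assert prev <= rep.post_concordant
            prev = rep.post_concordant

    def test_report_writing_is_deterministic(self, tmp_path):
        stats, _ = self.planted_stats()
        report = run_outlier_pipeline(stats, 0.001)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        write_outlier_report(report, str(d1))
        write_outlier_report(report, str(d2))
        for name in (
            "outliers_sd_post.tsv",
            "candidates.tsv",
            "concordant_sites_table.tsv",
            "outlier_summary.json",
        ):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
        summary = json.loads((d1 / "outlier_summary.json").read_text())
        assert summary["n_candidates"] == 1

    def test_table_rows_flag_candidates_bold(self):
        stats, planted = self.planted_stats()
        report = run_outlier_pipeline(stats, 0.001)
        rows = report.table_rows.set_index("site_id")
        assert bool(rows.at[planted, "bold"]) is True
        assert set(report.table_rows["site_id"]) == report.post_concordant
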