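"""Cluster ratios, correlation machinery and sham descriptive counts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from capselbow.cohort import Arm, CapsScores, Cohort, ParticipantRecord
from capselbow.clusters import (ClusterAssociationModel, association_matrices,
                                bootstrap_inference, cluster_ratios, correlate,
                                sham_threshold_count)
from capselbow.synthetic import PlantedConfig, decompose_total, \
    generate_planted_cohort

from conftest import record
from oracles import spearman_oracle


def raw_record(pid, pre, post, fup, arm=Arm.ACTIVE):
    return ParticipantRecord(pid, arm, CapsScores(*pre), CapsScores(*post),
                             CapsScores(*fup))


class TestClusterRatios:
    def test_ratio_arithmetic(self):
        rec = raw_record("P1", (44, 10, 4, 18, 12), (40, 10, 2, 16, 12),
                         (38, 10, 2, 14, 12))
        r = cluster_ratios(Cohort(records=[rec]))[0]
        assert r.post_ratio["C"] == pytest.approx(0.5)
        assert r.fup_ratio["D"] == pytest.approx(14 / 18)

    def test_zero_baseline_cluster_marked_undefined_others_kept(self):
        rec = raw_record("P1", (40, 12, 0, 16, 12), (36, 10, 0, 14, 12),
                         (30, 8, 0, 12, 10))
        r = cluster_ratios(Cohort(records=[rec]))[0]
        assert not r.defined["C"] and math.isnan(r.post_ratio["C"])
        assert r.defined["B"] and r.post_ratio["B"] == pytest.approx(10 / 12)

    def test_unchanged_scores_give_unit_ratios(self):
        rec = raw_record("P1", (40, 10, 4, 14, 12), (40, 10, 4, 14, 12),
                         (40, 10, 4, 14, 12))
        r = cluster_ratios(Cohort(records=[rec]))[0]
        assert all(r.post_ratio[c] == 1.0 for c in "BCDE")


class TestCorrelate:
    def test_perfect_monotone_association(self):
        x = [1, 2, 3, 5, 8]
        assert correlate(x, [v ** 2 for v in x]).r == pytest.approx(1.0)
        assert correlate(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 3.0, 5.0]
        assert correlate(x, y).r == pytest.approx(spearman_oracle(x, y))

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                    min_size=3, max_size=8))
    def test_spearman_equals_brute_force_on_small_inputs(self, pairs):
        x = [float(a) for a, _ in pairs]
        y = [float(b) for _, b in pairs]
        res = correlate(x, y)
        if res.undefined:
            assert len(set(x)) == 1 or len(set(y)) == 1
        else:
            assert res.r == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        y = x + rng.normal(size=25)
        r1 = correlate(x, y).r
        assert correlate(np.exp(x), y).r == pytest.approx(r1)
        assert correlate(x, y ** 3).r == pytest.approx(r1)

    def test_zero_variance_marked_undefined(self):
        res = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined and math.isnan(res.r)

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            correlate([1, 2], [3, 4])


class TestBootstrap:
    def test_perfectly_correlated_data_has_degenerate_ci(self):
        x = np.arange(10.0)
        p, ci = bootstrap_inference(x, 2 * x + 1, b=200, seed=0)
        assert ci == (1.0, 1.0)
        assert p < 0.05

    def test_seeded_rerun_is_identical(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        assert bootstrap_inference(x, y, b=200, seed=7) == \
            bootstrap_inference(x, y, b=200, seed=7)

    def test_ci_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)

        def mean_width(n, sims=10):
            widths = []
            for s in range(sims):
                x = rng.normal(size=n)
                y = 0.5 * x + rng.normal(size=n)
                _, ci = bootstrap_inference(x, y, b=200, seed=s)
                widths.append(ci[1] - ci[0])
            return np.mean(widths)

        assert mean_width(200) < mean_width(20)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="b must be"):
            bootstrap_inference([1, 2, 3], [1, 2, 3], b=50)


class TestAssociationMatrices:
    def test_single_driving_cluster_dominates_and_others_undefined(self):
        # only cluster B changes at POST; C, D, E stay flat across subjects
        recs = []
        for i in range(8):
            pre = (44, 12, 4, 16, 12)
            post = (44 - i, 12 - i, 4, 16, 12)
            fup = (43 - i, 11 - i, 4, 16, 12)
            recs.append(raw_record(f"P{i}", pre, post, fup))
        mats = association_matrices(Cohort(records=recs), b=200, seed=0)
        a = mats["post_vs_post_total"].results
        assert a["B"].r == pytest.approx(1.0)
        for cl in "CDE":
            assert a[cl].undefined

    def test_planted_cluster_c_dependence_ranks_first(self):
        # follow-up total tracks the avoidance-cluster change at POST
        rng = np.random.default_rng(2)
        recs = []
        for i in range(30):
            u = rng.uniform(0.1, 1.0)
            c_post = int(round(8 * u))
            e_post = int(rng.integers(0, 13))
            post_total = 10 + c_post + 14 + e_post
            fup_total = int(round(44 * (0.2 + 0.6 * u)))
            recs.append(ParticipantRecord(
                f"P{i}", Arm.ACTIVE,
                CapsScores(44, 10, 8, 14, 12),
                CapsScores(post_total, 10, c_post, 14, e_post),
                CapsScores(fup_total, *decompose_total(fup_total))))
        mats = association_matrices(Cohort(records=recs), b=200, seed=0)
        c = mats["postcluster_vs_fup_total"].results
        assert c["C"].r > c["E"].r
        assert c["C"].r > 0.8

    def test_results_reproducible_under_fixed_seed(self):
        cohort = generate_planted_cohort(PlantedConfig(n_active=30, n_sham=0,
                                                       seed=6))
        m1 = association_matrices(cohort, b=200, seed=9)
        m2 = association_matrices(cohort, b=200, seed=9)
        for comp in m1:
            for cl in "BCDE":
                r1, r2 = m1[comp].results[cl], m2[comp].results[cl]
                assert (r1.r == r2.r or (math.isnan(r1.r) and math.isnan(r2.r)))
                assert r1.p_bootstrap == r2.p_bootstrap
                assert r1.ci95 == r2.ci95

    def test_model_summary_and_frame(self):
        cohort = generate_planted_cohort(PlantedConfig(n_active=25, n_sham=0,
                                                       seed=1))
        res = ClusterAssociationModel(cohort).fit(b=150, seed=2)
        df = res.to_frame()
        assert len(df) == 12  # 3 comparisons x 4 clusters
        assert "Cluster associations" in res.summary()


class TestShamCounts:
    def test_default_generator_plants_one_deep_responder(self):
        cohort = generate_planted_cohort(PlantedConfig(seed=13))
        counts = sham_threshold_count(cohort, improvement_pct=35.0)
        assert counts.deep_responders == 1
        assert counts.n_sham == 28

    def test_unchanged_sham_arm_counts_zero(self):
        recs = [record(f"S{i}", 40 + i, 40 + i, 40 + i, arm=Arm.SHAM)
                for i in range(5)]
        counts = sham_threshold_count(Cohort(records=recs))
        assert (counts.deep_responders, counts.cluster_c_improved,
                counts.cluster_c_attenuated) == (0, 0, 0)

    def test_zero_percent_threshold_counts_any_improvement(self):
        recs = [record("S1", 40, 39, 40, arm=Arm.SHAM),
                record("S2", 40, 40, 40, arm=Arm.SHAM),
                record("S3", 40, 41, 40, arm=Arm.SHAM)]
        counts = sham_threshold_count(Cohort(records=recs), improvement_pct=0)
        assert counts.deep_responders == 1

    def test_empty_sham_arm_raises(self):
        with pytest.raises(ValueError, match="sham"):
            sham_threshold_count(Cohort(records=[record("P1", 40, 30, 28)]))
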