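"""Normalization, responder curve, permutation null and elbow selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from capselbow.cohort import Arm, Cohort
from capselbow.elbow import (NormalizedOutcome, ThresholdElbowModel,
                             default_grid, elbow_threshold, normalize_cohort,
                             permutation_null, responder_curve)
from capselbow.synthetic import PlantedConfig, generate_planted_cohort

from conftest import record


def outcomes_from(pairs):
    return [NormalizedOutcome(f"P{i}", Arm.ACTIVE, p, f)
            for i, (p, f) in enumerate(pairs)]


TOY = [(0.5, 0.4), (0.6, 0.7), (0.8, 0.7), (0.9, 1.0)]


class TestNormalize:
    def test_ratio_arithmetic_and_improvement_flag(self):
        cohort = Cohort(records=[record("P1", 40, 26, 20)])
        o = normalize_cohort(cohort).outcomes[0]
        assert o.post_ratio == pytest.approx(0.65)
        assert o.fup_ratio == pytest.approx(0.50)
        assert o.improved_at_fup

    def test_unchanged_scores_are_not_improvement(self):
        cohort = Cohort(records=[record("P1", 40, 40, 40)])
        o = normalize_cohort(cohort).outcomes[0]
        assert o.post_ratio == o.fup_ratio == 1.0
        assert not o.improved_at_fup

    def test_zero_baseline_and_missing_timepoints_excluded_with_reason(self):
        cohort = Cohort(records=[record("P1", 0, 10, 10),
                                 record("P2", 40, None, None),
                                 record("P3", 40, 26, 20)])
        norm = normalize_cohort(cohort)
        assert [o.participant_id for o in norm.outcomes] == ["P3"]
        assert dict(norm.excluded) == {"P1": "pre-zero",
                                       "P2": "missing-timepoint"}

    def test_empty_after_filtering_raises(self):
        cohort = Cohort(records=[record("P1", 40, None, None)])
        with pytest.raises(ValueError, match="no records"):
            normalize_cohort(cohort)

    def test_arm_filter(self, two_arm_cohort):
        assert all(o.arm is Arm.SHAM
                   for o in normalize_cohort(two_arm_cohort, "SHAM").outcomes)


class TestResponderCurve:
    def test_four_subject_hand_enumeration(self):
        curve = responder_curve(outcomes_from(TOY),
                                grid=np.array([0.55, 0.65, 0.85, 0.95]),
                                n_min=1)
        # S(0.65) = {0.5, 0.6}: improved flags {True, False} -> f = 0.5
        assert list(curve.n) == [1, 2, 3, 4]
        assert curve.f == pytest.approx([1.0, 0.5, 2 / 3, 0.5])
        assert curve.overall_rate == pytest.approx(0.5)

    def test_all_improved_curve_is_one_where_defined(self):
        outs = outcomes_from([(0.5, 0.3), (0.7, 0.5), (0.9, 0.8)])
        curve = responder_curve(outs, n_min=1)
        defined = curve.defined
        assert np.all(curve.f[defined] == 1.0)

    def test_empty_subgroup_is_undefined(self):
        curve = responder_curve(outcomes_from(TOY), n_min=1)
        assert curve.n[curve.grid <= 0.5][-1] == 0
        assert np.isnan(curve.f[curve.grid <= 0.5]).all()

    @given(st.lists(st.tuples(st.floats(0.05, 1.2), st.floats(0.05, 1.4)),
                    min_size=1, max_size=40))
    def test_monotone_sizes_and_bounded_fractions(self, pairs):
        curve = responder_curve(outcomes_from(pairs), n_min=1)
        assert np.all(np.diff(curve.n) >= 0)
        defined = curve.defined
        assert np.all((curve.f[defined] >= 0) & (curve.f[defined] <= 1))


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed_curve(self):
        outs = outcomes_from(TOY)
        curve = responder_curve(outs, n_min=1)
        null = permutation_null(outs, n_min=1,
                                permutations=[list(range(4))])
        assert np.allclose(null.curves[0], curve.f, equal_nan=True)

    def test_degenerate_equal_fup_values_give_constant_null(self):
        outs = outcomes_from([(0.4, 0.7), (0.6, 0.7), (0.9, 0.7)])
        null = permutation_null(outs, b=20, n_min=1, seed=0)
        for rep in null.curves:
            assert np.allclose(rep, null.curves[0], equal_nan=True)

    def test_mean_null_curve_stable_across_seeds(self):
        cfg = PlantedConfig(n_active=200, n_sham=0, seed=4)
        outs = normalize_cohort(generate_planted_cohort(cfg)).outcomes
        b = 1000
        m1 = permutation_null(outs, b=b, seed=1).mean_curve
        m2 = permutation_null(outs, b=b, seed=2).mean_curve
        defined = ~np.isnan(m1)
        assert np.all(np.abs(m1[defined] - m2[defined]) < 2 / math.sqrt(b))


class TestElbow:
    def test_observed_equal_to_null_mean_gives_zero_distance_and_p_one(self):
        outs = outcomes_from(TOY)
        curve = responder_curve(outs, n_min=1)
        null = permutation_null(outs, n_min=1, permutations=[list(range(4))])
        res = elbow_threshold(curve, null)
        assert res.d_obs == pytest.approx(0.0)
        assert res.p_value == 1.0

    def test_toy_diagonal_conditional_distance_by_hand(self):
        # grid {0.55,0.65,0.85,0.95}; f = {1, 1/2, 2/3, 1/2}; overall rate 1/2
        # conditional D = f - 1/2 = {1/2, 0, 1/6, 0}: argmax at t = 0.55
        outs = outcomes_from(TOY)
        grid = np.array([0.55, 0.65, 0.85, 0.95])
        curve = responder_curve(outs, grid=grid, n_min=1)
        null = permutation_null(outs, grid=grid, n_min=1,
                                permutations=[list(range(4))])
        res = elbow_threshold(curve, null, reference="diagonal",
                              statistic="conditional",
                              diagonal_mode="overall_rate")
        assert np.allclose(res.d_curve, [0.5, 0.0, 1 / 6, 0.0])
        assert res.t_star == 0.55
        assert res.d_obs == pytest.approx(0.5)
        assert res.n_at_t_star == 1

    def test_planted_threshold_recovered(self):
        cfg = PlantedConfig(n_active=200, n_sham=0, theta=0.65,
                            p_sustain_below=0.9, p_sustain_above=0.2, seed=21)
        res = ThresholdElbowModel(generate_planted_cohort(cfg)).fit(
            b=500, seed=21)
        assert abs(res.t_star - 0.65) <= 0.05 + 1e-9
        assert res.p_value < 0.05

    def test_mismatched_grids_rejected(self):
        outs = outcomes_from(TOY)
        curve = responder_curve(outs, grid=np.array([0.5, 0.9]), n_min=1)
        null = permutation_null(outs, b=3, n_min=1, seed=0)
        with pytest.raises(ValueError, match="grid"):
            elbow_threshold(curve, null)

    def test_no_defined_grid_point_is_explicit_error(self):
        outs = outcomes_from([(0.5, 0.4), (0.6, 0.5)])
        grid = np.array([0.1, 0.2])
        curve = responder_curve(outs, grid=grid, n_min=1)
        null = permutation_null(outs, grid=grid, b=3, n_min=1, seed=0)
        with pytest.raises(ValueError, match="no grid point"):
            elbow_threshold(curve, null)

    def test_estimate_invariant_to_order_and_id_relabeling(self):
        outs = outcomes_from([(0.5, 0.3), (0.62, 0.7), (0.71, 0.5),
                              (0.8, 0.9), (0.95, 1.0)])
        perms = list(itertools.permutations(range(5)))

        def fit(outcomes):
            curve = responder_curve(outcomes, n_min=1)
            null = permutation_null(outcomes, n_min=1, permutations=perms)
            return elbow_threshold(curve, null)

        res1 = fit(outs)
        shuffled = [NormalizedOutcome(f"Z{i}", o.arm, o.post_ratio, o.fup_ratio)
                    for i, o in enumerate(reversed(outs))]
        res2 = fit(shuffled)
        assert res1.t_star == res2.t_star
        assert res1.d_obs == pytest.approx(res2.d_obs)
        assert res1.p_value == res2.p_value

    def test_model_summary_reports_headline_numbers(self):
        cfg = PlantedConfig(n_active=60, n_sham=0, seed=5)
        res = ThresholdElbowModel(generate_planted_cohort(cfg)).fit(b=99, seed=5)
        text = res.summary()
        assert f"{res.t_star:.2f}" in text
        assert "permutation p-value" in text
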