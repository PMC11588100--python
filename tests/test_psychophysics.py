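"""d', elbow-fit, bootstrap, permutation and asymptote-matching tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from noiseschema.psychophysics import (
    bootstrap_elbow,
    bootstrap_elbow_matrix,
    compute_dprime,
    delay_benefit,
    dprime_by_onset,
    fit_elbow,
    fit_elbow_batch,
    match_asymptote,
    performance_curve,
    permutation_diff_test,
    permutation_diff_test_matrix,
)
from noiseschema.stimuli import elbow_curve, gen_synthetic_behavior

ONSETS = np.arange(250.0, 2501.0, 250.0)


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert compute_dprime(10, 20, 10, 20) == pytest.approx(0.0)

    def test_inverse_normal_oracle(self):
        expected = norm.ppf(0.75) - norm.ppf(0.25)
        assert compute_dprime(15, 20, 5, 20) == pytest.approx(expected, abs=1e-12)

    def test_perfect_hits_corrected_to_half_rule(self):
        expected = norm.ppf(39 / 40) - norm.ppf(0.25)
        assert compute_dprime(20, 20, 5, 20) == pytest.approx(expected, abs=1e-12)

    def test_loglinear_correction(self):
        expected = norm.ppf(20.5 / 21) - norm.ppf(5.5 / 21)
        assert compute_dprime(20, 20, 5, 20, "loglinear") == pytest.approx(expected)

    def test_antisymmetric_under_swap(self):
        d1 = compute_dprime(17, 20, 4, 20)
        d2 = compute_dprime(4, 20, 17, 20)
        assert d1 == pytest.approx(-d2)

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            compute_dprime(0, 0, 1, 20)


class TestPerformanceCurve:
    def test_identical_participants_zero_se(self):
        tb = gen_synthetic_behavior({-2.0: (1.0, 0.001, 900.0)}, 1, 50, 200, seed=1,
                                    participant_sd=0.0)
        clones = [tb.assign(participant_id=i) for i in range(6)]
        import pandas as pd

        table = pd.concat(clones, ignore_index=True)
        curve = performance_curve(table)
        assert np.allclose(curve.se, 0.0)

    def test_single_participant_flagged(self, caplog):
        tb = gen_synthetic_behavior({-2.0: (1.0, 0.001, 900.0)}, 1, 20, 100, seed=1)
        import logging

        with caplog.at_level(logging.WARNING, logger="noiseschema.psychophysics"):
            curve = performance_curve(tb)
        assert curve.n_participants == 1
        assert any("SE undefined" in r.message for r in caplog.records)

    def test_recovers_generating_curves_per_snr(self):
        params = {-2.0: (1.2, 0.0012, 900.0), -6.0: (0.3, 0.0012, 900.0)}
        tb = gen_synthetic_behavior(params, 150, 12, 200, seed=4)
        curve = performance_curve(tb)
        for g, dp in zip(curve.group_labels, curve.dprime):
            truth = elbow_curve(curve.onsets_ms, *params[g])
            assert np.allclose(dp, truth, atol=0.15)


class TestElbowFit:
    def test_exact_recovery_of_noiseless_elbow(self):
        values = elbow_curve(ONSETS, 1.0, 0.001, 900.0)
        fit = fit_elbow(ONSETS, values)
        assert fit.elbow_ms == pytest.approx(900.0)
        assert fit.a == pytest.approx(1.0, abs=1e-9)
        assert fit.b == pytest.approx(0.001, abs=1e-12)
        assert fit.rss < 1e-18

    def test_constant_values_tie_break_to_smallest_elbow(self):
        fit = fit_elbow(ONSETS, np.full(10, 2.0))
        assert fit.b == pytest.approx(0.0)
        assert fit.elbow_ms == pytest.approx(ONSETS[0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_elbow(ONSETS[:3], np.zeros(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_value_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        y = elbow_curve(ONSETS, 0.5, 0.001, 1100.0) + rng.normal(0, 0.2, 10)
        f0 = fit_elbow(ONSETS, y)
        f1 = fit_elbow(ONSETS, y + shift)
        assert f1.elbow_ms == pytest.approx(f0.elbow_ms)
        assert f1.b == pytest.approx(f0.b, abs=1e-9)
        assert f1.a == pytest.approx(f0.a + shift, abs=1e-7)

    def test_onset_rescaling_rescales_elbow(self):
        y = elbow_curve(ONSETS, 0.5, 0.001, 1000.0)
        f1 = fit_elbow(ONSETS, y, step=5.0)
        f2 = fit_elbow(ONSETS / 2, y, step=2.5)
        assert f2.elbow_ms == pytest.approx(f1.elbow_ms / 2)

    def test_noisy_recovery_median_error_bounded(self):
        errs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            y = elbow_curve(ONSETS, 0.5, 0.0012, 900.0) + rng.normal(0, 0.1, 10)
            errs.append(abs(fit_elbow(ONSETS, y).elbow_ms - 900.0))
        assert np.median(errs) < 150.0


class TestDelayBenefit:
    def test_flat_curve_zero_benefit(self):
        fit = fit_elbow(ONSETS, np.full(10, 1.3))
        assert delay_benefit(fit, 250.0) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        values = elbow_curve(ONSETS, 1.0, 0.001, 900.0)
        fit = fit_elbow(ONSETS, values)
        assert delay_benefit(fit, 250.0) == pytest.approx(0.65, abs=1e-9)


class TestBootstrap:
    def test_zero_between_participant_variance_gives_tiny_ci(self):
        mat = np.tile(elbow_curve(ONSETS, 0.5, 0.001, 900.0), (15, 1))
        b = bootstrap_elbow_matrix(ONSETS, mat, n_boot=100, seed=0)
        assert b.ci_high_ms - b.ci_low_ms < 1e-9

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        mat = elbow_curve(ONSETS, 0.5, 0.001, 900.0) + rng.normal(0, 0.3, (20, 10))
        b1 = bootstrap_elbow_matrix(ONSETS, mat, n_boot=200, seed=11)
        b2 = bootstrap_elbow_matrix(ONSETS, mat, n_boot=200, seed=11)
        assert (b1.ci_low_ms, b1.ci_high_ms) == (b2.ci_low_ms, b2.ci_high_ms)

    def test_table_interface_requires_ten_participants(self):
        tb = gen_synthetic_behavior({-2.0: (1.0, 0.001, 900.0)}, 5, 8, 40, seed=0)
        with pytest.raises(ValueError):
            bootstrap_elbow(tb, n_boot=50)


class TestPermutation:
    def _mat(self, n, benefit_slope, seed):
        rng = np.random.default_rng(seed)
        base = elbow_curve(ONSETS, 0.5, benefit_slope, 900.0)
        return base + rng.normal(0, 0.3, (n, 10))

    def test_large_injected_difference_detected(self):
        a = self._mat(25, 0.0000, 1)
        b = self._mat(25, 0.0016, 2)  # delay benefit ~1.0 d'
        res = permutation_diff_test_matrix(ONSETS, a, b, "delay_benefit",
                                           n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.observed_diff < -0.5

    def test_identical_groups_not_significant(self):
        a = self._mat(20, 0.001, 3)
        b = self._mat(20, 0.001, 4)
        res = permutation_diff_test_matrix(ONSETS, a, b, "elbow_ms",
                                           n_perm=199, seed=0)
        assert res.p_value > 0.05

    def test_zero_permutations_rejected(self):
        a, b = self._mat(5, 0.001, 1), self._mat(5, 0.001, 2)
        with pytest.raises(ValueError):
            permutation_diff_test_matrix(ONSETS, a, b, n_perm=0)

    def test_table_interface_rejects_shared_participants(self):
        tb = gen_synthetic_behavior({-2.0: (1.0, 0.001, 900.0)}, 6, 8, 40, seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            permutation_diff_test(tb, tb, n_perm=10)


class TestMatchAsymptote:
    LATE = (1500.0, 2000.0, 2500.0)

    def test_already_matched_identity(self):
        mat = np.tile(elbow_curve(ONSETS, 0.5, 0.001, 900.0), (8, 1))
        ka, kb, gap = match_asymptote(ONSETS, mat, mat.copy(), self.LATE, tol=0.05)
        assert len(ka) == 8 and len(kb) == 8
        assert abs(gap) < 1e-12

    def test_single_outlier_dropped_first(self):
        base = elbow_curve(ONSETS, 0.5, 0.001, 900.0)
        a = np.tile(base, (8, 1))
        a[3] += 2.0  # dominant high performer in group A
        b = np.tile(base, (8, 1))
        ka, kb, gap = match_asymptote(ONSETS, a, b, self.LATE, tol=0.05)
        assert 3 not in ka and len(ka) == 7
        assert abs(gap) < 0.05

    def test_ceiling_group_equalized_within_tolerance(self):
        rng = np.random.default_rng(0)
        base = elbow_curve(ONSETS, 0.5, 0.001, 900.0)
        a = base + rng.normal(0.6, 0.4, (25, 1))  # inflated group
        b = base + rng.normal(0.0, 0.4, (25, 1))
        ka, kb, gap = match_asymptote(ONSETS, a, b, self.LATE, tol=0.1)
        assert abs(gap) < 0.1

    def test_unreachable_tolerance_reports_gap(self):
        base = elbow_curve(ONSETS, 0.5, 0.001, 900.0)
        a = np.tile(base + 3.0, (3, 1))
        b = np.tile(base, (3, 1))
        with pytest.raises(ValueError, match="achieved gap"):
            match_asymptote(ONSETS, a, b, self.LATE, tol=0.01)


def test_pipeline_recovery_from_trial_tables():
    """End-to-end: synthetic cohort -> participant d' -> elbow near truth."""
    params = {-2.0: (1.0, 0.0012, 900.0), -6.0: (0.2, 0.0012, 900.0)}
    tb = gen_synthetic_behavior(params, 95, 8, 160, seed=9)
    onsets, mat = dprime_by_onset(tb)
    fit = fit_elbow(onsets, mat.mean(axis=0))
    assert abs(fit.elbow_ms - 900.0) < 250.0
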