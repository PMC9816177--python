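"""Circular tuning statistics: selectivity index, Rayleigh test,
preferred angle, sliding windows, tuning classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossadapt import synthetic_data as synth
from crossadapt.tuning import (TuningCurve, UndefinedTuningError,
                               classify_tuning, holm_bonferroni,
                               preferred_angle, rayleigh_significance,
                               selectivity_index, sliding_tuning,
                               evaluate_selectivity)

COLOR_ANGLES = np.arange(16) * 22.5
ORI_ANGLES = np.arange(16) * 11.25


class TestSelectivityIndex:
    def test_uniform_curve_is_untuned(self):
        curve = TuningCurve(COLOR_ANGLES, np.full(16, 10.0))
        assert selectivity_index(curve) == pytest.approx(0.0, abs=1e-12)

    def test_single_response_is_perfectly_tuned(self):
        r = np.zeros(16)
        r[5] = 10.0
        curve = TuningCurve(COLOR_ANGLES, r)
        assert selectivity_index(curve) == pytest.approx(1.0, abs=1e-12)
        assert preferred_angle(curve) == pytest.approx(5 * 22.5)

    def test_matches_direct_formula_evaluation(self):
        # independent arithmetic oracle: evaluate the vector-sum formula
        # directly on a kappa=2 von Mises curve sampled at 16 angles
        kappa, mu = 2.0, 78.3
        r = 5.0 + 20.0 * np.exp(kappa * (np.cos(np.radians(COLOR_ANGLES - mu))
                                         - 1.0))
        expected = abs(np.sum(r * np.exp(1j * np.radians(COLOR_ANGLES)))) \
            / np.sum(r)
        curve = TuningCurve(COLOR_ANGLES, r)
        assert selectivity_index(curve) == pytest.approx(expected, abs=1e-12)

    def test_orientation_uses_doubled_angles(self):
        # two equal responses 90 deg apart cancel on the doubled circle
        r = np.zeros(16)
        r[0] = r[8] = 10.0   # 0 and 90 deg in orientation space
        curve = TuningCurve(ORI_ANGLES, r, period=180)
        assert selectivity_index(curve) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_and_baseline_penalty(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(1.0, 20.0, size=16)
        c = TuningCurve(COLOR_ANGLES, r)
        c_scaled = TuningCurve(COLOR_ANGLES, 3.7 * r)
        c_base = TuningCurve(COLOR_ANGLES, r + 5.0)
        assert selectivity_index(c_scaled) == pytest.approx(
            selectivity_index(c), rel=1e-12)
        assert selectivity_index(c_base) < selectivity_index(c)

    def test_all_zero_responses_raise(self):
        curve = TuningCurve(COLOR_ANGLES, np.zeros(16))
        with pytest.raises(UndefinedTuningError):
            selectivity_index(curve)
        with pytest.raises(UndefinedTuningError):
            preferred_angle(curve)


class TestPreferredAngle:
    def test_noiseless_von_mises_recovers_mean(self):
        mu = 90.0
        r = 2.0 + 10.0 * np.exp(1.5 * (np.cos(
            2 * np.radians(ORI_ANGLES - mu)) - 1.0))
        curve = TuningCurve(ORI_ANGLES, r, period=180)
        assert preferred_angle(curve) == pytest.approx(mu, abs=1e-9)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(1.0, 10.0, 16)
        base = preferred_angle(TuningCurve(COLOR_ANGLES, r))
        shifted = preferred_angle(TuningCurve(COLOR_ANGLES, np.roll(r, 1)))
        assert (shifted - base) % 360 == pytest.approx(22.5, abs=1e-9)


class TestRayleigh:
    def test_strongly_tuned_neuron_is_significant(self):
        cfg = synth.PopulationConfig(seed=5, n_neurons=5,
                                     tuning_concentration=4.0,
                                     fraction_untuned=0.0,
                                     n_trials_per_stimulus=30)
        table, _, _ = synth.generate_population(cfg)
        for k in range(5):
            p = rayleigh_significance(table.stimulus_angle, table.counts[:, k])
            assert p < 1e-6

    def test_uniform_noiseless_curve_not_significant(self):
        angles = np.repeat(COLOR_ANGLES, 3)
        counts = np.full(len(angles), 7.0)
        assert rayleigh_significance(angles, counts) > 0.9

    def test_type_i_error_calibrated(self):
        # Monte-Carlo under the null: untuned neurons from the generator
        cfg = synth.PopulationConfig(seed=11, n_neurons=400,
                                     fraction_untuned=1.0)
        table, _, _ = synth.generate_population(cfg)
        ps = np.array([rayleigh_significance(table.stimulus_angle,
                                             table.counts[:, k])
                       for k in range(cfg.n_neurons)])
        rate = (ps < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / cfg.n_neurons)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_matches_pingouin_on_binned_weights(self):
        pingouin = pytest.importorskip("pingouin")
        from crossadapt._circ import rayleigh_p
        rng = np.random.default_rng(2)
        w = rng.uniform(0.0, 5.0, 36)
        ang = np.radians(np.arange(36) * 10.0)
        z, p_ref = pingouin.circ_rayleigh(ang, w=w, d=np.radians(10.0))
        assert rayleigh_p(ang, w, d=np.radians(10.0)) == pytest.approx(
            p_ref, rel=1e-9)

    def test_single_angle_undefined(self):
        with pytest.raises(UndefinedTuningError):
            rayleigh_significance(np.zeros(10), np.ones(10))


def brute_force_holm(p, alpha=0.05):
    """Literal step-down procedure, as an independent oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


class TestHolmBonferroni:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_brute_force_step_down(self, pvals):
        p = np.array(pvals)
        assert np.array_equal(holm_bonferroni(p), brute_force_holm(p))

    def test_many_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            assert np.array_equal(holm_bonferroni(p), brute_force_holm(p))


class TestSlidingTuning:
    def test_stationary_tuning_has_first_window_latency(self):
        cfg = synth.PopulationConfig(seed=6, n_neurons=3,
                                     tuning_concentration=3.0,
                                     fraction_untuned=0.0,
                                     response_latency_ms=0.0,
                                     n_trials_per_stimulus=30)
        bu, _, bin_starts, angles, _ = synth.generate_population_timecourse(
            cfg, epoch_ms=(0.0, 400.0))
        tc = sliding_tuning(bu[:, 0, :], bin_starts, angles)
        assert tc.tuning_latency_ms == bin_starts[0]
        assert np.nanstd(tc.csi) < 0.1   # flat CSI timecourse

    def test_latency_shift_recovered(self):
        # sharp responses with onset well inside the window grid, so the
        # first significant window tracks onset instead of being clamped
        # at the epoch edge or blurred by borderline windows
        cfg = synth.PopulationConfig(seed=8, n_neurons=12,
                                     tuning_concentration=4.0,
                                     tuning_amplitude=80.0,
                                     fraction_untuned=0.0,
                                     n_trials_per_stimulus=40,
                                     response_latency_ms=150.0,
                                     latency_shift_ms=20.0)
        bu, ba, bin_starts, angles, _ = synth.generate_population_timecourse(
            cfg)
        deltas = []
        for k in range(cfg.n_neurons):
            tu = sliding_tuning(bu[:, k, :], bin_starts, angles)
            ta = sliding_tuning(ba[:, k, :], bin_starts, angles)
            assert tu.tuning_latency_ms is not None
            assert ta.tuning_latency_ms is not None
            deltas.append(ta.tuning_latency_ms - tu.tuning_latency_ms)
        assert np.mean(deltas) == pytest.approx(20.0, abs=5.0)

    def test_untuned_neuron_rarely_reaches_significance(self):
        cfg = synth.PopulationConfig(seed=9, n_neurons=40,
                                     fraction_untuned=1.0,
                                     n_trials_per_stimulus=20)
        bu, _, bin_starts, angles, _ = synth.generate_population_timecourse(
            cfg, epoch_ms=(0.0, 300.0))
        latencies = [sliding_tuning(bu[:, k, :], bin_starts,
                                    angles).tuning_latency_ms
                     for k in range(cfg.n_neurons)]
        assert np.mean([lat is None for lat in latencies]) >= 0.95

    def test_window_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            sliding_tuning(np.zeros((4, 10)), np.arange(10) * 5.0,
                           np.zeros(4), window_ms=500.0)


class TestClassifyTuning:
    def _result(self, significant, peak):
        from crossadapt.tuning import SelectivityResult
        return SelectivityResult(csi=0.2, p_value=0.01 if significant else 0.5,
                                 preferred_angle=0.0, significant=significant,
                                 peak_rate=peak)

    def test_class_assignment(self):
        both = classify_tuning(self._result(True, 20), self._result(True, 20))
        assert both == "both"
        assert classify_tuning(self._result(True, 20),
                               self._result(False, 20)) == "color-only"
        assert classify_tuning(self._result(False, 20),
                               self._result(True, 20)) == "orientation-only"
        assert classify_tuning(self._result(False, 20),
                               self._result(False, 20)) == "neither"

    def test_low_peak_rate_excluded(self):
        assert classify_tuning(self._result(True, 8.0), None) == "excluded"

    def test_untuned_population_mostly_neither(self):
        cfg = synth.PopulationConfig(seed=13, n_neurons=200,
                                     fraction_untuned=1.0)
        table, _, _ = synth.generate_population(cfg)
        classes = [classify_tuning(evaluate_selectivity(table, k), None)
                   for k in range(cfg.n_neurons)]
        frac_neither = np.mean([c == "neither" for c in classes])
        assert frac_neither >= 0.9   # ~(1 - alpha) expected


def test_population_delta_csi_positive_under_kappa_boost():
    """Sharpened adapted tuning shows up as a positive mean CSI change."""
    deltas = []
    for seed in range(3):
        cfg = synth.PopulationConfig(seed=seed, n_neurons=25,
                                     adapt_kappa_boost=0.5,
                                     fraction_untuned=0.0)
        unadapt, adapt, _ = synth.generate_population(cfg)
        for k in range(cfg.n_neurons):
            du = evaluate_selectivity(unadapt, k).csi
            da = evaluate_selectivity(adapt, k).csi
            deltas.append(da - du)
    assert np.mean(deltas) > 0
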