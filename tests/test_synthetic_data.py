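"""Generators: determinism, configured ground truth, and the statistical
contracts downstream analyses rely on."""

import numpy as np
import pytest

from crossadapt import synthetic_data as synth
from crossadapt.eye_events import detect_fixations, eye_speed
from crossadapt.image_features import classify_patch, feature_map, patch_osi
from crossadapt.tuning import TuningCurve, preferred_angle


class TestPopulationConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.PopulationConfig(n_neurons=0)
        with pytest.raises(synth.ConfigurationError):
            synth.PopulationConfig(n_trials_per_stimulus=-1)
        with pytest.raises(synth.ConfigurationError):
            synth.PopulationConfig(adapt_shared_shrink=0.0)
        with pytest.raises(synth.ConfigurationError):
            synth.PopulationConfig(adapt_shared_shrink=1.5)
        with pytest.raises(synth.ConfigurationError):
            synth.PopulationConfig(stimulus_angles=np.array([0.0, 10.0, 15.0]))


class TestGeneratePopulation:
    def test_deterministic_under_seed(self):
        cfg = synth.PopulationConfig(seed=99, n_neurons=5,
                                     n_trials_per_stimulus=4)
        u1, a1, g1 = synth.generate_population(cfg)
        u2, a2, g2 = synth.generate_population(cfg)
        assert np.array_equal(u1.counts, u2.counts)
        assert np.array_equal(a1.counts, a2.counts)
        assert np.array_equal(g1.loadings, g2.loadings)

    def test_counts_are_nonnegative_integers_with_equal_trials(self):
        cfg = synth.PopulationConfig(seed=1, n_neurons=8,
                                     n_trials_per_stimulus=7)
        u, a, _ = synth.generate_population(cfg)
        for t in (u, a):
            assert t.counts.dtype.kind == "i"
            assert (t.counts >= 0).all()
            _, counts = np.unique(t.stimulus_angle, return_counts=True)
            assert (counts == 7).all()

    def test_null_adaptation_is_distributionally_identical(self):
        """With all adaptation knobs at identity, the two conditions come
        from one distribution: matched means and covariance scale."""
        cfg = synth.PopulationConfig(seed=2, n_neurons=10,
                                     n_trials_per_stimulus=300,
                                     adapt_gain=1.0, adapt_shared_shrink=1.0,
                                     adapt_kappa_boost=0.0)
        u, a, _ = synth.generate_population(cfg)
        mu_u, mu_a = u.rates().mean(axis=0), a.rates().mean(axis=0)
        se = u.rates().std(axis=0) / np.sqrt(u.n_trials)
        assert np.all(np.abs(mu_u - mu_a) < 5 * se)
        assert np.trace(np.cov(a.rates().T)) == pytest.approx(
            np.trace(np.cov(u.rates().T)), rel=0.1)

    def test_per_neuron_adaptation_parameters(self):
        """Gain and kappa boost accept per-neuron arrays; neurons with
        identity parameters keep their unadapted expected curves."""
        boost = np.array([0.0, 0.0, 1.0, 1.0])
        cfg = synth.PopulationConfig(seed=17, n_neurons=4,
                                     fraction_untuned=0.0,
                                     adapt_kappa_boost=boost)
        _, _, gt = synth.generate_population(cfg)
        ru = gt.mean_rates(cfg.stimulus_angles, adapted=False)
        ra = gt.mean_rates(cfg.stimulus_angles, adapted=True)
        assert np.allclose(ru[:, :2], ra[:, :2])
        assert not np.allclose(ru[:, 2:], ra[:, 2:])

    def test_untuned_limit_gives_flat_expected_curves(self):
        cfg = synth.PopulationConfig(seed=3, n_neurons=4, fraction_untuned=1.0)
        _, _, gt = synth.generate_population(cfg)
        rates = gt.mean_rates(cfg.stimulus_angles, adapted=False)
        assert np.allclose(rates, rates[0], atol=1e-12)

    def test_covariance_contract_at_large_n(self):
        """Empirical trial covariance converges to the configured
        loadings.loadings^T + diagonal form (5% Frobenius at n=10,000)."""
        cfg = synth.PopulationConfig(
            seed=4, n_neurons=10, n_trials_per_stimulus=625,  # 10,000 trials
            baseline_rate=200.0, tuning_amplitude=0.0, fraction_untuned=1.0,
            shared_dims=2, shared_sd=15.0, private_sd=10.0,
            window_ms=(0.0, 1000.0))
        u, _, gt = synth.generate_population(cfg)
        emp = np.cov(u.rates().T)
        target = gt.rate_covariance(adapted=False)
        rel = np.linalg.norm(emp - target) / np.linalg.norm(target)
        assert rel < 0.05

    def test_top_eigenvalue_ratio_matches_closed_form(self):
        """One dominant shared dim with sd halved under adaptation: the
        leading-eigenvalue ratio follows from the closed-form covariance
        (loadings have unit norm, so top eigenvalue = shared_sd^2 +
        private_sd^2 -> ratio (4+1)/(1+1) = 2.5)."""
        cfg = synth.PopulationConfig(
            seed=5, n_neurons=12, n_trials_per_stimulus=500,
            baseline_rate=300.0, tuning_amplitude=0.0, fraction_untuned=1.0,
            shared_dims=1, shared_sd=2.0, private_sd=1.0,
            adapt_shared_shrink=0.5, window_ms=(0.0, 1000.0))
        u, a, gt = synth.generate_population(cfg)
        expected = 2.5
        cov_ratio = (np.linalg.eigvalsh(gt.rate_covariance(False))[-1]
                     / np.linalg.eigvalsh(gt.rate_covariance(True))[-1])
        assert cov_ratio == pytest.approx(expected, abs=1e-12)
        top_u = np.linalg.eigvalsh(np.cov(u.rates().T))[-1]
        top_a = np.linalg.eigvalsh(np.cov(a.rates().T))[-1]
        assert top_u / top_a == pytest.approx(expected, rel=0.15)

    def test_preferred_angle_recovery(self):
        """Fitting the preferred angle on generated tuning (kappa >= 1,
        >= 30 trials/stimulus) recovers mu within half a stimulus step
        for >= 95% of neurons."""
        cfg = synth.PopulationConfig(seed=6, n_neurons=100,
                                     n_trials_per_stimulus=30,
                                     tuning_concentration=1.5,
                                     fraction_untuned=0.0)
        u, _, gt = synth.generate_population(cfg)
        half_step = 22.5 / 2
        hits = 0
        for k in range(cfg.n_neurons):
            curve = TuningCurve.from_trial_table(u, k)
            est = preferred_angle(curve)
            err = abs((est - gt.preferred_angle[k] + 180) % 360 - 180)
            hits += err <= half_step
        assert hits / cfg.n_neurons >= 0.95


class TestGenerateScene:
    def test_empty_scene_is_all_neither(self):
        cfg = synth.SceneConfig(image_size=(100, 100), n_oriented_patches=0,
                                n_colored_patches=0, background="gray",
                                seed=0)
        image, patches = synth.generate_scene(cfg)
        assert patches == []
        labels = {f.label for f in feature_map(image, 50, 25)}
        assert labels == {"neither"}

    def test_grating_patch_orientation_recovered(self):
        for ori in (0.0, 45.0, 90.0, 135.0):
            g = synth.grating_patch(50, ori, 12.0, 80.0)
            feat = patch_osi(g.astype(float))
            err = abs((feat.mean_orientation - ori + 90) % 180 - 90)
            assert err <= 5.0, ori

    def test_uniform_red_patch_is_colored(self):
        patch = np.full((50, 50, 3), (200, 40, 40), dtype=np.uint8)
        assert classify_patch(patch).label == "colored"

    def test_patches_do_not_overlap_and_fit(self):
        cfg = synth.SceneConfig(image_size=(300, 300), patch_size=50,
                                n_oriented_patches=3, n_colored_patches=3,
                                seed=8)
        image, patches = synth.generate_scene(cfg)
        h, w = cfg.image_size
        for p in patches:
            assert 0 <= p.row <= h - p.size and 0 <= p.col <= w - p.size
        for i, p in enumerate(patches):
            for q in patches[i + 1:]:
                assert abs(p.row - q.row) >= 50 or abs(p.col - q.col) >= 50

    def test_impossible_placement_raises(self):
        with pytest.raises(synth.PlacementError):
            # three 50-px patches cannot coexist on 60x60
            synth.generate_scene(synth.SceneConfig(
                image_size=(60, 60), patch_size=50, n_oriented_patches=2,
                n_colored_patches=1, seed=0))

    def test_deterministic_under_seed(self):
        cfg = synth.SceneConfig(seed=11)
        img1, _ = synth.generate_scene(cfg)
        img2, _ = synth.generate_scene(cfg)
        assert np.array_equal(img1, img2)


class TestGenerateEyeTrace:
    def test_too_short_duration_rejected(self):
        with pytest.raises(synth.ConfigurationError):
            synth.EyeTraceConfig(duration_s=0.05)

    def test_velocity_invariants(self):
        """Saccadic peaks exceed 100 deg/s; within-fixation speed stays
        below it (including microsaccades)."""
        cfg = synth.EyeTraceConfig(duration_s=20.0, seed=21,
                                   microsaccade_rate_hz=1.0)
        trace, truth = synth.generate_eye_trace(cfg)
        speed = eye_speed(trace)
        for f in truth:
            seg = slice(int(f.onset_ms) + 2, int(f.offset_ms) - 2)
            assert speed[seg].max() < 100.0
        for a, b in zip(truth[:-1], truth[1:]):
            gap = slice(int(a.offset_ms), int(b.onset_ms))
            if gap.stop > gap.start:
                assert speed[gap].max() > 100.0

    def test_noiseless_trace_recovered_exactly_on_grid(self):
        cfg = synth.EyeTraceConfig(duration_s=10.0, seed=1, drift_sd_deg=0.0,
                                   microsaccade_rate_hz=0.0)
        trace, truth = synth.generate_eye_trace(cfg)
        fixations = detect_fixations(trace, layout=cfg.layout)
        assert len(fixations) == len(truth)
        for f, t in zip(fixations, truth):
            assert abs(f.onset_ms - t.onset_ms) <= 5.0
            assert abs(f.offset_ms - t.offset_ms) <= 5.0
            assert f.quadrant == t.quadrant

    def test_fixation_count_recovered(self):
        cfg = synth.EyeTraceConfig(duration_s=40.0, seed=22)
        trace, truth = synth.generate_eye_trace(cfg)
        fixations = detect_fixations(trace, layout=cfg.layout)
        assert len(fixations) == len(truth)

    def test_deterministic_under_seed(self):
        cfg = synth.EyeTraceConfig(duration_s=5.0, seed=33)
        t1, _ = synth.generate_eye_trace(cfg)
        t2, _ = synth.generate_eye_trace(cfg)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.pupil,
                                                             t2.pupil)


def test_freeview_session_conditions_follow_fixation_history():
    pop_cfg = synth.PopulationConfig(seed=0, n_neurons=5)
    eye_cfg = synth.EyeTraceConfig(
        duration_s=8.0, seed=0, quadrant_sequence=(
            "gray", "test1", "adapter", "test2", "test1"))
    session = synth.generate_freeview_session(pop_cfg, eye_cfg)
    conds = [session.conditions[(f.onset_ms, f.offset_ms)]
             for f in session.truth]
    expected = {"gray": None}
    seq = [t.quadrant for t in session.truth]
    for k, q in enumerate(seq):
        if q in ("test1", "test2") and k > 0:
            if seq[k - 1] == "gray":
                assert conds[k] == "unadapt"
            elif seq[k - 1] == "adapter":
                assert conds[k] == "adapt"
            else:
                assert conds[k] is None
        else:
            assert conds[k] is None
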