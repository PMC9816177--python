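import pytest

from crossadapt import synthetic_data as synth


@pytest.fixture(scope="session")
def tuned_population():
    """A moderately tuned population with no adaptation effects."""
    cfg = synth.PopulationConfig(seed=42, n_neurons=20,
                                 n_trials_per_stimulus=30,
                                 fraction_untuned=0.0)
    unadapt, adapt, gt = synth.generate_population(cfg)
    return cfg, unadapt, adapt, gt


@pytest.fixture(scope="session")
def scene_with_truth():
    """A 200x200 scene with one large grating and one color patch, big
    enough for sliding windows to fall fully inside each patch."""
    cfg = synth.SceneConfig(image_size=(200, 200), patch_size=80,
                            n_oriented_patches=1, n_colored_patches=1,
                            seed=7)
    image, patches = synth.generate_scene(cfg)
    return cfg, image, patches


@pytest.fixture(scope="session")
def clean_eye_session():
    """A drift-free, microsaccade-free eye trace with ground truth."""
    cfg = synth.EyeTraceConfig(duration_s=30.0, seed=3, drift_sd_deg=0.0,
                               microsaccade_rate_hz=0.0)
    trace, truth = synth.generate_eye_trace(cfg)
    return cfg, trace, truth
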