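"""Synthetic recordings, scenes and eye traces with known ground truth.

Everything the analysis pipeline consumes can be generated here:

* tuned spiking populations (von Mises tuning on a color or orientation
  circle, a low-dimensional shared-variability structure, and
  controllable adaptation effects: a rate gain, tuning sharpening,
  reduced shared variability and a tuning-latency shift),
* patch-structured surrogate scenes (achromatic gratings and uniform
  color fields on a gray or pink-noise background),
* free-viewing eye traces over a four-quadrant display with
  minimum-jerk saccades, fixational drift, microsaccades and a pupil
  series.

Each generator records its ground truth so parameter-recovery tests
can compare estimates against the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .eye_events import EyeTrace, QuadrantLayout
from .trials import ADAPT, UNADAPT, TrialTable


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


def color_angles() -> np.ndarray:
    """16 hue angles in 22.5 degree steps over [0, 360)."""
    return np.arange(16) * 22.5


def orientation_angles() -> np.ndarray:
    """16 grating orientations in 11.25 degree steps over [0, 180)."""
    return np.arange(16) * 11.25


# --------------------------------------------------------------------------
# tuned populations
# --------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Parameters of a synthetic tuned population.

    Rates are in spikes/s; spike counts are taken over ``window_ms``.
    Adaptation acts through three knobs mirroring the observed effect
    directions: ``adapt_gain`` scales mean rates (a value slightly
    below 1 reproduces the small rate decrease), ``adapt_kappa_boost``
    sharpens tuning, and ``adapt_shared_shrink`` multiplies the shared
    latent s.d. (values below 1 decorrelate the population).
    """

    n_neurons: int = 30
    n_trials_per_stimulus: int = 28       # 16 stimuli -> ~450 trials/condition
    stimulus_angles: np.ndarray = field(default_factory=color_angles)
    period: int = 360
    baseline_rate: float = 10.0
    tuning_amplitude: float = 20.0
    tuning_concentration: float = 1.5
    fraction_untuned: float = 0.3
    shared_dims: int = 3
    shared_sd: float = 15.0
    private_sd: float = 10.0
    # adapt_gain and adapt_kappa_boost may be scalars or per-neuron
    # arrays; single-cell adaptation outcomes are heterogeneous and no
    # canonical distribution over them exists, so it stays configurable
    adapt_gain: float | np.ndarray = 1.0
    adapt_shared_shrink: float = 1.0
    adapt_kappa_boost: float | np.ndarray = 0.0
    latency_shift_ms: float = 0.0
    response_latency_ms: float = 50.0
    window_ms: tuple[float, float] = (0.0, 200.0)
    seed: int = 0

    def __post_init__(self):
        self.stimulus_angles = np.asarray(self.stimulus_angles, dtype=float)
        if self.n_neurons <= 0 or self.n_trials_per_stimulus <= 0:
            raise ConfigurationError("neuron and trial counts must be positive")
        if not 0 < self.adapt_shared_shrink <= 1:
            raise ConfigurationError("adapt_shared_shrink must lie in (0, 1]")
        if self.shared_sd < 0 or self.private_sd < 0:
            raise ConfigurationError("noise s.d. must be non-negative")
        if self.tuning_concentration < 0 \
                or np.any(np.asarray(self.adapt_kappa_boost) < 0):
            raise ConfigurationError("concentration parameters must be >= 0")
        if not 0 <= self.fraction_untuned <= 1:
            raise ConfigurationError("fraction_untuned must lie in [0, 1]")
        if self.latency_shift_ms < 0:
            raise ConfigurationError("latency_shift_ms must be >= 0")
        steps = np.diff(self.stimulus_angles)
        if len(self.stimulus_angles) < 2 or np.any(steps <= 0) \
                or not np.allclose(steps, steps[0]):
            raise ConfigurationError(
                "stimulus angles must be strictly increasing, equally spaced")
        if self.period not in (180, 360):
            raise ConfigurationError("period must be 180 or 360")

    @property
    def feature(self) -> str:
        return "color" if self.period == 360 else "orientation"

    @property
    def angle_multiplier(self) -> int:
        """1 for a 360-degree (color) space, 2 for 180-degree orientation."""
        return 360 // self.period


@dataclass
class PopulationGroundTruth:
    kappa: np.ndarray              # per-neuron concentration, unadapted
    preferred_angle: np.ndarray    # per-neuron mu_i in degrees
    untuned: np.ndarray            # boolean mask (kappa forced to 0)
    gain: np.ndarray               # per-neuron adapted gain
    kappa_boost: np.ndarray        # per-neuron adapted kappa increment
    loadings: np.ndarray           # (n_neurons, shared_dims), unit columns
    shared_sd: float
    private_sd: float
    config: PopulationConfig

    def mean_rates(self, angles_deg: np.ndarray,
                   adapted: bool) -> np.ndarray:
        """Expected rate (spikes/s), shape (len(angles), n_neurons)."""
        cfg = self.config
        kappa = self.kappa + (self.kappa_boost if adapted else 0.0)
        p = cfg.angle_multiplier
        dtheta = np.radians(p * (np.asarray(angles_deg, float)[:, None]
                                 - self.preferred_angle[None, :]))
        tuned = np.exp(kappa[None, :] * (np.cos(dtheta) - 1.0))
        rates = cfg.baseline_rate + cfg.tuning_amplitude * tuned
        if adapted:
            rates = rates * self.gain[None, :]
        return rates

    def rate_covariance(self, adapted: bool) -> np.ndarray:
        """Closed-form trial covariance of rates in (spikes/s)^2."""
        sd = self.shared_sd * (self.config.adapt_shared_shrink
                               if adapted else 1.0)
        shared = sd ** 2 * (self.loadings @ self.loadings.T)
        return shared + self.private_sd ** 2 * np.eye(len(self.kappa))


def _draw_ground_truth(cfg: PopulationConfig,
                       rng: np.random.Generator) -> PopulationGroundTruth:
    kappa = np.full(cfg.n_neurons, cfg.tuning_concentration)
    untuned = rng.random(cfg.n_neurons) < cfg.fraction_untuned
    kappa[untuned] = 0.0
    preferred = rng.uniform(0, cfg.period, size=cfg.n_neurons)
    loadings = rng.standard_normal((cfg.n_neurons, cfg.shared_dims))
    loadings /= np.linalg.norm(loadings, axis=0, keepdims=True)
    gain = np.broadcast_to(np.asarray(cfg.adapt_gain, float),
                           (cfg.n_neurons,)).copy()
    boost = np.broadcast_to(np.asarray(cfg.adapt_kappa_boost, float),
                            (cfg.n_neurons,)).copy()
    return PopulationGroundTruth(
        kappa=kappa, preferred_angle=preferred, untuned=untuned,
        gain=gain, kappa_boost=boost,
        loadings=loadings, shared_sd=cfg.shared_sd,
        private_sd=cfg.private_sd, config=cfg)


def _counts_from_rates(rates: np.ndarray, window_s: float) -> np.ndarray:
    """Integerize rates into window spike counts, truncated at zero."""
    return np.rint(np.clip(rates, 0.0, None) * window_s).astype(np.int64)


def _condition_counts(gt: PopulationGroundTruth, adapted: bool,
                      rng: np.random.Generator) -> TrialTable:
    cfg = gt.config
    angles = np.repeat(cfg.stimulus_angles, cfg.n_trials_per_stimulus)
    order = rng.permutation(len(angles))   # interleave stimulus order
    angles = angles[order]
    means = gt.mean_rates(angles, adapted)
    sd = cfg.shared_sd * (cfg.adapt_shared_shrink if adapted else 1.0)
    latents = rng.standard_normal((len(angles), cfg.shared_dims)) * sd
    private = rng.standard_normal(means.shape) * cfg.private_sd
    rates = means + latents @ gt.loadings.T + private
    counts = _counts_from_rates(rates, (cfg.window_ms[1]
                                        - cfg.window_ms[0]) / 1000.0)
    cond = ADAPT if adapted else UNADAPT
    return TrialTable(counts=counts,
                      condition=np.full(len(angles), cond, dtype=object),
                      stimulus_angle=angles, period=cfg.period,
                      window_ms=cfg.window_ms, feature=cfg.feature,
                      seed=cfg.seed)


def generate_population(cfg: PopulationConfig
                        ) -> tuple[TrialTable, TrialTable,
                                   PopulationGroundTruth]:
    """Spike-count tables for the unadapted and adapted conditions.

    Per-trial rates are the von Mises tuning mean plus a shared
    low-dimensional latent fluctuation and private noise; counts are
    the rates integerized over the analysis window and truncated at
    zero. Both conditions have equal trial counts per stimulus.
    """
    rng = np.random.default_rng(cfg.seed)
    gt = _draw_ground_truth(cfg, rng)
    unadapt = _condition_counts(gt, adapted=False, rng=rng)
    adapt = _condition_counts(gt, adapted=True, rng=rng)
    return unadapt, adapt, gt


def generate_population_timecourse(
        cfg: PopulationConfig, epoch_ms: tuple[float, float] = (-100.0, 400.0),
        bin_ms: float = 5.0):
    """Time-resolved counts for tuning-latency analyses.

    Returns ``(binned_unadapt, binned_adapt, bin_starts_ms, angles, gt)``
    where each binned array has shape (n_trials, n_neurons, n_bins) of
    Poisson counts. The tuned response component switches on at
    ``response_latency_ms`` after stimulus onset, delayed by a further
    ``latency_shift_ms`` in the adapted condition.
    """
    rng = np.random.default_rng(cfg.seed)
    gt = _draw_ground_truth(cfg, rng)
    bin_starts = np.arange(epoch_ms[0], epoch_ms[1], bin_ms)
    angles = np.repeat(cfg.stimulus_angles, cfg.n_trials_per_stimulus)
    out = []
    for adapted in (False, True):
        onset = cfg.response_latency_ms + (cfg.latency_shift_ms
                                           if adapted else 0.0)
        driven = gt.mean_rates(angles, adapted)      # (trials, neurons)
        rate_t = np.where((bin_starts + bin_ms)[None, None, :] <= onset,
                          cfg.baseline_rate,
                          driven[:, :, None])
        out.append(rng.poisson(rate_t * bin_ms / 1000.0))
    return out[0], out[1], bin_starts, angles, gt


def adaptation_effect_config(seed: int = 0, **overrides) -> PopulationConfig:
    """Population config carrying the canonical adaptation effects.

    The three knobs mirror the reported effect directions: a small mean
    rate decrease (gain 0.967, i.e. -3.3%), a modest tuning sharpening
    (kappa boost 0.5 on a base concentration of 1.5), and reduced shared
    variability (latent s.d. multiplied by 0.7).
    """
    params = dict(adapt_gain=0.967, adapt_kappa_boost=0.5,
                  adapt_shared_shrink=0.7, seed=seed)
    params.update(overrides)
    return PopulationConfig(**params)


# --------------------------------------------------------------------------
# surrogate scenes
# --------------------------------------------------------------------------

@dataclass
class ScenePatch:
    """Ground-truth record of one generated patch."""

    label: str                  # 'oriented' | 'colored'
    row: int
    col: int
    size: int
    orientation_deg: float | None = None
    rgb: tuple[int, int, int] | None = None


DEFAULT_HUES = ((200, 60, 60), (60, 180, 90), (70, 90, 200), (200, 160, 60))


@dataclass
class SceneConfig:
    image_size: tuple[int, int] = (200, 200)
    patch_size: int = 50
    n_oriented_patches: int = 1
    n_colored_patches: int = 1
    grating_spatial_period: float = 12.0
    grating_orientations: tuple = (0.0, 45.0, 90.0, 135.0)
    grating_contrast: float = 80.0
    patch_hues: tuple = DEFAULT_HUES
    background: str = "gray"
    background_gray: int = 128
    max_placement_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if self.patch_size > min(h, w):
            raise ConfigurationError("patches must fit inside the image")
        if self.n_oriented_patches < 0 or self.n_colored_patches < 0:
            raise ConfigurationError("patch counts must be non-negative")
        if self.background not in ("gray", "pink-noise"):
            raise ConfigurationError("background must be gray or pink-noise")


def grating_patch(size: int, orientation_deg: float, period: float,
                  contrast: float, mean: float = 128.0) -> np.ndarray:
    """Achromatic sinusoidal grating whose stripes lie at the given
    orientation (0 = horizontal stripes, 90 = vertical)."""
    rows, cols = np.mgrid[0:size, 0:size]
    th = np.radians(orientation_deg)
    # stripes constant along (cos th, sin th) in display coords (y up):
    # the phase advances along the normal, which in (row, col) array
    # coordinates is -(col sin th + row cos th).
    phase = -2 * np.pi / period * (cols * np.sin(th) + rows * np.cos(th))
    g = mean + contrast * np.sin(phase)
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)


def _pink_noise(shape: tuple[int, int], rng: np.random.Generator,
                amplitude: float = 12.0, mean: float = 128.0) -> np.ndarray:
    """Achromatic 1/f noise field scaled to +-3 s.d. ~ amplitude."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spec = np.fft.fft2(white) / f
    field = np.real(np.fft.ifft2(spec))
    field = field / field.std() * (amplitude / 3.0)
    return np.clip(np.rint(mean + field), 0, 255).astype(np.uint8)


def generate_scene(cfg: SceneConfig) -> tuple[np.ndarray, list[ScenePatch]]:
    """RGB scene with non-overlapping grating and uniform color patches.

    Returns the (H, W, 3) uint8 image and per-patch ground truth.
    Raises PlacementError when non-overlapping positions cannot be
    found within the configured number of retries.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    if cfg.background == "gray":
        img = np.full((h, w, 3), cfg.background_gray, dtype=np.uint8)
    else:
        img = np.repeat(_pink_noise((h, w), rng)[:, :, None], 3, axis=2)
    s = cfg.patch_size
    n_patches = cfg.n_oriented_patches + cfg.n_colored_patches

    def try_layout() -> list[tuple[int, int]] | None:
        spots: list[tuple[int, int]] = []
        for _ in range(n_patches):
            for _ in range(cfg.max_placement_retries):
                r = int(rng.integers(0, h - s + 1))
                c = int(rng.integers(0, w - s + 1))
                if all(abs(r - pr) >= s or abs(c - pc) >= s
                       for pr, pc in spots):
                    spots.append((r, c))
                    break
            else:
                return None   # dead end (e.g. first patch placed centrally)
        return spots

    spots = None
    for _ in range(cfg.max_placement_retries):
        spots = try_layout()
        if spots is not None:
            break
    if spots is None:
        raise PlacementError("could not place non-overlapping patches")

    placed: list[ScenePatch] = []
    for r, c in spots[:cfg.n_oriented_patches]:
        ori = float(rng.choice(cfg.grating_orientations))
        g = grating_patch(s, ori, cfg.grating_spatial_period,
                          cfg.grating_contrast)
        img[r:r + s, c:c + s, :] = g[:, :, None]
        placed.append(ScenePatch("oriented", r, c, s, orientation_deg=ori))
    for r, c in spots[cfg.n_oriented_patches:]:
        rgb = tuple(int(v) for v in
                    cfg.patch_hues[int(rng.integers(len(cfg.patch_hues)))])
        img[r:r + s, c:c + s, :] = np.array(rgb, dtype=np.uint8)
        placed.append(ScenePatch("colored", r, c, s, rgb=rgb))
    return img, placed


def save_scene(path: str | Path, image: np.ndarray,
               patches: list[ScenePatch]) -> None:
    from PIL import Image
    path = Path(path)
    Image.fromarray(image).save(path)
    records = [{k: v for k, v in vars(p).items()} for p in patches]
    path.with_suffix(".json").write_text(json.dumps(records, indent=1))


# --------------------------------------------------------------------------
# eye traces
# --------------------------------------------------------------------------

@dataclass
class EyeTraceConfig:
    """Free-viewing gaze simulation over a four-quadrant display.

    Saccades follow minimum-jerk position profiles whose peak velocity
    obeys a linear main sequence; fixation durations are log-normal.
    """

    duration_s: float = 60.0
    sample_rate_hz: float = 1000.0
    layout: QuadrantLayout = field(default_factory=QuadrantLayout)
    fixation_mean_ms: float = 350.0
    fixation_sigma_log: float = 0.3
    min_fixation_ms: float = 120.0
    main_sequence_slope: float = 45.0     # deg/s per degree of amplitude
    main_sequence_intercept: float = 80.0  # deg/s
    microsaccade_rate_hz: float = 0.5
    microsaccade_amplitude_deg: float = 0.25
    microsaccade_duration_ms: float = 12.0
    drift_sd_deg: float = 0.003
    pupil_mean: float = 500.0
    pupil_sd: float = 20.0
    quadrant_sequence: tuple | None = None   # explicit roles to visit
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate_hz != 1000.0:
            raise ConfigurationError("traces are defined at 1 kHz sampling")
        if self.duration_s * 1000.0 < self.min_fixation_ms:
            raise ConfigurationError("duration too short for one fixation")


@dataclass
class FixationTruth:
    onset_ms: float
    offset_ms: float
    quadrant: str
    point: tuple[float, float]


def _min_jerk(n: int) -> np.ndarray:
    """Minimum-jerk displacement profile from 0 to 1 over n samples."""
    s = np.linspace(0.0, 1.0, n)
    return 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5


def _fixation_point(layout: QuadrantLayout, role: str,
                    rng: np.random.Generator) -> tuple[float, float]:
    xmin, xmax, ymin, ymax = layout.quadrant_bounds(role)
    # keep targets in the central half of the quadrant, away from borders
    fx = rng.uniform(0.3, 0.7)
    fy = rng.uniform(0.3, 0.7)
    return (xmin + fx * (xmax - xmin), ymin + fy * (ymax - ymin))


def generate_eye_trace(cfg: EyeTraceConfig
                       ) -> tuple[EyeTrace, list[FixationTruth]]:
    """Simulated 1 kHz gaze trace plus ground-truth fixation intervals.

    The gaze alternates between fixations on randomly (or explicitly)
    chosen quadrants and minimum-jerk saccades between them. Fixations
    carry low-velocity drift and optional microsaccades whose peak
    velocity stays below the 100 deg/s saccade threshold.
    """
    rng = np.random.default_rng(cfg.seed)
    dt_ms = 1000.0 / cfg.sample_rate_hz
    n_total = int(round(cfg.duration_s * cfg.sample_rate_hz))
    roles = list(cfg.layout.roles)

    x = np.empty(n_total)
    y = np.empty(n_total)
    truth: list[FixationTruth] = []
    seq_idx = 0

    def next_role(current: str | None = None) -> str:
        nonlocal seq_idx
        if cfg.quadrant_sequence is not None:
            role = cfg.quadrant_sequence[seq_idx % len(cfg.quadrant_sequence)]
            seq_idx += 1
            return role
        # avoid revisiting the same quadrant: within-quadrant saccades can
        # be small enough to fall below the detection threshold
        options = [r for r in roles if r != current]
        return options[int(rng.integers(len(options)))]

    role = next_role()
    point = _fixation_point(cfg.layout, role, rng)
    i = 0
    while i < n_total:
        # --- fixation segment ---
        dur = rng.lognormal(np.log(cfg.fixation_mean_ms),
                            cfg.fixation_sigma_log)
        dur_n = max(int(round(max(dur, cfg.min_fixation_ms) / dt_ms)), 1)
        end = min(i + dur_n, n_total)
        # no room for another saccade plus a full fixation: absorb the
        # remainder into this fixation so truth never lists a truncated one
        margin = int((cfg.min_fixation_ms + 60.0) / dt_ms)
        if n_total - end < margin:
            end = n_total
        seg = slice(i, end)
        n_seg = end - i
        xs = np.full(n_seg, point[0])
        ys = np.full(n_seg, point[1])
        if cfg.drift_sd_deg > 0:
            xs = xs + np.cumsum(rng.standard_normal(n_seg)) \
                * cfg.drift_sd_deg / np.sqrt(max(n_seg, 1))
            ys = ys + np.cumsum(rng.standard_normal(n_seg)) \
                * cfg.drift_sd_deg / np.sqrt(max(n_seg, 1))
        if cfg.microsaccade_rate_hz > 0 and n_seg > 3 * int(
                cfg.microsaccade_duration_ms / dt_ms):
            n_ms = rng.poisson(cfg.microsaccade_rate_hz * n_seg * dt_ms
                               / 1000.0)
            ms_n = int(cfg.microsaccade_duration_ms / dt_ms)
            for _ in range(n_ms):
                start = int(rng.integers(0, n_seg - ms_n))
                ang = rng.uniform(0, 2 * np.pi)
                prof = _min_jerk(ms_n) * cfg.microsaccade_amplitude_deg
                xs[start:start + ms_n] += prof * np.cos(ang)
                ys[start:start + ms_n] += prof * np.sin(ang)
                xs[start + ms_n:] += prof[-1] * np.cos(ang)
                ys[start + ms_n:] += prof[-1] * np.sin(ang)
        x[seg], y[seg] = xs, ys
        truth.append(FixationTruth(onset_ms=i * dt_ms, offset_ms=end * dt_ms,
                                   quadrant=role, point=point))
        i = end
        if i >= n_total:
            break
        # --- saccade segment ---
        role = next_role(role)
        new_point = _fixation_point(cfg.layout, role, rng)
        amp = float(np.hypot(new_point[0] - x[i - 1],
                             new_point[1] - y[i - 1]))
        peak_v = cfg.main_sequence_intercept + cfg.main_sequence_slope * amp
        sac_ms = max(1.875 * amp / peak_v * 1000.0, 2 * dt_ms)
        sac_n = min(max(int(round(sac_ms / dt_ms)), 2), n_total - i)
        prof = _min_jerk(sac_n)
        x[i:i + sac_n] = x[i - 1] + prof * (new_point[0] - x[i - 1])
        y[i:i + sac_n] = y[i - 1] + prof * (new_point[1] - y[i - 1])
        i += sac_n
        point = new_point

    t = np.arange(n_total) * dt_ms
    pupil = cfg.pupil_mean + np.zeros(n_total)
    if cfg.pupil_sd > 0:
        ar = np.empty(n_total)
        ar[0] = 0.0
        eps = rng.standard_normal(n_total)
        rho = 0.995
        for k in range(1, n_total):
            ar[k] = rho * ar[k - 1] + eps[k]
        ar = ar / (ar.std() or 1.0) * cfg.pupil_sd
        pupil = cfg.pupil_mean + ar
    trace = EyeTrace(t=t, x=x, y=y, pupil=pupil)
    return trace, truth


def save_eye_trace(path: str | Path, trace: EyeTrace,
                   truth: list[FixationTruth]) -> None:
    path = Path(path)
    trace.to_csv(path)
    records = [{"onset_ms": f.onset_ms, "offset_ms": f.offset_ms,
                "quadrant": f.quadrant, "point": list(f.point)}
               for f in truth]
    path.with_suffix(".truth.json").write_text(json.dumps(records, indent=1))


# --------------------------------------------------------------------------
# full free-viewing sessions (eye trace + per-fixation spike counts)
# --------------------------------------------------------------------------

@dataclass
class FreeviewSession:
    trace: EyeTrace
    truth: list[FixationTruth]
    counts: dict               # (onset_ms, offset_ms) -> per-neuron counts
    conditions: dict           # (onset_ms, offset_ms) -> 'unadapt'|'adapt'|None
    ground_truth: PopulationGroundTruth
    test_angles: tuple[float, float]


def generate_freeview_session(pop_cfg: PopulationConfig,
                              eye_cfg: EyeTraceConfig,
                              test_angles: tuple[float, float] = (45.0, 67.5),
                              ) -> FreeviewSession:
    """Free-viewing session: gaze trace plus spike counts per fixation.

    Counts for fixations on the test quadrants are drawn from the tuned
    population at the quadrant's stimulus angle; the adapted parameter
    set applies when the previous fixation was on the adapter quadrant,
    and the unadapted set when it was on the gray control quadrant.
    Fixations on other quadrants (and test fixations with ambiguous
    history) receive unadapted baseline-driven counts.
    """
    rng = np.random.default_rng(pop_cfg.seed + 1)
    gt_rng = np.random.default_rng(pop_cfg.seed)
    gt = _draw_ground_truth(pop_cfg, gt_rng)
    trace, truth = generate_eye_trace(eye_cfg)
    angle_of = {"test1": test_angles[0], "test2": test_angles[1]}
    counts, conditions = {}, {}
    for prev, cur in zip([None] + truth[:-1], truth):
        key = (cur.onset_ms, cur.offset_ms)
        if cur.quadrant in angle_of:
            if prev is not None and prev.quadrant == "adapter":
                cond = ADAPT
            elif prev is not None and prev.quadrant == "gray":
                cond = UNADAPT
            else:
                cond = None
            adapted = cond == ADAPT
            mean = gt.mean_rates(np.array([angle_of[cur.quadrant]]),
                                 adapted)[0]
        else:
            cond, adapted = None, False
            mean = np.full(pop_cfg.n_neurons, pop_cfg.baseline_rate)
        sd = pop_cfg.shared_sd * (pop_cfg.adapt_shared_shrink
                                  if adapted else 1.0)
        latent = rng.standard_normal(pop_cfg.shared_dims) * sd
        rate = mean + gt.loadings @ latent \
            + rng.standard_normal(pop_cfg.n_neurons) * pop_cfg.private_sd
        dur_s = (cur.offset_ms - cur.onset_ms) / 1000.0
        counts[key] = _counts_from_rates(rate, dur_s)
        conditions[key] = cond
    return FreeviewSession(trace=trace, truth=truth, counts=counts,
                           conditions=conditions, ground_truth=gt,
                           test_angles=test_angles)
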