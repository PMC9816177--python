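"""Eye-movement event detection and pseudo-trial extraction.

Free-viewing sessions have no imposed trial structure. Fixations are
segmented from the eye-velocity trace by thresholding speed at
100 deg/s, and 'pseudo-trials' are built from consecutive fixation
pairs: a fixation on the neutral gray quadrant followed by a fixation
on a test quadrant defines an unadapted trial, while adapter -> test
defines an adapted trial. Trials are kept only when the population's
aggregate receptive field, translated by gaze, stays inside a single
quadrant and within the monitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

VELOCITY_THRESHOLD_DEG_S = 100.0

QUADRANT_ROLES = ("gray", "adapter", "test1", "test2")


@dataclass
class QuadrantLayout:
    """Four-quadrant stimulus display in degrees of visual angle.

    The monitor is split at (0, 0): upper-right gray control,
    upper-left adapter, lower-left test1, lower-right test2
    (y increases upward).
    """

    x_extent: tuple[float, float] = (-20.0, 20.0)
    y_extent: tuple[float, float] = (-15.0, 15.0)
    roles: dict = field(default_factory=lambda: {
        "gray": "upper-right", "adapter": "upper-left",
        "test1": "lower-left", "test2": "lower-right"})

    def __post_init__(self):
        if set(self.roles) != set(QUADRANT_ROLES):
            raise ValueError(f"layout must assign exactly {QUADRANT_ROLES}")
        if len(set(self.roles.values())) != 4:
            raise ValueError("each quadrant may carry only one role")

    def quadrant_of(self, x: float, y: float) -> str:
        """Role of the quadrant containing (x, y); 'none' if off-monitor."""
        if not (self.x_extent[0] <= x <= self.x_extent[1]
                and self.y_extent[0] <= y <= self.y_extent[1]):
            return "none"
        pos = ("upper" if y >= 0 else "lower") + "-" + \
              ("right" if x >= 0 else "left")
        for role, p in self.roles.items():
            if p == pos:
                return role
        return "none"

    def quadrant_bounds(self, role: str) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the quadrant holding `role`."""
        pos = self.roles[role]
        ver, hor = pos.split("-")
        xmin, xmax = (0.0, self.x_extent[1]) if hor == "right" \
            else (self.x_extent[0], 0.0)
        ymin, ymax = (0.0, self.y_extent[1]) if ver == "upper" \
            else (self.y_extent[0], 0.0)
        return xmin, xmax, ymin, ymax


@dataclass
class EyeTrace:
    """Gaze samples at 1 kHz: time (ms), position (deg), pupil (a.u.)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.pupil)):
            raise ValueError("trace arrays must share length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt_ms(self) -> float:
        return float(np.median(np.diff(self.t)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t_ms": self.t, "x_deg": self.x, "y_deg": self.y,
                      "pupil": self.pupil}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EyeTrace":
        df = pd.read_csv(path)
        return cls(df["t_ms"].to_numpy(), df["x_deg"].to_numpy(),
                   df["y_deg"].to_numpy(), df["pupil"].to_numpy())


@dataclass
class FixationEvent:
    onset_ms: float
    offset_ms: float
    centroid: tuple[float, float]
    quadrant: str = "none"
    mean_pupil: float = float("nan")
    microsaccade_count: int = 0
    microsaccade_peak_velocities: list = field(default_factory=list)
    rf_confined: bool = True

    def __post_init__(self):
        if self.offset_ms <= self.onset_ms:
            raise ValueError("fixation offset must follow onset")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class PseudoTrial:
    condition: str                 # 'unadapt' | 'adapt'
    adapter_fixation: FixationEvent
    test_fixation: FixationEvent
    test_stimulus: str             # 'test1' | 'test2'
    spike_counts: np.ndarray | None = None


def eye_speed(trace: EyeTrace, smooth_ms: float = 7.0) -> np.ndarray:
    """Gaze speed (deg/s) by central differences plus moving average.

    A short boxcar (default 7 ms) suppresses sample-to-sample tracker
    jitter that would otherwise split fixations.
    """
    dt_s = trace.dt_ms / 1000.0
    if len(trace.t) > 1:
        steps = np.diff(trace.t)
        if np.any(np.abs(steps - trace.dt_ms) > 1e-6):
            raise ValueError("detect_fixations requires uniform sampling")
    vx = np.gradient(trace.x, dt_s)
    vy = np.gradient(trace.y, dt_s)
    speed = np.hypot(vx, vy)
    k = max(1, int(round(smooth_ms / trace.dt_ms)))
    if k > 1:
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.pad(speed, pad, mode="reflect")
        speed = np.convolve(padded, kernel, mode="same")[pad:pad + len(speed)]
    return speed


def detect_fixations(trace: EyeTrace,
                     velocity_threshold: float = VELOCITY_THRESHOLD_DEG_S,
                     min_duration_ms: float = 50.0,
                     smooth_ms: float = 7.0,
                     layout: QuadrantLayout | None = None,
                     microsaccade_sd_factor: float = 3.0,
                     ) -> list[FixationEvent]:
    """Segment fixations as maximal runs of sub-threshold eye speed.

    Runs shorter than ``min_duration_ms`` are discarded. Microsaccades
    are flagged within each fixation as speed excursions above
    ``microsaccade_sd_factor`` s.d. of the within-fixation speed while
    remaining below the saccade threshold.
    """
    if len(trace.t) < 3:
        raise ValueError("trace too short for velocity estimation")
    speed = eye_speed(trace, smooth_ms=smooth_ms)
    below = speed < velocity_threshold
    fixations: list[FixationEvent] = []
    # run-length segmentation of the boolean mask
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(below) - 1]
    for s, e in zip(starts, ends):
        if not below[s]:
            continue
        onset, offset = trace.t[s], trace.t[e] + trace.dt_ms
        if offset - onset < min_duration_ms:
            continue
        seg = slice(s, e + 1)
        cx, cy = float(np.mean(trace.x[seg])), float(np.mean(trace.y[seg]))
        ms_count, ms_peaks = _count_microsaccades(
            speed[seg], velocity_threshold, microsaccade_sd_factor)
        fixations.append(FixationEvent(
            onset_ms=float(onset), offset_ms=float(offset),
            centroid=(cx, cy),
            quadrant=layout.quadrant_of(cx, cy) if layout else "none",
            mean_pupil=float(np.mean(trace.pupil[seg])),
            microsaccade_count=ms_count,
            microsaccade_peak_velocities=ms_peaks))
    return fixations


def _count_microsaccades(speed_seg: np.ndarray, threshold: float,
                         sd_factor: float) -> tuple[int, list]:
    """Sub-threshold velocity excursions above mean + sd_factor * s.d."""
    mu, sd = speed_seg.mean(), speed_seg.std()
    if sd == 0:
        return 0, []
    high = (speed_seg > mu + sd_factor * sd) & (speed_seg < threshold)
    edges = np.flatnonzero(np.diff(high.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(high) - 1]
    peaks = [float(speed_seg[s:e + 1].max())
             for s, e in zip(starts, ends) if high[s]]
    return len(peaks), peaks


def label_quadrants(fixations: list[FixationEvent],
                    layout: QuadrantLayout) -> list[FixationEvent]:
    for f in fixations:
        f.quadrant = layout.quadrant_of(*f.centroid)
    return fixations


def rf_confined(fixation: FixationEvent, layout: QuadrantLayout,
                rf_extent: tuple[float, float, float, float]) -> bool:
    """True when the gaze-shifted aggregate RF box stays inside one
    quadrant and inside the monitor.

    ``rf_extent`` is the population RF bounding box relative to gaze:
    (dx_min, dx_max, dy_min, dy_max) in degrees.
    """
    if fixation.quadrant in ("none",):
        return False
    gx, gy = fixation.centroid
    x0, x1 = gx + rf_extent[0], gx + rf_extent[1]
    y0, y1 = gy + rf_extent[2], gy + rf_extent[3]
    qxmin, qxmax, qymin, qymax = layout.quadrant_bounds(fixation.quadrant)
    return (qxmin <= x0 and x1 <= qxmax and qymin <= y0 and y1 <= qymax)


def extract_pseudo_trials(fixations: list[FixationEvent],
                          layout: QuadrantLayout,
                          rf_extent: tuple[float, float, float, float],
                          counts_for=None) -> list[PseudoTrial]:
    """Build unadapted/adapted pseudo-trials from a fixation sequence.

    Consecutive fixation pairs gray -> test_k yield unadapted trials and
    adapter -> test_k adapted trials. The test fixation must pass the RF
    confinement filter. ``counts_for`` optionally maps a FixationEvent to
    a per-neuron spike-count vector for the test fixation.
    """
    if set(QUADRANT_ROLES) - set(layout.roles):
        raise ValueError("layout must define all four quadrant roles")
    trials: list[PseudoTrial] = []
    for prev, cur in zip(fixations[:-1], fixations[1:]):
        if cur.quadrant not in ("test1", "test2"):
            continue
        if prev.quadrant == "gray":
            condition = "unadapt"
        elif prev.quadrant == "adapter":
            condition = "adapt"
        else:
            continue
        cur.rf_confined = rf_confined(cur, layout, rf_extent)
        if not cur.rf_confined:
            continue
        trials.append(PseudoTrial(
            condition=condition, adapter_fixation=prev, test_fixation=cur,
            test_stimulus=cur.quadrant,
            spike_counts=None if counts_for is None else counts_for(cur)))
    return trials


_COVARIATES = {
    "adapter_fixation_duration_ms": lambda t: t.adapter_fixation.duration_ms,
    "test_fixation_duration_ms": lambda t: t.test_fixation.duration_ms,
    "mean_pupil": lambda t: t.test_fixation.mean_pupil,
    "microsaccade_count": lambda t: t.test_fixation.microsaccade_count,
    "microsaccade_peak_velocity": lambda t: (
        float(np.mean(t.test_fixation.microsaccade_peak_velocities))
        if t.test_fixation.microsaccade_peak_velocities else np.nan),
}


def covariate_comparison(trials: list[PseudoTrial]) -> pd.DataFrame:
    """Rank-sum comparison of fixation covariates across conditions.

    Adaptation-strength confounds would show up as condition differences
    in fixation durations, pupil size or microsaccade statistics; each
    covariate is compared between unadapted and adapted trials with a
    two-sided Wilcoxon rank-sum test.
    """
    unadapt = [t for t in trials if t.condition == "unadapt"]
    adapt = [t for t in trials if t.condition == "adapt"]
    rows = []
    for name, getter in _COVARIATES.items():
        a = np.array([getter(t) for t in unadapt], dtype=float)
        b = np.array([getter(t) for t in adapt], dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"covariate {name}: too few trials, skipped")
            rows.append({"covariate": name, "median_unadapt": np.nan,
                         "median_adapt": np.nan, "p_value": np.nan})
            continue
        stat = stats.ranksums(a, b)
        rows.append({"covariate": name,
                     "median_unadapt": float(np.median(a)),
                     "median_adapt": float(np.median(b)),
                     "p_value": float(stat.pvalue)})
    # adapter-fixation durations preceding test1 vs test2 (within condition)
    for cond, group in (("unadapt", unadapt), ("adapt", adapt)):
        d1 = np.array([t.adapter_fixation.duration_ms for t in group
                       if t.test_stimulus == "test1"])
        d2 = np.array([t.adapter_fixation.duration_ms for t in group
                       if t.test_stimulus == "test2"])
        name = f"pre_test1_vs_pre_test2_duration_{cond}"
        if len(d1) < 2 or len(d2) < 2:
            rows.append({"covariate": name, "median_unadapt": np.nan,
                         "median_adapt": np.nan, "p_value": np.nan})
            continue
        stat = stats.ranksums(d1, d2)
        rows.append({"covariate": name,
                     "median_unadapt": float(np.median(d1)),
                     "median_adapt": float(np.median(d2)),
                     "p_value": float(stat.pvalue)})
    return pd.DataFrame(rows)
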