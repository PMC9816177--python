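"""Statistics-driven scanpath simulation over images.

Pseudo-saccades are sampled from empirical amplitude and direction
distributions (binned histograms fitted from measured saccades) and
chained into scanpaths over an image; the patch under each fixation is
classified as oriented, colored or neither, and transitions between
successive fixations are tallied as iso-feature (colored->colored,
oriented->oriented), cross-feature (colored->oriented or the reverse)
or other (touching an unclassified patch). Scanpaths are
statistics-driven, not content-driven: landing points ignore image
content entirely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_features import (ColorCriteria, OrientationField, classify_patch,
                             sobel_orientation_field)

AMPLITUDE_BIN_DEG = 0.5
DIRECTION_BIN_DEG = 10.0


class EstimationError(ValueError):
    pass


@dataclass
class SaccadeModel:
    """Binned empirical saccade amplitude and direction distributions.

    Sampling draws a bin proportional to its mass, then a uniform value
    within the bin.
    """

    amplitude_edges: np.ndarray
    amplitude_mass: np.ndarray
    direction_edges: np.ndarray
    direction_mass: np.ndarray

    def sample(self, rng: np.random.Generator,
               n: int) -> tuple[np.ndarray, np.ndarray]:
        amp = _sample_binned(rng, self.amplitude_edges,
                             self.amplitude_mass, n)
        direc = _sample_binned(rng, self.direction_edges,
                               self.direction_mass, n)
        return amp, direc % 360.0


def _sample_binned(rng, edges, mass, n):
    idx = rng.choice(len(mass), size=n, p=mass)
    lo, hi = edges[idx], edges[idx + 1]
    return lo + rng.random(n) * (hi - lo)


def fit_saccade_model(saccades) -> SaccadeModel:
    """Fit the binned model from (amplitude_deg, direction_deg) pairs.

    Amplitudes use 0.5-degree bins, directions 10-degree bins over
    [0, 360).
    """
    saccades = np.asarray(saccades, dtype=float)
    if saccades.size == 0:
        raise EstimationError("need at least one saccade")
    amp = saccades[:, 0]
    direc = saccades[:, 1] % 360.0
    if np.any(amp < 0):
        raise EstimationError("amplitudes must be non-negative")
    amp_hi = np.ceil(amp.max() / AMPLITUDE_BIN_DEG + 1) * AMPLITUDE_BIN_DEG
    amp_edges = np.arange(0.0, amp_hi + AMPLITUDE_BIN_DEG / 2,
                          AMPLITUDE_BIN_DEG)
    amp_mass, _ = np.histogram(amp, bins=amp_edges)
    dir_edges = np.arange(0.0, 360.0 + DIRECTION_BIN_DEG / 2,
                          DIRECTION_BIN_DEG)
    dir_mass, _ = np.histogram(direc, bins=dir_edges)
    return SaccadeModel(
        amplitude_edges=amp_edges,
        amplitude_mass=amp_mass / amp_mass.sum(),
        direction_edges=dir_edges,
        direction_mass=dir_mass / dir_mass.sum())


@dataclass
class Scanpath:
    fixation_points: np.ndarray       # (n_saccades + 1, 2) as (row, col)
    patch_labels: list[str]
    transitions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.transitions = list(zip(self.patch_labels[:-1],
                                    self.patch_labels[1:]))

    def to_json(self) -> str:
        return json.dumps({
            "fixation_points": self.fixation_points.tolist(),
            "patch_labels": self.patch_labels})


def simulate_scanpath(model: SaccadeModel, image: np.ndarray,
                      n_saccades: int = 300,
                      start: tuple[float, float] | str = "random",
                      deg_to_px: float = 10.0, patch_size: int = 50,
                      criteria: ColorCriteria | None = None,
                      rng: np.random.Generator | None = None,
                      field_cache: OrientationField | None = None,
                      max_retries: int = 20) -> Scanpath:
    """Chain sampled saccades over an image and classify each fixation.

    Landing points falling outside the image are re-sampled up to
    ``max_retries`` times, then clipped. The fixated patch is the
    ``patch_size`` window centered on the landing point (shifted to fit
    inside the image) and classified via the patch feature criteria.
    """
    rng = rng or np.random.default_rng(0)
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise ValueError("image extent must exceed one patch")
    field = field_cache if field_cache is not None \
        else sobel_orientation_field(image)
    if start == "random":
        pos = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
    else:
        pos = np.asarray(start, dtype=float)
    points = [pos.copy()]
    for _ in range(n_saccades):
        for _ in range(max_retries):
            amp, direc = model.sample(rng, 1)
            d_px = amp[0] * deg_to_px
            ang = np.radians(direc[0])
            # direction 0 = rightward, measured counterclockwise (y up),
            # so the row displacement is -sin in array coordinates
            cand = pos + np.array([-d_px * np.sin(ang), d_px * np.cos(ang)])
            if 0 <= cand[0] <= h - 1 and 0 <= cand[1] <= w - 1:
                break
        cand = np.clip(cand, [0, 0], [h - 1, w - 1])
        pos = cand
        points.append(pos.copy())
    labels = [
        _classify_at(image, field, p, patch_size, criteria) for p in points]
    return Scanpath(fixation_points=np.array(points), patch_labels=labels)


def _classify_at(image, field, point, patch_size, criteria) -> str:
    h, w = image.shape[:2]
    r0 = int(np.clip(round(point[0] - patch_size / 2), 0, h - patch_size))
    c0 = int(np.clip(round(point[1] - patch_size / 2), 0, w - patch_size))
    win = (slice(r0, r0 + patch_size), slice(c0, c0 + patch_size))
    sub = OrientationField(field.orientation[win], field.magnitude[win])
    patch = image[win] if image.ndim == 2 else image[win[0], win[1]]
    return classify_patch(patch, criteria, field=sub).label


@dataclass
class TransitionSummary:
    n_transitions: int
    n_iso: int
    n_cross: int
    n_other: int
    iso_pct: float
    cross_pct: float
    other_pct: float
    cross_pct_feature_only: float   # denominator excludes 'neither' pairs
    per_image: pd.DataFrame | None = None


def _tally(transitions) -> tuple[int, int, int]:
    iso = cross = other = 0
    for a, b in transitions:
        if "neither" in (a, b):
            other += 1
        elif a == b:
            iso += 1
        else:
            cross += 1
    return iso, cross, other


def cross_feature_fraction(scanpaths: list[Scanpath]) -> TransitionSummary:
    """Pooled and per-image iso-/cross-feature transition percentages.

    Percentages are over all transitions; ``cross_pct_feature_only``
    additionally reports the cross-feature share when transitions
    touching an unclassified ('neither') patch are dropped from the
    denominator. Raises when there are no transitions at all.
    """
    rows = []
    iso = cross = other = 0
    for k, sp in enumerate(scanpaths):
        i, c, o = _tally(sp.transitions)
        iso, cross, other = iso + i, cross + c, other + o
        rows.append({"image": k, "n_iso": i, "n_cross": c, "n_other": o})
    total = iso + cross + other
    if total == 0:
        raise ValueError("no transitions: cross-feature fraction undefined")
    feature_total = iso + cross
    return TransitionSummary(
        n_transitions=total, n_iso=iso, n_cross=cross, n_other=other,
        iso_pct=100.0 * iso / total, cross_pct=100.0 * cross / total,
        other_pct=100.0 * other / total,
        cross_pct_feature_only=(100.0 * cross / feature_total
                                if feature_total else float("nan")),
        per_image=pd.DataFrame(rows))
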