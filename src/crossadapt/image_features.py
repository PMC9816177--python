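"""Orientation and color content of image patches.

Orientation content is scored from the Sobel gradient field: each
pixel contributes its edge orientation (the direction of locally
constant brightness, in [0, 180)) weighted by gradient magnitude to a
36-bin histogram in 5 degree steps. The orientation selectivity index
(OSI) of a patch is the normalized first Fourier component of that
histogram on the doubled-angle circle, so OSI = 1 for a single
orientation and 0 for an isotropic patch. Color content is scored from
the R, G, B channel histograms: a patch counts as colored when the
channel peaks avoid black/white (criterion a), are not mutually within
a gray band (criterion b), and the patch carries no significant
orientation signal (criterion c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._circ import rayleigh_p

N_ORIENT_BINS = 36           # 5 degree bins over [0, 180)
BIN_WIDTH_DEG = 180.0 / N_ORIENT_BINS
BIN_CENTERS_DEG = (np.arange(N_ORIENT_BINS) + 0.5) * BIN_WIDTH_DEG
# luma weights for RGB -> brightness conversion (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])


class PatchSizeError(ValueError):
    pass


@dataclass
class OrientationField:
    """Per-pixel edge orientation (deg, [0,180)) and gradient magnitude."""

    orientation: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        if self.orientation.shape != self.magnitude.shape:
            raise ValueError("orientation and magnitude must share shape")


@dataclass
class ColorCriteria:
    """Thresholds for the colored-patch decision.

    delta is the channel-value margin: peaks within delta of 0 or 255
    mark black/white patches, and peaks that all fall within a single
    +-delta band mark gray patches.
    """

    delta: float = 30.0
    smoothing_width: int = 5

    def __post_init__(self):
        if not 0 < self.delta < 128:
            raise ValueError("delta must lie in (0, 128)")


@dataclass
class PatchFeature:
    histogram: np.ndarray        # 36-bin magnitude-weighted counts
    osi: float
    mean_orientation: float      # degrees in [0,180); nan when undefined
    n_histogram_peaks: int
    label: str                   # 'oriented' | 'colored' | 'neither'
    rayleigh_p: float = float("nan")
    row: int = 0
    col: int = 0


def to_brightness(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to a 2-D brightness map by luma weighting."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] >= 3:
        return img[..., :3] @ _LUMA
    raise ValueError(f"cannot interpret image of shape {img.shape}")


def sobel_orientation_field(image: np.ndarray) -> OrientationField:
    """Edge orientation and gradient magnitude from 3x3 Sobel kernels.

    The gradient direction is atan2(Gy, Gx); the reported orientation is
    that of the underlying edge (constant-brightness contour), i.e. the
    gradient direction rotated by 90 degrees and collapsed to [0, 180).
    Under this convention a brightness ramp along x (vertical contours)
    scores 90 degrees. Borders use reflected padding.
    """
    bright = to_brightness(image)
    if bright.ndim != 2:
        raise ValueError("expected a 2-D brightness array")
    if min(bright.shape) < 3:
        raise ValueError("image must be at least 3x3")
    gy = ndimage.sobel(bright, axis=0, mode="reflect")
    gx = ndimage.sobel(bright, axis=1, mode="reflect")
    magnitude = np.hypot(gx, gy)
    # axis 0 points down the image, so the display-space gradient is
    # (gx, -gy); rotating it by 90 deg gives the edge orientation with
    # 0 = horizontal contours, 90 = vertical, measured counterclockwise.
    orientation = (np.degrees(np.arctan2(-gy, gx)) + 90.0) % 180.0
    return OrientationField(orientation=orientation, magnitude=magnitude)


def orientation_histogram(field: OrientationField,
                          window=None) -> np.ndarray:
    """Magnitude-weighted 36-bin orientation histogram of a region.

    ``window`` is an optional (row_slice, col_slice) pair selecting a
    patch of the field.
    """
    ori = field.orientation
    mag = field.magnitude
    if window is not None:
        ori = ori[window]
        mag = mag[window]
    bins = np.minimum((ori.ravel() / BIN_WIDTH_DEG).astype(np.intp),
                      N_ORIENT_BINS - 1)
    return np.bincount(bins, weights=mag.ravel(), minlength=N_ORIENT_BINS)


def histogram_osi(hist: np.ndarray) -> tuple[float, float]:
    """(osi, mean_orientation_deg) of a 36-bin orientation histogram.

    The histogram is treated as a circular distribution with doubled
    angles (period 180 deg): osi = |sum h_b exp(2i theta_b)| / sum h_b
    and the mean orientation is half the argument of the same sum.
    Returns (0, nan) for an all-zero histogram.
    """
    total = hist.sum()
    if total <= 0:
        return 0.0, float("nan")
    z = np.sum(hist * np.exp(2j * np.radians(BIN_CENTERS_DEG)))
    osi = float(abs(z) / total)
    if abs(z) == 0:
        return osi, float("nan")
    mean_deg = (np.degrees(np.angle(z)) / 2.0) % 180.0
    return osi, float(mean_deg)


def patch_osi(patch: np.ndarray | None = None,
              field: OrientationField | None = None) -> PatchFeature:
    """OSI, mean orientation and orientation histogram of one patch.

    Either a raw (RGB or grayscale) ``patch`` or a precomputed
    ``field`` restricted to the patch may be given; passing the field
    avoids recomputing Sobel gradients in sliding-window analyses.
    """
    if field is None:
        if patch is None:
            raise ValueError("need a patch or an orientation field")
        field = sobel_orientation_field(patch)
    hist = orientation_histogram(field)
    osi, mean_ori = histogram_osi(hist)
    try:
        n_peaks = _count_osi_peaks(field)
    except PatchSizeError:
        n_peaks = 0
    return PatchFeature(histogram=hist, osi=osi, mean_orientation=mean_ori,
                        n_histogram_peaks=n_peaks,
                        label="", rayleigh_p=float("nan"))


def channel_peaks(patch_rgb: np.ndarray,
                  criteria: ColorCriteria) -> np.ndarray:
    """Peak (mode) location of each RGB channel's smoothed histogram.

    Histograms use 256 value bins and a moving-average smoother of
    width ``criteria.smoothing_width``; ties break toward the lower
    value (first maximum).
    """
    patch = np.asarray(patch_rgb)
    if patch.ndim != 3 or patch.shape[2] < 3:
        raise ValueError("colored-patch criteria need an RGB patch")
    w = criteria.smoothing_width
    kernel = np.ones(w) / w
    peaks = np.empty(3)
    for c in range(3):
        hist = np.bincount(patch[..., c].ravel().astype(np.intp),
                           minlength=256)[:256].astype(float)
        smoothed = np.convolve(hist, kernel, mode="same")
        peaks[c] = np.argmax(smoothed)
    return peaks


def _color_criteria_ab(patch_rgb: np.ndarray,
                       criteria: ColorCriteria) -> bool:
    """Criteria (a) and (b): peaks away from black/white and not gray."""
    peaks = channel_peaks(patch_rgb, criteria)
    d = criteria.delta
    if np.any(peaks < d) or np.any(peaks > 255 - d):
        return False                       # (a) black / white patch
    return peaks.max() - peaks.min() > d   # (b) not all in one gray band


def _count_osi_peaks(field: OrientationField, grid: int = 5,
                     n_bins: int = 10, sd_factor: float = 3.0) -> int:
    """Peaks of the sub-window OSI distribution of a patch.

    The patch is tiled into a grid x grid set of sub-windows, the OSI of
    each sub-window is computed, and peaks are local maxima of the
    binned OSI distribution exceeding mean + sd_factor * s.d. of the bin
    counts. Patches whose OSI distribution has more than one such peak
    contain multiple orientations and are excluded from the 'oriented'
    class.
    """
    h, w = field.orientation.shape
    if h < grid or w < grid:
        raise PatchSizeError("patch smaller than the sub-window grid")
    # per-pixel doubled-angle resultants, box-summed per sub-window
    bins = np.minimum((field.orientation / BIN_WIDTH_DEG).astype(np.intp),
                      N_ORIENT_BINS - 1)
    z = field.magnitude * np.exp(2j * np.radians(BIN_CENTERS_DEG))[bins]
    hh, ww = (h // grid) * grid, (w // grid) * grid
    zb = z[:hh, :ww].reshape(grid, hh // grid, grid, ww // grid)
    mb = field.magnitude[:hh, :ww].reshape(grid, hh // grid, grid, ww // grid)
    num = np.abs(zb.sum(axis=(1, 3)))
    den = mb.sum(axis=(1, 3))
    osis = np.divide(num, den, out=np.zeros_like(num), where=den > 0).ravel()
    counts, _ = np.histogram(osis, bins=n_bins, range=(0.0, 1.0))
    thresh = counts.mean() + sd_factor * counts.std()
    padded = np.r_[-1.0, counts.astype(float), -1.0]
    local_max = (padded[1:-1] > padded[:-2]) & (padded[1:-1] >= padded[2:])
    return int(np.sum(local_max & (counts > thresh)))


def _rayleigh_p_histogram(hist: np.ndarray, n_pixels: int) -> float:
    """Rayleigh p on the doubled-angle weighted orientation histogram.

    Magnitude weights are rescaled so their sum equals the pixel count,
    giving an effective sample size of one observation per pixel.
    """
    total = hist.sum()
    if total <= 0:
        return 1.0
    weights = hist * (n_pixels / total)
    angles = np.radians(2.0 * BIN_CENTERS_DEG)
    return rayleigh_p(angles, weights, d=np.radians(2.0 * BIN_WIDTH_DEG))


def classify_patch(patch_rgb: np.ndarray,
                   criteria: ColorCriteria | None = None,
                   osi_significance: float = 0.05,
                   field: OrientationField | None = None) -> PatchFeature:
    """Label a patch 'oriented', 'colored' or 'neither'.

    colored: channel-peak criteria (a) and (b) hold and the orientation
    signal is not significant (criterion c). oriented: the Rayleigh test
    on the doubled-angle weighted histogram is significant, the
    sub-window OSI distribution has at most one peak, and the patch
    carries no color information. Everything else is 'neither'.
    """
    criteria = criteria or ColorCriteria()
    patch_rgb = np.asarray(patch_rgb)
    if field is None:
        field = sobel_orientation_field(patch_rgb)
    hist = orientation_histogram(field)
    osi, mean_ori = histogram_osi(hist)
    n_pixels = field.orientation.size
    p = _rayleigh_p_histogram(hist, n_pixels)
    n_peaks = _count_osi_peaks(field)
    oriented_sig = (p < osi_significance) and (n_peaks <= 1)
    has_color = (patch_rgb.ndim == 3 and patch_rgb.shape[-1] >= 3
                 and _color_criteria_ab(patch_rgb, criteria))
    if has_color and not (p < osi_significance):
        label = "colored"
    elif oriented_sig and not has_color:
        label = "oriented"
    else:
        label = "neither"
    return PatchFeature(histogram=hist, osi=osi, mean_orientation=mean_ori,
                        n_histogram_peaks=n_peaks, label=label,
                        rayleigh_p=p)


def feature_map(image: np.ndarray, window: int = 50, stride: int = 10,
                criteria: ColorCriteria | None = None,
                osi_significance: float = 0.05) -> list[PatchFeature]:
    """Sliding-window patch features over a whole image.

    A ``window`` x ``window`` patch is scored at every position on a
    ``stride`` grid; only full windows are evaluated. Each returned
    PatchFeature carries its (row, col) top-left corner.
    """
    if stride <= 0:
        raise ValueError("stride must be positive")
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < window or w < window:
        raise ValueError("image smaller than one window")
    full_field = sobel_orientation_field(image)
    features = []
    for r in range(0, h - window + 1, stride):
        for c in range(0, w - window + 1, stride):
            win = (slice(r, r + window), slice(c, c + window))
            sub = OrientationField(full_field.orientation[win],
                                   full_field.magnitude[win])
            patch = image[win] if image.ndim == 2 else image[win[0], win[1]]
            feat = classify_patch(patch, criteria, osi_significance,
                                  field=sub)
            feat.row, feat.col = r, c
            features.append(feat)
    return features


def feature_map_dataframe(features: list[PatchFeature]) -> pd.DataFrame:
    return pd.DataFrame([{
        "row": f.row, "col": f.col, "osi": f.osi,
        "mean_orientation_deg": f.mean_orientation, "label": f.label,
        "rayleigh_p": f.rayleigh_p, "n_histogram_peaks": f.n_histogram_peaks,
    } for f in features])
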