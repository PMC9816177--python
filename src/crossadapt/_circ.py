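"""Circular statistics primitives shared across modules.

Angles are handled in radians internally; public modules convert from
degrees and apply angle doubling for 180°-periodic (orientation) data
before calling in here.
"""

from __future__ import annotations

import numpy as np


def resultant(angles: np.ndarray, weights: np.ndarray | None = None,
              d: float | None = None) -> complex:
    """Weighted complex resultant sum of circular data.

    Parameters
    ----------
    angles : array of angles in radians.
    weights : optional non-negative weights (binned counts or firing rates).
    d : optional bin spacing in radians; when given, the classical
        grouping bias correction ``(d/2)/sin(d/2)`` is applied to the
        resultant magnitude.
    """
    angles = np.asarray(angles, dtype=float)
    if weights is None:
        weights = np.ones_like(angles)
    weights = np.asarray(weights, dtype=float)
    z = np.sum(weights * np.exp(1j * angles))
    if d is not None and d > 0:
        z *= (d / 2) / np.sin(d / 2)
    return z


def resultant_length(angles, weights=None, d=None) -> float:
    """Mean resultant length r in [0, 1] (up to the grouping correction)."""
    angles = np.asarray(angles, dtype=float)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    total = w.sum()
    if total <= 0:
        return 0.0
    return abs(resultant(angles, w, d)) / total


def rayleigh_p(angles, weights=None, d=None) -> float:
    """Rayleigh test p-value for non-uniformity of circular data.

    Uses the Zar (1999) large-sample approximation with the standard
    small-sample correction term, matching the CircStat convention.
    With ``weights`` the effective sample size is ``sum(weights)``.
    """
    angles = np.asarray(angles, dtype=float)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    n = w.sum()
    if n <= 0:
        return 1.0
    # grouping correction can push r marginally above 1 for a histogram
    # concentrated in one bin; clamp so the p approximation stays defined
    r = min(abs(resultant(angles, w, d)) / n, 1.0)
    R = n * r
    arg = max(1 + 4 * n + 4 * (n * n - R * R), 0.0)
    p = np.exp(np.sqrt(arg) - (1 + 2 * n))
    return float(min(p, 1.0))


def circ_mean(angles, weights=None) -> float:
    """Circular mean direction in radians, in (-pi, pi]."""
    z = resultant(angles, weights)
    if abs(z) == 0:
        raise ValueError("circular mean undefined for zero resultant")
    return float(np.angle(z))
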