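"""Circular (directional) statistics helpers.

All public functions take and return **degrees**; radians appear only
transiently inside computations.  Vector angles live in (−180°, 180°],
axial (180°-periodic) angles in (−90°, 90°].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "wrap_axial",
    "signed_angle",
    "resultant_length",
    "circular_mean",
    "circular_sd",
    "axial_mean",
    "acute_angle_to_axis",
    "sample_wrapped_normal",
    "circular_correlation",
]

#: σ reported when the mean resultant length underflows (R → 0).
SIGMA_CAP_DEG = 180.0


def wrap_angle(deg):
    """Wrap angle(s) to the interval (−180°, 180°]."""
    return 180.0 - np.mod(180.0 - np.asarray(deg, dtype=float), 360.0)


def wrap_axial(deg):
    """Wrap 180°-periodic orientation(s) to (−90°, 90°]."""
    return 90.0 - np.mod(90.0 - np.asarray(deg, dtype=float), 180.0)


def signed_angle(reference_xy, vector_xy) -> float:
    """Signed angle (degrees) from ``reference_xy`` to ``vector_xy``.

    Positive counterclockwise in a mathematical frame (y up).  Result in
    (−180°, 180°].  Raises on a zero-length vector.
    """
    rx, ry = float(reference_xy[0]), float(reference_xy[1])
    vx, vy = float(vector_xy[0]), float(vector_xy[1])
    if (vx == 0.0 and vy == 0.0) or (rx == 0.0 and ry == 0.0):
        raise ValueError("zero-length vector has no direction")
    cross = rx * vy - ry * vx
    dot = rx * vx + ry * vy
    return float(wrap_angle(np.degrees(np.arctan2(cross, dot))))


def _unit_sums(angles_deg):
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return np.cos(a).sum(), np.sin(a).sum(), a.size


def resultant_length(angles_deg) -> float:
    """Mean resultant length R ∈ [0, 1] of the unit vectors."""
    c, s, n = _unit_sums(angles_deg)
    if n == 0:
        raise ValueError("no angles")
    return float(min(1.0, np.hypot(c, s) / n))


def circular_mean(angles_deg) -> float:
    """Circular mean direction in degrees, (−180°, 180°]."""
    c, s, n = _unit_sums(angles_deg)
    if n == 0:
        raise ValueError("no angles")
    return float(wrap_angle(np.degrees(np.arctan2(s, c))))


def circular_sd(angles_deg) -> float:
    """Circular standard deviation σ = √(−2 ln R), in degrees.

    σ = 0 exactly for identical angles (R = 1); the report is capped at
    180° as R → 0 (e.g. four angles at right angles to each other).
    """
    angles = np.asarray(angles_deg, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least two angles")
    r = resultant_length(angles)
    if r >= 1.0:
        return 0.0
    if r <= 0.0:
        return SIGMA_CAP_DEG
    sd = np.degrees(np.sqrt(-2.0 * np.log(r)))
    return float(min(sd, SIGMA_CAP_DEG))


def axial_mean(orientations_deg) -> float:
    """Mean of 180°-periodic orientations via the doubled-angle method.

    Returns the orientation in (−90°, 90°] of the mean of the doubled
    unit vectors: ½·atan2(Σ sin 2θ, Σ cos 2θ).
    """
    a = 2.0 * np.radians(np.asarray(orientations_deg, dtype=float))
    if a.size == 0:
        raise ValueError("no orientations")
    return float(wrap_axial(0.5 * np.degrees(np.arctan2(np.sin(a).sum(), np.cos(a).sum()))))


def acute_angle_to_axis(vector_angle_deg, axis_angle_deg) -> float:
    """Acute angle [0°, 90°] between a vector direction and an axis.

    The axis is 180°-periodic, so the result is min over the axis and its
    flip.
    """
    d = abs(float(wrap_angle(vector_angle_deg - axis_angle_deg)))
    return min(d, 180.0 - d)


def sample_wrapped_normal(mean_deg, sigma_deg, n, rng) -> np.ndarray:
    """Draw ``n`` wrapped-normal angles (degrees, wrapped to (−180°, 180°]).

    For the wrapped normal, σ_deg is both the underlying normal SD and the
    circular SD √(−2 ln R) of the distribution, making the estimator in
    :func:`circular_sd` self-consistent.
    """
    draws = rng.normal(loc=mean_deg, scale=sigma_deg, size=int(n))
    return wrap_angle(draws)


def circular_correlation(a_deg, b_deg) -> float:
    """Fisher–Lee circular correlation coefficient between paired angles."""
    a = np.radians(np.asarray(a_deg, dtype=float))
    b = np.radians(np.asarray(b_deg, dtype=float))
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired angle samples")
    abar = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        raise ValueError("degenerate sample (no angular spread)")
    return float((sa * sb).sum() / denom)
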