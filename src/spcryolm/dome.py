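"""Membrane-dome geometry: interblade distance, in-plane radius, curvature.

The three labeled blade tips of the trimer form an equilateral triangle of
side d (the interblade distance); its circumradius is d / sqrt(3).  The label
site sits ~1.5 nm inside the blade edge, so the in-plane radius of the blade
tips is

    r = (d + 1.5) / sqrt(3).

If the protein-membrane region locally forms a spherical cap of height h that
reaches the circle of radius r, the cap's radius of curvature is

    R = (r^2 + h^2) / (2 h),

which diverges as h -> 0 (a flat membrane) and attains its minimum R = r at
h = r (a hemisphere).  When the cap height is uncertain, R is summarized by
its median over heights sampled uniformly on an interval (0, h_max].
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

SQRT3 = np.sqrt(3.0)
LABEL_EDGE_OFFSET_NM = 1.5  # label site to blade edge, from the AF2 model
DEFAULT_DISTANCE_ERROR_NM = 2.3  # median propagated distance error


class RadiusEstimate(NamedTuple):
    value: float  # nm
    error: float  # nm, propagated from the distance error


class CurvatureSummary(NamedTuple):
    median: float  # nm
    lo: float  # 2.5th percentile of sampled R
    hi: float  # 97.5th percentile of sampled R


def radius_from_distance(
    d: float, distance_error: float = DEFAULT_DISTANCE_ERROR_NM
) -> RadiusEstimate:
    """In-plane radius r = (d + 1.5) / sqrt(3) with propagated uncertainty."""
    if d < 0:
        raise ValueError("interblade distance must be non-negative")
    return RadiusEstimate(
        value=(d + LABEL_EDGE_OFFSET_NM) / SQRT3, error=distance_error / SQRT3
    )


def curvature_radius(r: float, h: float) -> float:
    """Spherical-cap curvature radius R = (r^2 + h^2) / (2 h); requires h > 0."""
    if h <= 0:
        raise ValueError("cap height must be positive (R diverges at h = 0)")
    return (r * r + h * h) / (2.0 * h)


def median_curvature(
    r: float,
    h_max: float = 5.0,
    h_min: float = 0.0,
    n_samples: int = 100_000,
    seed=None,
    r_sigma: float | None = None,
) -> CurvatureSummary:
    """Median curvature radius over cap heights sampled uniformly on (h_min, h_max].

    The lower end is open, so h = 0 (R = infinity) is never drawn.  If
    ``r_sigma`` is given, the in-plane radius is additionally propagated as
    r ~ N(r, r_sigma^2).  Returns the median and the 2.5-97.5 percentile
    interval of the sampled R values.
    """
    if r <= 0:
        raise ValueError("in-plane radius must be positive")
    if h_max <= 0 or h_min < 0 or h_min > h_max:
        raise ValueError("need 0 <= h_min <= h_max and h_max > 0")
    rng = np.random.default_rng(seed)
    if h_min == h_max:
        h = np.full(n_samples, h_max)
    else:
        h = h_max - rng.uniform(0.0, h_max - h_min, size=n_samples)  # (h_min, h_max]
    rv = rng.normal(r, r_sigma, size=n_samples) if r_sigma else np.full(n_samples, r)
    big_r = (rv * rv + h * h) / (2.0 * h)
    lo, med, hi = np.percentile(big_r, [2.5, 50.0, 97.5])
    return CurvatureSummary(median=float(med), lo=float(lo), hi=float(hi))
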