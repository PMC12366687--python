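"""Projected-triangle statistics and mixture-model class discovery.

The three fluorophores of a trimer form an equilateral triangle of side d, but
a random 3D orientation shrinks the projected pairwise distances.  The largest
projected side is far less sensitive to this smearing: over all orientations it
stays within [sqrt(3)/2 * d, d], so the per-particle maximum-side statistic
concentrates near the true side length and separates conformational classes
that overlap in the raw pairwise-distance histogram.  Classes are discovered
by fitting 1D Gaussian mixtures to the raw (unbinned) max-side values and
selecting the component count by an information criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.mixture import GaussianMixture

from .localize import LocalizedFluorophore, ParticleProjection
from .simulate import equilateral_vertices

SQRT3 = np.sqrt(3.0)
_PAIRS = ((0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class TriangleGeometry:
    """Pairwise projected distances of one particle and the max-side statistic."""

    d12: float
    d13: float
    d23: float
    d_max: float
    d_max_error: float

    @property
    def distances(self) -> np.ndarray:
        return np.array([self.d12, self.d13, self.d23])


def distance_error(f1: LocalizedFluorophore, f2: LocalizedFluorophore) -> float:
    """Propagated error of a pairwise distance: sqrt(prec1^2 + prec2^2)."""
    return float(np.hypot(f1.precision, f2.precision))


def pairwise_distances(p: ParticleProjection) -> TriangleGeometry:
    """Euclidean distances between the three localizations and the max side.

    The max-side error is propagated from the precisions of the two
    fluorophores spanning the longest side."""
    pos = p.positions
    d = [float(np.linalg.norm(pos[i] - pos[j])) for i, j in _PAIRS]
    imax = int(np.argmax(d))
    i, j = _PAIRS[imax]
    return TriangleGeometry(
        d12=d[0],
        d13=d[1],
        d23=d[2],
        d_max=d[imax],
        d_max_error=distance_error(p.fluorophores[i], p.fluorophores[j]),
    )


def filter_distance_error(particles, cutoff: float = 2.2):
    """Keep particles whose max-side propagated error is below ``cutoff`` nm."""
    return [p for p in particles if pairwise_distances(p).d_max_error < cutoff]


def max_projected_side(side: float, orientations) -> np.ndarray:
    """Max projected side of an ideal equilateral triangle for each orientation.

    ``orientations`` is (n, 3) of (yaw, pitch, roll) degrees; noise-free."""
    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    verts = equilateral_vertices(side)  # (3, 3)
    rots = Rotation.from_euler("ZXY", orientations, degrees=True).as_matrix()
    proj = np.einsum("nij,kj->nki", rots[:, :2, :], verts)  # (n, 3, 2)
    dists = np.stack(
        [np.linalg.norm(proj[:, i] - proj[:, j], axis=1) for i, j in _PAIRS], axis=1
    )
    return dists.max(axis=1)


def max_side_bound_check(side: float, orientations, tol: float = 1e-9) -> np.ndarray:
    """Indices of orientations whose noise-free max projected side falls outside
    the theoretical range [sqrt(3)/2 * side, side]."""
    m = max_projected_side(side, orientations)
    lo = SQRT3 / 2.0 * side - tol
    hi = side + tol
    return np.nonzero((m < lo) | (m > hi))[0]


@dataclass
class GMMFit:
    """Selected 1D Gaussian mixture over max-side values."""

    n_components: int
    means: np.ndarray  # nm, ascending
    sds: np.ndarray
    weights: np.ndarray
    criterion: str
    criterion_scores: dict  # k -> score
    bin_size_display: float
    converged: bool


def fit_gmm(
    values,
    k_range=range(1, 6),
    criterion: str = "aic",
    bin_size_display: float = 1.5,
    n_init: int = 10,
    seed: int = 0,
) -> GMMFit:
    """Fit 1D Gaussian mixtures to raw max-side values and select k.

    EM with ``n_init`` k-means++ style restarts per component count; the
    component count minimizing the chosen information criterion wins, with ties
    broken toward fewer components.  ``bin_size_display`` is carried along for
    plotting only -- the fit never sees binned counts.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 values to fit a mixture")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    scores: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in k_range:
        if len(x) < 2 * k:
            continue
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(x)
        scores[k] = float(gm.aic(x) if criterion == "aic" else gm.bic(x))
        fits[k] = gm
    best_k = min(scores, key=lambda k: (scores[k], k))
    gm = fits[best_k]
    order = np.argsort(gm.means_[:, 0])
    return GMMFit(
        n_components=best_k,
        means=gm.means_[order, 0],
        sds=np.sqrt(gm.covariances_[order, 0, 0]),
        weights=gm.weights_[order],
        criterion=criterion,
        criterion_scores=scores,
        bin_size_display=bin_size_display,
        converged=bool(gm.converged_),
    )
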