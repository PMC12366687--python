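"""Per-state localization, precision filtering and 2D probability maps.

Each dipole state of a particle collects many localization events; their mean
is the fluorophore position and the spread sets the localization precision.
The precision of a position estimated from N events with per-axis event SDs
(sigma_x, sigma_y) is the geometric mean of the two standard errors,

    precision = sqrt( (sigma_x / sqrt(N)) * (sigma_y / sqrt(N)) ),

which reduces to sigma / sqrt(N) for isotropic spread: the longer a state is
occupied, the better its position is known.  A particle's super-resolved 2D
image is the sum of one isotropic Gaussian per fluorophore, each with width
equal to that fluorophore's precision, normalized to unit total probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import PolarizationTrace, StateDecomposition


class GridBoundsError(ValueError):
    """A fluorophore position falls outside the rendering grid."""


@dataclass(frozen=True)
class LocalizedFluorophore:
    """One fluorophore position with spread, event count and precision (nm)."""

    x: float
    y: float
    sigma_x: float
    sigma_y: float
    n_loc: int
    precision: float


@dataclass
class ParticleProjection:
    """One particle: three localized fluorophores in the image plane."""

    particle_id: int
    fluorophores: tuple

    @property
    def positions(self) -> np.ndarray:
        return np.array([[f.x, f.y] for f in self.fluorophores])

    @property
    def precisions(self) -> np.ndarray:
        return np.array([f.precision for f in self.fluorophores])

    @property
    def mean_precision(self) -> float:
        return float(self.precisions.mean())


def localize_state(x, y) -> LocalizedFluorophore:
    """Localize one dipole state from its event coordinates (nm).

    Position is the event mean; sigma_x/sigma_y are sample SDs (ddof=1);
    precision follows the geometric-mean-of-standard-errors formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2 or len(y) != n:
        raise ValueError("localization requires >= 2 events with matching x/y")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    return LocalizedFluorophore(
        x=float(x.mean()),
        y=float(y.mean()),
        sigma_x=sx,
        sigma_y=sy,
        n_loc=n,
        precision=float(np.sqrt((sx / np.sqrt(n)) * (sy / np.sqrt(n)))),
    )


def localize_particle(
    trace: PolarizationTrace, decomposition: StateDecomposition
) -> ParticleProjection:
    """Localize each dipole state of a decomposed trace."""
    fluors = []
    for s in range(decomposition.n_states):
        mask = decomposition.assignments == s
        fluors.append(localize_state(trace.x[mask], trace.y[mask]))
    return ParticleProjection(particle_id=trace.particle_id, fluorophores=tuple(fluors))


def localize_known_fluorophores(events: pd.DataFrame, min_events: int = 2):
    """Localize particles using the ground-truth fluorophore index of each event.

    Bypasses trace decomposition (the generator records which dye produced each
    event); particles missing a fluorophore with ``min_events`` events are
    dropped.  Returns a list of ParticleProjection.
    """
    out = []
    for pid, group in events.groupby("particle_id", sort=True):
        fluors = []
        for f in range(3):
            sub = group[group["fluorophore_index"] == f]
            if len(sub) < max(min_events, 2):
                break
            fluors.append(localize_state(sub["x_nm"].to_numpy(), sub["y_nm"].to_numpy()))
        if len(fluors) == 3:
            out.append(ParticleProjection(particle_id=int(pid), fluorophores=tuple(fluors)))
    return out


def filter_by_precision(
    particles, cutoff: float, max_distance: float | None = None
):
    """Keep particles whose mean localization precision is below ``cutoff`` nm.

    If ``max_distance`` is given, particles whose largest pairwise fluorophore
    distance exceeds it are also dropped (e.g. 45 nm for the mutant dataset)."""
    kept = []
    for p in particles:
        if p.mean_precision >= cutoff:
            continue
        if max_distance is not None:
            pos = p.positions
            dmax = max(
                np.linalg.norm(pos[i] - pos[j]) for i in range(3) for j in range(i + 1, 3)
            )
            if dmax >= max_distance:
                continue
        kept.append(p)
    return kept


def grid_coords(half_size: float, pixel_size: float) -> np.ndarray:
    """Pixel-center coordinates (nm) of a square grid spanning [-half, half]."""
    n = int(round(2 * half_size / pixel_size))
    return (np.arange(n) - (n - 1) / 2.0) * pixel_size


def render_gaussians(
    points: np.ndarray,
    sigmas,
    half_size: float = 48.0,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Render a sum of unit-mass isotropic Gaussians on a square grid.

    ``points`` is (k, 2) in nm, ``sigmas`` scalar or length-k (nm).  The map is
    normalized to unit total sum.  Raises GridBoundsError if a point lies
    outside the grid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (len(points),))
    if np.abs(points).max(initial=0.0) > half_size:
        raise GridBoundsError("point outside rendering grid")
    g = grid_coords(half_size, pixel_size)
    out = np.zeros((len(g), len(g)))
    for (px, py), s in zip(points, sigmas):
        s = max(float(s), 0.25 * pixel_size)  # floor keeps sub-pixel spots visible
        gx = np.exp(-0.5 * ((g - px) / s) ** 2)
        gy = np.exp(-0.5 * ((g - py) / s) ** 2)
        out += np.outer(gy, gx) / (gx.sum() * gy.sum())
    total = out.sum()
    if total <= 0:
        raise GridBoundsError("rendered map has no mass inside the grid")
    return out / total


def render_particle(
    p: ParticleProjection,
    half_size: float = 48.0,
    pixel_size: float = 1.0,
    center: bool = True,
    sigma: float | None = None,
) -> np.ndarray:
    """Render a particle's 2D probability map (row = y, col = x, origin center).

    Each fluorophore is an isotropic Gaussian with width equal to its
    localization precision (or the ``sigma`` override); by default the map is
    centered at the particle centroid.
    """
    pos = p.positions
    if center:
        pos = pos - pos.mean(axis=0)
    widths = p.precisions if sigma is None else np.full(3, float(sigma))
    return render_gaussians(pos, widths, half_size=half_size, pixel_size=pixel_size)
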