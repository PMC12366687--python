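"""Particle orientation by penalized simulated annealing and 3D accumulation.

A classified particle's 2D map is matched against projections of an ideal
equilateral triangle of its class's side length over all rotations (yaw about
the optical z axis, pitch about x, roll about y).  The fitted orientation
minimizes

    objective = -NCC + theta * (pitch + roll)

where NCC is the normalized 2D cross-correlation between the particle map and
the rendered model projection, and the penalty with weight ``theta`` (per
degree) prefers in-plane poses, reflecting that membrane proteins mostly lie in
the imaging plane.  A projection is unchanged by viewing the triangle from the
other side, so pitch and roll are reported folded into [0, 90] degrees.

The module also provides a naive 3D density accumulator that back-rotates each
particle's Gaussians into a common frame and sums them without imposing
symmetry -- a diagnostic, not a resolution claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .localize import ParticleProjection, grid_coords
from .simulate import equilateral_vertices, rotation_matrix

DEFAULT_THETA = 0.005  # per degree: a 10 deg excursion costs 0.1 correlation units


def _triangle_symmetries() -> list:
    """Proper rotations mapping the model triangle onto itself (D3, 6 elements):
    120-degree turns about the triangle normal and 180-degree flips about the
    three in-plane symmetry axes through the vertices."""
    from scipy.spatial.transform import Rotation

    mats = []
    for a in (0.0, 120.0, 240.0):
        mats.append(Rotation.from_euler("z", a, degrees=True).as_matrix())
    for a in (90.0, 210.0, 330.0):
        ax = np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a)), 0.0])
        mats.append(Rotation.from_rotvec(np.pi * ax).as_matrix())
    return mats


_SYMMETRIES = _triangle_symmetries()
_MIRROR_Z = np.diag([1.0, 1.0, -1.0])


def canonical_orientation(yaw: float, pitch: float, roll: float):
    """Canonical (yaw, pitch, roll) among all orientations with the same projection.

    The projected image of an equilateral triangle is unchanged by the
    triangle's own D3 symmetry and by viewing the plane from the other side,
    and a pose and its mirror share every out-of-plane statistic (a tilt about
    a symmetry axis even projects to the self-same isosceles shape).  The
    resulting equivalents share the out-of-plane tilt magnitude but split it
    differently between pitch and roll; the representative with pitch, roll in
    [0, 90] and minimal pitch + roll (the orientation the in-plane penalty
    prefers) is returned.
    """
    from scipy.spatial.transform import Rotation

    rot = rotation_matrix(yaw, pitch, roll)
    tol = 1e-9
    best = None
    for s in _SYMMETRIES:
        y, p, r = Rotation.from_matrix(rot @ s).as_euler("ZXY", degrees=True)
        # view inversion and mirroring flip the signs of pitch/roll (with a
        # compensating yaw flip), so all four sign variants are equivalent
        for py, ry, yy in ((p, r, y), (-p, -r, y), (p, -r, -y), (-p, r, -y)):
            if py < -tol or ry < -tol or ry > 90.0 + tol:
                continue
            key = (py + ry, py, ry, yy % 360.0)
            if best is None or key < best:
                best = key
    if best is None:  # numerically degenerate pose; fall back to folding
        return float(yaw % 360.0), fold_out_of_plane(pitch), fold_out_of_plane(roll)
    _, p, r, y = best
    return float(y), float(np.clip(p, 0.0, 90.0)), float(np.clip(r, 0.0, 90.0))


def fold_out_of_plane(angle: float):
    """Fold an out-of-plane angle into [0, 90] using projection symmetry."""
    a = np.abs((np.asarray(angle) + 90.0) % 180.0 - 90.0)
    return float(a) if np.isscalar(angle) else a


@dataclass
class OrientationEstimate:
    """Fitted particle orientation (degrees) and the objective achieved."""

    particle_id: int
    yaw: float
    pitch: float  # folded into [0, 90]
    roll: float  # folded into [0, 90]
    objective: float
    theta: float
    low_confidence: bool = False
    trace: list | None = None  # optional (temperature, objective) annealing trace


class _ProjectionMatcher:
    """Caches the particle map and renders model projections for scoring.

    Rendering is separable (isotropic Gaussians), so one objective evaluation
    is a handful of small vectorized operations.
    """

    def __init__(
        self,
        particle: ParticleProjection,
        model_side: float,
        pixel_size: float = 1.0,
        half_size: float | None = None,
        sigma: float | None = None,
    ):
        self.verts = equilateral_vertices(model_side)  # (3, 3)
        pos = particle.positions
        pos = pos - pos.mean(axis=0)
        self.sigma = float(sigma if sigma is not None else particle.mean_precision)
        self.sigma = max(self.sigma, 0.25 * pixel_size)
        if half_size is None:
            extent = max(
                float(np.abs(pos).max()), model_side / np.sqrt(3.0)
            ) + 4.0 * self.sigma
            half_size = extent + 2.0 * pixel_size
        self.grid = grid_coords(half_size, pixel_size)
        # particle map: per-fluorophore precision widths, zero-mean unit-norm
        m = np.zeros((len(self.grid), len(self.grid)))
        for (px, py), s in zip(pos, particle.precisions):
            s = max(float(s), 0.25 * pixel_size)
            gx = np.exp(-0.5 * ((self.grid - px) / s) ** 2)
            gy = np.exp(-0.5 * ((self.grid - py) / s) ** 2)
            m += np.outer(gy, gx) / max(gx.sum() * gy.sum(), 1e-300)
        flat = m.ravel() - m.mean()
        self.particle_flat = flat / np.linalg.norm(flat)
        # degenerate if all three spots overlap within the precision
        dists = [np.linalg.norm(pos[i] - pos[j]) for i in range(3) for j in range(i + 1, 3)]
        self.degenerate = max(dists) < particle.mean_precision

    def correlation(self, yaw: float, pitch: float, roll: float) -> float:
        rot = rotation_matrix(yaw, pitch, roll)
        pts = self.verts @ rot.T  # rotated vertices
        m = np.zeros((len(self.grid), len(self.grid)))
        for px, py in pts[:, :2]:
            gx = np.exp(-0.5 * ((self.grid - px) / self.sigma) ** 2)
            gy = np.exp(-0.5 * ((self.grid - py) / self.sigma) ** 2)
            norm = gx.sum() * gy.sum()
            if norm <= 0:
                return -1.0  # model projected outside the grid
            m += np.outer(gy, gx) / norm
        flat = m.ravel() - m.mean()
        n = np.linalg.norm(flat)
        if n == 0:
            return 0.0
        return float(np.dot(self.particle_flat, flat) / n)

    def objective(self, yaw: float, pitch: float, roll: float, theta: float) -> float:
        p = fold_out_of_plane(pitch)
        r = fold_out_of_plane(roll)
        return -self.correlation(yaw, pitch, roll) + theta * (p + r)


def estimate_orientation(
    particle: ParticleProjection,
    model_side: float,
    theta: float = DEFAULT_THETA,
    seed: int = 0,
    n_restarts: int = 20,
    n_steps: int = 200,
    t_start: float = 1.0,
    cooling: float = 0.95,
    proposal_start: float = 10.0,
    proposal_end: float = 1.0,
    pixel_size: float = 1.0,
    half_size: float | None = None,
    sigma: float | None = None,
    keep_trace: bool = False,
) -> OrientationEstimate:
    """Fit (yaw, pitch, roll) by simulated annealing with geometric cooling.

    Each restart anneals from a random orientation with Gaussian angle
    proposals whose SD shrinks geometrically from ``proposal_start`` to
    ``proposal_end`` degrees.  The best state over all restarts is returned;
    results are reproducible for a fixed seed.  Degenerate particles (all
    fluorophores overlapping within the precision) are flagged low-confidence.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    matcher = _ProjectionMatcher(particle, model_side, pixel_size, half_size, sigma)
    rng = np.random.default_rng(seed)
    shrink = (proposal_end / proposal_start) ** (1.0 / max(n_steps - 1, 1))
    best_state, best_obj = None, np.inf
    trace = [] if keep_trace else None
    for _ in range(n_restarts):
        state = np.array(
            [rng.uniform(0, 360), rng.uniform(0, 90), rng.uniform(0, 90)]
        )
        obj = matcher.objective(*state, theta)
        temp = t_start
        prop = proposal_start
        for _ in range(n_steps):
            cand = state + rng.normal(0.0, prop, size=3)
            cand[0] %= 360.0
            cand[1] = fold_out_of_plane(cand[1])
            cand[2] = fold_out_of_plane(cand[2])
            cand_obj = matcher.objective(*cand, theta)
            if cand_obj < obj or rng.random() < np.exp(-(cand_obj - obj) / temp):
                state, obj = cand, cand_obj
            if obj < best_obj:
                best_state, best_obj = state.copy(), obj
            if trace is not None:
                trace.append((temp, obj))
            temp *= cooling
            prop *= shrink
    yaw, pitch, roll = canonical_orientation(*best_state)
    return OrientationEstimate(
        particle_id=particle.particle_id,
        yaw=yaw,
        pitch=pitch,
        roll=roll,
        objective=float(best_obj),
        theta=theta,
        low_confidence=matcher.degenerate,
        trace=trace,
    )


def grid_search_orientation(
    particle: ParticleProjection,
    model_side: float,
    step: float = 10.0,
    theta: float = DEFAULT_THETA,
    pixel_size: float = 1.0,
    half_size: float | None = None,
    sigma: float | None = None,
) -> OrientationEstimate:
    """Exhaustive orientation search on a regular angle grid (oracle baseline)."""
    matcher = _ProjectionMatcher(particle, model_side, pixel_size, half_size, sigma)
    best_state, best_obj = (0.0, 0.0, 0.0), np.inf
    for yaw in np.arange(0.0, 360.0, step):
        for pitch in np.arange(0.0, 90.0 + 1e-9, step):
            for roll in np.arange(0.0, 90.0 + 1e-9, step):
                obj = matcher.objective(yaw, pitch, roll, theta)
                if obj < best_obj:
                    best_state, best_obj = (yaw, pitch, roll), obj
    yaw, pitch, roll = canonical_orientation(*best_state)
    return OrientationEstimate(
        particle_id=particle.particle_id,
        yaw=yaw,
        pitch=pitch,
        roll=roll,
        objective=float(best_obj),
        theta=theta,
        low_confidence=matcher.degenerate,
    )


def orientation_distribution(estimates, bin_width: float = 5.0) -> dict:
    """Normalized pitch/roll histograms over [0, 90] degrees.

    Returns {"edges", "pitch", "roll"}; probabilities sum to 1 per angle."""
    if not estimates:
        raise ValueError("no orientation estimates given")
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    pitch = np.histogram([e.pitch for e in estimates], bins=edges)[0].astype(float)
    roll = np.histogram([e.roll for e in estimates], bins=edges)[0].astype(float)
    return {"edges": edges, "pitch": pitch / pitch.sum(), "roll": roll / roll.sum()}


def accumulate_density(
    particles,
    estimates,
    voxel: float = 1.0,
    half_size: float = 30.0,
) -> np.ndarray:
    """Back-rotate particle Gaussians into a common 3D frame and sum.

    Each localized fluorophore, placed at z = 0 in the image frame, is rotated
    by the inverse of its particle's fitted orientation and accumulated as an
    isotropic 3D Gaussian of width equal to its precision.  No symmetry is
    imposed; the grid is indexed [iz, iy, ix] and normalized to unit sum.
    """
    if not particles:
        raise ValueError("no particles given")
    by_id = {e.particle_id: e for e in estimates}
    g = grid_coords(half_size, voxel)
    n = len(g)
    out = np.zeros((n, n, n))
    used = 0
    for p in particles:
        e = by_id.get(p.particle_id)
        if e is None:
            continue
        rot = rotation_matrix(e.yaw, e.pitch, e.roll)
        pos = p.positions
        pos = pos - pos.mean(axis=0)
        pts3 = np.column_stack([pos, np.zeros(3)]) @ rot  # R^-1 = R.T applied rowwise
        for (px, py, pz), s in zip(pts3, p.precisions):
            s = max(float(s), 0.25 * voxel)
            gx = np.exp(-0.5 * ((g - px) / s) ** 2)
            gy = np.exp(-0.5 * ((g - py) / s) ** 2)
            gz = np.exp(-0.5 * ((g - pz) / s) ** 2)
            norm = gx.sum() * gy.sum() * gz.sum()
            if norm <= 0:
                continue
            out += np.einsum("z,y,x->zyx", gz, gy, gx) / norm
            used += 1
    if used == 0 or out.sum() <= 0:
        raise ValueError("no density accumulated inside the grid")
    return out / out.sum()
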