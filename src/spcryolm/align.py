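"""Rotational template matching, class assignment and aligned averages.

Each particle map is compared against rendered equilateral-triangle templates
(default sides 9, 19 and 34 nm) over all in-plane rotations; the normalized 2D
cross-correlation at the best rotation is the template-matching score in
[0, 1].  Because an equilateral triangle has three-fold symmetry, rotation
angles are meaningful modulo 120 degrees.  Particles whose largest projected
distance exceeds the protein dimension (43 nm) remain unclassified.  Summing
the per-class maps after rotating each to its best alignment yields the
composite "Y-shaped" class average; low-probability outlier pixels (below half
the composite maximum) are suppressed for display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.transform import rotate as _rotate_image

from .localize import ParticleProjection, render_gaussians
from .simulate import equilateral_vertices
from .triangles import pairwise_distances

DEFAULT_TEMPLATE_SIDES = (9.0, 19.0, 34.0)
DEFAULT_SIDE_LABELS = ("i", "ii", "iii")
DEFAULT_DMAX_CUTOFF = 43.0  # nm; beyond the protein dimension
DEFAULT_TEMPLATE_SIGMA = 1.4  # nm; population-median localization precision


def _rot2(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _flat_norm(m: np.ndarray) -> np.ndarray:
    f = m.ravel().astype(float) - m.mean()
    n = np.linalg.norm(f)
    if n == 0:
        raise ValueError("cannot normalize an all-constant map")
    return f / n


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized (Pearson) cross-correlation of two equal-shape maps."""
    return float(np.dot(_flat_norm(a), _flat_norm(b)))


@dataclass
class TemplateBank:
    """Rendered triangle templates over sides and in-plane rotations."""

    sides: tuple
    labels: tuple
    sigma: float
    half_size: float
    pixel_size: float
    angles: np.ndarray  # degrees in [0, 120)
    maps: np.ndarray  # (n_sides, n_angles, H, W)
    flat: np.ndarray  # (n_sides * n_angles, H*W), zero-mean unit-norm rows

    def render_points(self, points: np.ndarray, sigmas) -> np.ndarray:
        return render_gaussians(
            points, sigmas, half_size=self.half_size, pixel_size=self.pixel_size
        )


def build_template_bank(
    sides=DEFAULT_TEMPLATE_SIDES,
    labels=DEFAULT_SIDE_LABELS,
    sigma: float = DEFAULT_TEMPLATE_SIGMA,
    half_size: float = 48.0,
    pixel_size: float = 1.0,
    angle_step: float = 1.0,
) -> TemplateBank:
    """Render an equilateral-triangle template bank over [0, 120) degrees."""
    angles = np.arange(0.0, 120.0, angle_step)
    maps = []
    for side in sides:
        base = equilateral_vertices(side)[:, :2]
        maps.append(
            [
                render_gaussians(base @ _rot2(a).T, sigma, half_size, pixel_size)
                for a in angles
            ]
        )
    maps = np.asarray(maps)
    flat = np.stack([_flat_norm(m) for m in maps.reshape(-1, *maps.shape[2:])])
    return TemplateBank(
        sides=tuple(sides),
        labels=tuple(labels),
        sigma=sigma,
        half_size=half_size,
        pixel_size=pixel_size,
        angles=angles,
        maps=maps,
        flat=flat,
    )


def align_rotation(
    image: np.ndarray,
    template: np.ndarray,
    step: float = 1.0,
    refine: bool = True,
    symmetry_fold: float | None = 120.0,
) -> tuple[float, float]:
    """In-plane rotation of ``template`` that best matches ``image``.

    Scans [0, 360) at ``step`` degrees with optional golden-section refinement
    of the best bracket; returns (angle, correlation).  For three-fold symmetric
    templates the angle is reported modulo ``symmetry_fold`` (default 120).
    """
    if image.shape != template.shape:
        raise ValueError("image and template must share a grid")
    img_flat = _flat_norm(image)  # raises on an all-zero map

    def corr(angle: float) -> float:
        rot = _rotate_image(template, -angle, order=3, preserve_range=True)
        return float(np.dot(img_flat, _flat_norm(rot)))

    angles = np.arange(0.0, 360.0, step)
    scores = np.array([corr(a) for a in angles])
    best = int(np.argmax(scores))
    angle, score = float(angles[best]), float(scores[best])
    if refine and len(angles) > 2:
        res = minimize_scalar(
            lambda a: -corr(a),
            bounds=(angle - step, angle + step),
            method="bounded",
            options={"xatol": 1e-3},
        )
        if -res.fun > score:
            angle, score = float(res.x), float(-res.fun)
    if symmetry_fold:
        angle %= symmetry_fold
    return angle, score


@dataclass
class ClassAssignment:
    """Template-matching result for one particle."""

    particle_id: int
    class_label: str  # one of the bank labels or "unclassified"
    score: float
    rotation_deg: float  # best in-plane rotation, modulo 120
    d_max: float


def _particle_flat(p: ParticleProjection, bank: TemplateBank) -> np.ndarray:
    pos = p.positions
    m = bank.render_points(pos - pos.mean(axis=0), p.precisions)
    return _flat_norm(m)


def classify_particles(
    particles,
    bank: TemplateBank | None = None,
    d_max_cutoff: float = DEFAULT_DMAX_CUTOFF,
    score_floor: float | None = None,
) -> list[ClassAssignment]:
    """Assign each particle to the best-matching template class.

    A particle is unclassified when its max side exceeds ``d_max_cutoff`` nm or
    (optionally) when its best score falls below ``score_floor``.  Rotation is
    resampling-free: the particle is re-rendered from its fluorophore
    coordinates, so scores are exactly invariant to in-plane rotation and
    translation of the input.
    """
    bank = bank or build_template_bank()
    n_angles = len(bank.angles)
    out = []
    for p in particles:
        geom = pairwise_distances(p)
        if geom.d_max > d_max_cutoff:
            out.append(
                ClassAssignment(p.particle_id, "unclassified", 0.0, 0.0, geom.d_max)
            )
            continue
        scores = bank.flat @ _particle_flat(p, bank)
        best = int(np.argmax(scores))
        side_idx, angle_idx = divmod(best, n_angles)
        score = float(scores[best])
        label = bank.labels[side_idx]
        if score_floor is not None and score < score_floor:
            label = "unclassified"
        out.append(
            ClassAssignment(
                p.particle_id, label, score, float(bank.angles[angle_idx]), geom.d_max
            )
        )
    return out


def classify_template(
    p: ParticleProjection,
    bank: TemplateBank | None = None,
    d_max_cutoff: float = DEFAULT_DMAX_CUTOFF,
    score_floor: float | None = None,
) -> ClassAssignment:
    """Classify a single particle (see classify_particles)."""
    return classify_particles([p], bank, d_max_cutoff, score_floor)[0]


def class_fractions(assignments) -> tuple[dict, int]:
    """Fractional weight of each class over classified particles.

    Returns (fractions, n_unclassified); fractions sum to 1.  Raises on empty
    input or when nothing was classified."""
    if not assignments:
        raise ValueError("no assignments given")
    labels = [a.class_label for a in assignments]
    n_unclassified = labels.count("unclassified")
    classified = [lab for lab in labels if lab != "unclassified"]
    if not classified:
        raise ValueError("no classified particles")
    keys = sorted(set(classified), key=lambda lab: labels.index(lab))
    fracs = {k: classified.count(k) / len(classified) for k in keys}
    return fracs, n_unclassified


def sum_aligned(
    particles,
    assignments,
    class_label: str,
    bank: TemplateBank | None = None,
    suppress_below: float = 0.5,
) -> np.ndarray:
    """Composite map of one class: rotate members to alignment and average.

    Each particle's fluorophore coordinates are rotated by the negative of its
    best template angle (exact, no image resampling), re-rendered, and
    averaged.  Pixels of the average below ``suppress_below`` times its maximum
    are zeroed (outlier suppression for display) before renormalization.
    """
    bank = bank or build_template_bank()
    by_id = {a.particle_id: a for a in assignments}
    maps = []
    for p in particles:
        a = by_id.get(p.particle_id)
        if a is None or a.class_label != class_label:
            continue
        pos = p.positions
        pos = (pos - pos.mean(axis=0)) @ _rot2(-a.rotation_deg).T
        maps.append(bank.render_points(pos, p.precisions))
    if not maps:
        raise ValueError(f"no particles assigned to class {class_label!r}")
    avg = np.mean(maps, axis=0)
    if suppress_below:
        avg = np.where(avg < suppress_below * avg.max(), 0.0, avg)
    return avg / avg.sum()
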