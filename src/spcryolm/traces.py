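"""Spot detection and polarization trace decomposition.

A diffraction-limited spot (PSF) of a labeled trimer contains up to three
fluorophores whose frozen dipoles give distinct, stable two-channel intensity
ratios.  The polarization value p = I_ch1 / (I_ch1 + I_ch2) of the on-events of
one spot therefore hops between a few discrete levels, one per dye.  This
module detects candidate spots in raw frames and decomposes each spot's trace
of on-events into discrete dipole states in two stages:

1. divisive change-point segmentation of the 1D polarization signal, scored
   with a BIC penalty (``alpha`` scales the penalty), followed by agglomerative
   merging of segment levels while the BIC keeps improving;
2. refinement by a Gaussian mixture over polarization and event coordinates
   jointly, which can also split dyes with identical azimuth but distinct
   positions; the final state count minimizes the mixture BIC.

Particles with exactly three states and sufficient polarization signal-to-noise
ratio are retained for localization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max
from sklearn.mixture import GaussianMixture

_EPS = 1e-12


@dataclass
class PolarizationTrace:
    """Ordered on-events of one particle: frame, position, polarization, photons."""

    particle_id: int
    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    p: np.ndarray
    photons: np.ndarray

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "PolarizationTrace":
        """Build a trace from an event table of a single particle.

        Off-times are implicit (only on-events are stored); zero-photon rows
        are dropped; events are sorted by frame."""
        pid = events["particle_id"].unique()
        if len(pid) != 1:
            raise ValueError("expected events from exactly one particle")
        total = (events["counts_ch1"] + events["counts_ch2"]).to_numpy()
        keep = total > 0
        ev = events.loc[keep].sort_values("frame", kind="stable")
        total = (ev["counts_ch1"] + ev["counts_ch2"]).to_numpy(dtype=float)
        return cls(
            particle_id=int(pid[0]),
            frame=ev["frame"].to_numpy(),
            x=ev["x_nm"].to_numpy(dtype=float),
            y=ev["y_nm"].to_numpy(dtype=float),
            p=ev["counts_ch1"].to_numpy(dtype=float) / total,
            photons=total,
        )


@dataclass
class StateDecomposition:
    """Result of decomposing one trace into discrete dipole states."""

    particle_id: int
    n_states: int
    assignments: np.ndarray  # per-event state index, states sorted by mean p
    state_means: np.ndarray  # mean polarization per state, ascending
    criterion_scores: dict  # candidate state count -> mixture BIC
    snr: float


def detect_spots(
    image: np.ndarray,
    low_pass: float = 0.3,
    high_pass: float = 3.0,
    threshold: float = 10.0,
) -> np.ndarray:
    """Detect PSF candidates as local maxima of a band-pass filtered image.

    The band-pass is a difference of Gaussians with sigmas ``low_pass`` (noise
    suppression) and ``high_pass`` (background suppression), both in pixels;
    maxima below ``threshold`` in the filtered image are discarded.  Returns an
    (n, 2) array of (row, col) pixel coordinates.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    band = gaussian_filter(img, low_pass) - gaussian_filter(img, high_pass)
    band = np.clip(band, 0.0, None)
    return peak_local_max(
        band,
        min_distance=max(1, int(round(high_pass))),
        threshold_abs=threshold,
        exclude_border=False,
    )


def _best_split(p: np.ndarray) -> tuple[int, float]:
    """Best single change point of a segment: index k (split before k) and the
    resulting residual sum of squares, minimized over k."""
    n = len(p)
    c1 = np.cumsum(p)
    c2 = np.cumsum(p * p)
    k = np.arange(1, n)
    left_rss = c2[k - 1] - c1[k - 1] ** 2 / k
    right_n = n - k
    right_sum = c1[-1] - c1[k - 1]
    right_sq = c2[-1] - c2[k - 1]
    right_rss = right_sq - right_sum**2 / right_n
    rss = left_rss + right_rss
    j = int(np.argmin(rss))
    return int(k[j]), float(rss[j])


def _divisive_segments(p: np.ndarray, alpha: float) -> np.ndarray:
    """Top-down change-point segmentation with a BIC stopping rule.

    A split is accepted while it lowers n*log(RSS/n) by more than
    alpha * 2 * log(N) (one extra level plus one change point)."""
    n_total = len(p)
    penalty = alpha * 2.0 * np.log(n_total)
    labels = np.zeros(n_total, dtype=int)
    stack = [(0, n_total)]
    next_label = 1
    while stack:
        i, j = stack.pop()
        m = j - i
        if m < 4:
            continue
        seg = p[i:j]
        rss0 = float(np.sum((seg - seg.mean()) ** 2))
        k, rss1 = _best_split(seg)
        gain = m * np.log((rss0 + _EPS) / m) - m * np.log((rss1 + _EPS) / m)
        if gain > penalty:
            labels[i + k : j] = next_label
            next_label += 1
            stack.append((i, i + k))
            stack.append((i + k, j))
    # relabel contiguous segments consecutively
    change = np.nonzero(np.diff(labels) != 0)[0]
    out = np.zeros(n_total, dtype=int)
    for s, start in enumerate(np.concatenate([[0], change + 1])):
        end = change[s] + 1 if s < len(change) else n_total
        out[start:end] = s
    return out


def _merge_segments(p: np.ndarray, seg_labels: np.ndarray, alpha: float, max_states: int):
    """Agglomeratively merge segment levels into states while BIC improves."""
    n = len(p)

    def bic(labels: np.ndarray) -> float:
        rss = 0.0
        for lab in np.unique(labels):
            v = p[labels == lab]
            rss += float(np.sum((v - v.mean()) ** 2))
        k = len(np.unique(labels))
        return n * np.log((rss + _EPS) / n) + alpha * 2.0 * k * np.log(n)

    labels = seg_labels.copy()
    while True:
        uniq = np.unique(labels)
        means = np.array([p[labels == u].mean() for u in uniq])
        if len(uniq) <= 1:
            break
        order = np.argsort(means)
        gaps = np.diff(means[order])
        a, b = uniq[order[np.argmin(gaps)]], uniq[order[np.argmin(gaps) + 1]]
        merged = labels.copy()
        merged[merged == b] = a
        if len(uniq) > max_states or bic(merged) <= bic(labels):
            labels = merged
        else:
            break
    uniq = np.unique(labels)
    means = np.array([p[labels == u].mean() for u in uniq])
    return means[np.argsort(means)]


def decompose_trace(
    trace: PolarizationTrace,
    max_states: int = 5,
    alpha: float = 1.0,
    seed: int = 0,
) -> StateDecomposition:
    """Decompose a polarization trace into discrete dipole states.

    Stage 1 segments the polarization signal by divisive change-point splitting
    with a BIC penalty scaled by ``alpha`` and merges segment levels into
    candidate states.  Stage 2 fits Gaussian mixtures over (p, x, y) jointly
    (coordinates standardized to the trace's positional SD) for every candidate
    state count and keeps the BIC minimizer; stage-1 level means seed one of
    the initializations.
    """
    n = len(trace)
    if n == 0:
        raise ValueError("cannot decompose an empty trace")
    if max_states < 1:
        raise ValueError("max_states must be >= 1")
    max_states = min(max_states, n)

    # Anscombe-stabilized polarization: binomial noise on p is skewed near 0/1
    # and has point masses at exactly 0 and 1 (all photons in one channel),
    # which a Gaussian model would oversplit into spurious states
    n_ph = np.maximum(trace.photons, 1.0)
    c1 = np.clip(trace.p, 0.0, 1.0) * n_ph
    z = 2.0 * np.arcsin(np.sqrt((c1 + 0.375) / (n_ph + 0.75)))
    seg_labels = _divisive_segments(z, alpha)
    stage1_means = _merge_segments(z, seg_labels, alpha, max_states)

    p_sd = max(float(np.std(z)), _EPS)
    pos_var = 0.5 * (np.var(trace.x) + np.var(trace.y))
    pos_sd = max(float(np.sqrt(pos_var)), _EPS)
    feats = np.column_stack(
        [
            (z - z.mean()) / p_sd,
            (trace.x - trace.x.mean()) / pos_sd,
            (trace.y - trace.y.mean()) / pos_sd,
        ]
    )

    scores: dict[int, float] = {}
    best = None
    for k in range(1, max_states + 1):
        if n < 2 * k:
            break
        fits = []
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=4,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(feats)
        fits.append(gm)
        if k == len(stage1_means) and k > 1:
            # seed means from stage 1 (polarization levels, coordinates at center)
            means_init = np.zeros((k, 3))
            means_init[:, 0] = (stage1_means - z.mean()) / p_sd
            gm2 = GaussianMixture(
                n_components=k,
                covariance_type="full",
                means_init=means_init,
                random_state=seed,
                reg_covar=1e-6,
            ).fit(feats)
            fits.append(gm2)
        gm_best = min(fits, key=lambda g: g.bic(feats))
        score = float(gm_best.bic(feats))
        scores[k] = score
        if best is None or score < best[0]:
            best = (score, k, gm_best)

    _, n_states, gm = best
    raw = gm.predict(feats)
    # sort states by mean polarization, relabel ascending, drop empty components
    occupied = np.unique(raw)
    means = np.array([trace.p[raw == s].mean() for s in occupied])
    order = np.argsort(means)
    remap = {int(occupied[o]): i for i, o in enumerate(order)}
    assignments = np.array([remap[int(s)] for s in raw])
    state_means = means[order]
    n_states = len(occupied)

    snr = 0.0
    if n_states > 1:
        within = [
            np.std(trace.p[assignments == s], ddof=1)
            for s in range(n_states)
            if np.sum(assignments == s) >= 2
        ]
        mean_within = float(np.mean(within)) if within else _EPS
        snr = float((state_means[-1] - state_means[0]) / max(mean_within, _EPS))
    return StateDecomposition(
        particle_id=trace.particle_id,
        n_states=n_states,
        assignments=assignments,
        state_means=state_means,
        criterion_scores=scores,
        snr=snr,
    )


def select_three_state(
    decompositions: list[StateDecomposition], min_snr: float = 3.5
) -> list[StateDecomposition]:
    """Keep particles with exactly three dipole states and SNR above threshold.

    The SNR is (max state mean - min state mean) / mean within-state SD of the
    polarization value."""
    return [d for d in decompositions if d.n_states == 3 and d.snr > min_snr]
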