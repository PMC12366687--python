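# Methods

This note documents the models, parameter choices and numerical decisions
behind `spcryolm`, and what the synthetic-data tests do and do not establish
about real microscope data.

## Physical model of the synthetic data

A particle is a trimer whose three labeled blade tips form an equilateral
triangle of side d, drawn from three conformational classes (defaults
d = 9, 19, 34 nm with weights 0.21/0.51/0.28).  The triangle is rotated by
intrinsic z–x–y Euler angles (yaw about the optical axis, pitch about x, roll
about y, in degrees) and projected orthographically onto the image plane.

**Orientations.**  `uniform` draws Haar-random rotations (via normalized
random quaternions).  `in_plane_biased` models membrane proteins lying mostly
in the plane: yaw ~ U[0, 360°), pitch and roll half-normal on [0°, 90°] with
SD = 90°/concentration.  The default concentration 9 (SD 10°) reproduces a
strong peak of out-of-plane angles at 0° while leaving a realistic tail of
tilted particles; only the qualitative shape of this distribution is
experimentally constrained.

**Blinking.**  Each fluorophore alternates between exponential on and off
dwells (memoryless kinetics, the minimal model consistent with the observed
fast blinking).  Defaults: mean on-time 20 ms, mean off-time 200 ms (off/on
ratio 10; frames are >5× shorter than the typical off-time), photon rate
5000/s, frame time 14 ms, so an on-frame carries Poisson photons with mean 70.
A frame counts as "on" when the dye is on at the frame midpoint.

**Polarization.**  Dipole azimuths are fixed per dye, uniform on [0°, 180°).
Channel 1 receives a binomial share of each frame's photons with probability
cos²(azimuth) — the Malus-law contract of a two-channel polarizing splitter.
Note cos² maps azimuths θ and 180°−θ to the same ratio, so only dyes with
distinct cos² values are separable by polarization alone.

**Event noise.**  Each on-frame yields one localization event at the projected
vertex plus isotropic Gaussian noise, SD 10 nm per axis.  With the default
520-frame movies a fluorophore collects ~47 events, putting the final
localization precision near 1.4 nm and the median propagated max-side distance
error near 2.1 nm — the working point of the downstream filters (2 nm
precision cutoff, 2.2 nm error cutoff).  A single isotropic event SD cannot
reproduce the experimental precision and error medians exactly simultaneously;
the chosen value brackets both.

## Trace decomposition

Stage 1 segments the 1D polarization signal top-down: the best change point of
a segment is accepted while it lowers n·log(RSS/n) by more than
α·2·log(N) (α = 1 by default, scaling the BIC penalty), and the resulting
segment levels are merged agglomeratively while the same criterion improves.
Stage 2 refits assignments with Gaussian mixtures over (p, x, y) jointly —
coordinates standardized by the trace's positional SD — for every candidate
state count up to `max_states`, selecting the BIC minimizer; stage-1 levels
seed one initialization.  The joint refit can split dyes with identical
polarization but distinct positions.

Internally both stages operate on an Anscombe-stabilized polarization value
2·arcsin(√((c₁+3/8)/(n+3/4))): the raw ratio p = c₁/(c₁+c₂) is skewed near 0
and 1 and has point masses at exactly 0 and 1 (all photons in one channel),
which a Gaussian model would oversplit into spurious states.  Reported state
means remain on the raw p scale.

The trace SNR — not defined experimentally — is fixed here as
(max state mean − min state mean) / mean within-state SD of p; three-state
particles with SNR > 3.5 are retained.

## Localization precision

The precision of a position from N events with per-axis sample SDs σx, σy is
the geometric mean of the two standard errors, √((σx/√N)(σy/√N)).  This
reading is dimensionally correct, reduces to σ/√N for isotropic spread, and
decreases with state occupancy; it is isolated in `localize_state` should a
different combination be preferred.

## Class discovery and classification

The max-side statistic is computed from raw localized positions; Gaussian
mixtures are fitted to the raw values (never to binned counts; bin sizes
1.5/1.47/2 nm are display conventions only) with 10 k-means++ restarts per
component count and ties broken toward fewer components.  AIC is the default
criterion; BIC is available.  Because the per-class max-side distribution is
left-skewed by projection and right-biased by taking a maximum of noisy
distances, fitted means sit ~1 nm above the true side and AIC occasionally
adds a fourth component on unfiltered data; the distance-error filter
(< 2.2 nm) applied before fitting removes most of this.

Templates are equilateral triangles rendered with fluorophore width 1.4 nm
(the population-median precision; the experimental template width is not
documented) on a 96×96 grid at 1 nm/pixel, over in-plane angles [0°, 120°) in
1° steps — the equilateral ambiguity makes angles meaningful only modulo 120°.
Particles are re-rendered from their fluorophore coordinates at each candidate
rotation, so matching scores are exactly invariant to in-plane rotation and
translation (no image resampling).  A particle with max side > 43 nm (beyond
the protein dimension) is left unclassified; an optional score floor exists
but is off by default.  Class averages rotate each member to its best
alignment, average, suppress pixels below 0.5× the maximum (outlier
suppression for display) and renormalize.

## Orientation estimation

The objective is −NCC + ϑ·(pitch + roll), with the model triangle rendered at
the particle's Gaussian widths on the particle's grid.  Defaults (none are
experimentally documented): ϑ = 0.005 per degree — a combined 20° out-of-plane
excursion costs 0.1 correlation units, enough to break flat-landscape ties
without overriding clear tilts (a genuinely tilted particle at ~30° loses
~0.13 correlation when forced flat, so ϑ ≥ 0.005 begins to flatten such fits;
this trade-off is deliberate and configurable); annealing from T = 1.0 with
geometric cooling 0.95 over 200 steps, Gaussian proposals annealed from 10° to
1°, 20 restarts.

A projected equilateral triangle does not determine the pose uniquely: the
triangle's own D3 symmetry, viewing the plane from the other side, and — for
tilts about a triangle symmetry axis — mirror symmetry of the isosceles
projection all yield equivalent poses that share the out-of-plane tilt
magnitude (cos pitch · cos roll) but split it differently between pitch and
roll.  Estimates are therefore canonicalized to the equivalent with pitch,
roll ∈ [0°, 90°] and minimal pitch + roll — exactly the representative the
in-plane penalty prefers.  Orientation histograms (5° bins) and any
comparison against ground truth must use the same canonical form.

The density accumulator back-rotates each particle's Gaussians into a common
frame at z = 0 and sums them without imposing C3 symmetry.  It is a
diagnostic for orientation consistency, not a reconstruction: no likelihood
model, no resolution estimate.

## Dome geometry

r = (d + 1.5)/√3 converts an interblade distance to the in-plane radius of
the blade-tip circle: d/√3 is the circumradius of an equilateral triangle of
side d, and 1.5 nm is the label-to-blade-edge offset.  The propagated radius
uncertainty is (distance error)/√3 ≈ 1.33 nm at the 2.3-nm working error.
R = (r² + h²)/(2h) is the spherical-cap curvature radius, minimal (R = r) at
h = r and divergent at h → 0.  `median_curvature` samples h uniformly on the
open-bottom interval (0, h_max] (h = 0 never drawn), optionally propagates
r ~ N(r, σ²), and reports the median with a 2.5–97.5 percentile interval of
the sampled values; how the experimental 95 % intervals were constructed is
not documented, so the percentile interval is this package's convention.

## Blade scans

`rigid_body_scan` rotates the sub-chain from the N terminus to the pivot
rigidly about either the vertical axis through the pivot (in-plane) or the
in-plane axis through the pivot perpendicular to the blade direction
(out-of-plane), rebuilds the trimer by 120° replication about the central
axis, and measures the probe-probe distance — by construction rigidity holds
to machine precision and the pivot is fixed exactly.  Coordinates from
PDB/mmCIF files load in ångströms and convert to nanometers.

## Test problem sizes

The test suite validates the projection bound on 10⁵ uniform orientations
against a 2·10⁴-point view-direction grid oracle; class recovery on twenty
378-particle populations; trace decomposition on 50 traces at the 70
photons/frame budget; and orientation recovery on 30 tilted particles plus a
120-particle biased population, with annealing checked against a 10°
exhaustive grid.  These sizes keep the full suite under a few minutes while
leaving the statistical margins of each check comfortable.

## What the synthetic tests do not show

The generator omits camera noise and PSF overlap between neighboring
particles, drift, background and autofluorescence, labeling efficiency and
partial labeling (particles with fewer than three dyes), anisotropic or
photon-limited localization errors, and any coupling between dipole
orientation and detection efficiency.  Passing tests therefore demonstrate
the correctness and statistical behavior of the analysis under its stated
assumptions — not the end-to-end performance on raw microscope movies.
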