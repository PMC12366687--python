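# spcryolm

Single-particle cryo-light-microscopy (spCryo-LM) analysis of trimeric
membrane proteins labeled with one fluorophore per protomer — built around the
conformational-state analysis of the mechanosensitive channel PIEZO1, whose
three propeller-like "blades" carry a label near each blade tip.

At liquid-helium temperature each dye's emission dipole is frozen at a random
orientation, so a two-channel polarization splitter assigns the photons of a
diffraction-limited spot to individual fluorophores.  From the resulting
blinking traces the package localizes each blade tip with nanometer precision
and asks: what triangle do the three tips form, how is the trimer oriented in
the membrane, and what does that imply for the curvature of the surrounding
membrane dome?

The package is aimed at microscopists and structural biologists who want a
tested, self-contained implementation of this pipeline, together with a
synthetic-data generator that reproduces the statistical structure of the
experiment so every stage can be validated without microscope data.

## The analysis

1. **Simulation** (`simulate`): trimer populations with equilateral side
   lengths d ~ 9/19/34 nm mixed 21/51/28 %, random in-plane-biased 3D
   orientations, frozen dipole azimuths, exponential blinking with off/on
   ratio ~10 and ~5000 photons/s at 14-ms frames, Gaussian event noise.
2. **Traces** (`traces`): band-pass spot detection; decomposition of each
   polarization trace into discrete dipole states (divisive change-point
   segmentation with a BIC penalty, refined by a Gaussian mixture over
   polarization and coordinates jointly); selection of three-state particles
   with polarization SNR > 3.5.
3. **Localization** (`localize`): per-state positions with precision
   sqrt((σx/√N)(σy/√N)); precision filtering (< 2 nm); rendered 2D
   probability maps (one Gaussian per fluorophore, width = its precision).
4. **Triangle statistics** (`triangles`): pairwise projected distances and the
   **maximum-side statistic** — for a randomly oriented equilateral triangle
   the largest projected side always stays within [√3·d/2, d], so it resists
   projection smearing; distance errors √(σ₁²+σ₂²) and the < 2.2 nm filter;
   Gaussian-mixture class discovery on raw max-side values (AIC/BIC).
5. **Classification** (`align`): rotational template matching against
   9/19/34 nm triangle templates (normalized cross-correlation, score in
   [0, 1], angles modulo 120°), a 43-nm unclassified cutoff, class fractions,
   and aligned class-average maps.
6. **Orientation** (`orientation`): per-particle (yaw, pitch, roll) by
   simulated annealing of `-NCC + ϑ(pitch + roll)`, out-of-plane angle
   distributions, and a naive back-rotated 3D density accumulator.
7. **Dome geometry** (`dome`, `blades`): r = (d + 1.5)/√3,
   R = (r² + h²)/(2h), median R over an uncertain dome height, and rigid-body
   blade rotation scans about an elbow pivot on PDB/mmCIF or toy coordinates.

## Worked example

```sh
python examples/class_discovery.py
```

```
particles kept (error < 2.2 nm): 277 of 378
classes selected by AIC        : 3 (true: 3)
  d =  10.7 +-  1.5 nm, weight 0.25
  d =  20.3 +-  1.7 nm, weight 0.46
  d =  34.8 +-  1.7 nm, weight 0.29
```

A 378-particle synthetic population is localized, filtered to distance errors
below 2.2 nm, and the max-side mixture model selects three conformational
classes with means near the true 9/19/34 nm sides (biased slightly upward by
noise on the maximum) and weights near the true 21/51/28 % mix.

```sh
python examples/dome_geometry.py
```

```
class   d (nm)   r (nm)
i          9.0    6.06 +- 1.33
ii        19.0   11.84 +- 1.33
iii       34.0   20.50 +- 1.33
ii-mut    24.0   14.72 +- 1.33

R(r=6,  h=5.5) =    6.0 nm  (highly curved class i)
R(r=20, h=1.0) =  200.5 nm  (nearly flat class iii)
median R over h in (0, 5] nm at r = 12: 30.0 nm [17, 567] (intermediate class ii)
```

The three classes convert to in-plane radii of ~6, ~12 and ~20 nm and map onto
a highly curved (R ≈ 6 nm), an intermediate (median R ≈ 30 nm) and a nearly
flat membrane-dome state.  The other scripts in `examples/` demonstrate the
simulator, trace decomposition, template classification, orientation fitting
and the blade-rotation scan, each printing the numbers it computes.

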