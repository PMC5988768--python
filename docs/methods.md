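# Methods

## Forward model

The sample arm is modelled in Jones calculus.  The source light enters
vertically polarised, a quarter-wave plate at 45° circularises it, and the
tissue acts as a linear retarder whose retardance grows with the
birefringence integrated along the optical path.  The detected field is

    E_det = QWP(45°) · J(π/2 + 2 ψ(z), θ(z)) · QWP(45°) · E_V ,

where `J(Δ, θ)` is the linear-retarder operator and

    ψ(z) = (2π/λ₀) · 2 ∫₀ᶻ Δn(z′) dz′

is the *round-trip* retardation accumulated down to physical depth `z`
(air-path pixels are converted to physical tissue depth with n = 1.36).  The
closed form of this chain gives channel amplitudes

    A_V = s(z) · |sin(π/4 + ψ(z))| ,   A_H = s(z) · |cos(π/4 + ψ(z))| ,

with `s(z)` the backscatter profile, independent of the optic-axis map θ —
the axis independence that circular incidence is designed to provide, and
which the virtual Berek experiment verifies on a 19 × 19 (retardance × axis)
grid to < 10⁻⁹ degrees.  The arctan read-out therefore starts at π/4 in
isotropic tissue (a preserved circular state splits equally at the
polarising beamsplitter), climbs at 2π·2Δn/λ₀ per unit physical depth, and
folds at π/2.

Whether a physical instrument reports single- or double-pass retardance is a
convention; we fix the round-trip convention once, expose it as the inverse
pair `brc_for_dn`/`dn_for_brc`, and calibrate every synthetic tissue through
it.  Recovered gradients are then convention-independent: the pipeline is
judged against the configured truth, not against a particular hardware
convention.

The retarder algebra is exercised directly (unitarity, quarter+quarter =
half wave, identity at zero retardance), and the vectorised amplitude
formula is tested against the explicit matrix chain on random (ψ, θ).

### Speckle

Amplitude speckle is multiplicative per channel and pixel:
`A → A · (1 + σ (r − 1))` with `r` unit-mean Rayleigh distributed — a damped
form of the standard coherent-imaging amplitude statistics that keeps the
noisy mean equal to the noiseless A-scan (tested at the 1/√N rate).  Pixels
outside tissue carry only an additive Rayleigh noise floor (relative
amplitude 0.01).  The default σ = 0.06 gives a single-A-scan retardation SD
of ≈ 1.3° at mid-fold, the same scale as the repeatability reported for the
instrument's Berek validation sweeps (0.7°–1.6°).  σ was chosen jointly with
the smoothing window (below) so that the pipeline's rectified-noise floor on
a zero-birefringence sample stays below 0.5 rad/mm — comfortably under the
smallest group mean (1.1 rad/mm) — while the noiseless fold bias stays below
5 %.  No axial speckle correlation, k-space reconstruction, dispersion or
roll-off is modelled.

## Synthetic tissue

A `TissueModel` holds Δn, optic axis, backscatter and surface height on a
5 µm × 20 µm (depth × lateral) physical grid.  Grade presets carry the
published per-group BRC mean ± between-sample SD (three grades × three
configurations) and group sizes 10/8/8; each specimen's true BRC is drawn
from a normal truncated at zero (a BRC cannot be negative; the truncation
point is ~2.6 SD below the smallest mean, so the moment distortion is < 1 %,
verified empirically on 10⁴ draws).  The grade → Δn mapping is
phenomenological — Δn is set by `dn_for_brc(truth)` — because no
microstructural model of fibre destructuring is available; the generator is
a statistical contract, not a biomechanical simulation.

Indented-configuration models have a cosine surface bulge inside the 1 mm
channel gap (default bulge height 0.3 mm, a documented assumption), Δn
relaxed to 30 % at the bulge centre and full under the indenter flanks, and
an asymmetric lateral modulation (factor 0.15) mimicking the asymmetric
banding around the bulge.  The modulation is normalised to exactly 1 at the
default analysis position — the bulge shoulder, channel edge + 0.25 mm — so
the configured truth is what an ideal measurement recovers there.  The
analysis A-scan is an explicit parameter (the original analysis was
operator-selected); non-indented and XY models are laterally uniform with a
flat surface.  Other defaults: uncompressed thickness 2 mm (typical bovine
patellar cartilage; the source states block size only), creep strain 0.56,
flat-surface offset 0.35 mm of air path, backscatter 1/e depth 1 mm.

What the generator does *not* emulate: depth-dependent collagen zonation,
poroelastic mechanics, axis-map effects on the measurement (axis-independent
by construction), attenuation anisotropy, or inter-B-scan tissue variation
(adjacent B-scans differ only by speckle).  Passing tests therefore show
that the *pipeline* recovers configured gradients under realistic noise and
geometry; they cannot certify behaviour on structural features the
generator lacks.

## Pipeline numerical choices

- **Lateral averaging**: mean retardation over 10 A-scans (200 µm), clipped
  with a warning at image edges.
- **Surface**: first pixel exceeding 0.5 × the column maximum of the
  window-averaged intensity.  **Maximum depth**: the forward-looking 3-pixel
  mean of intensity is compared against 0.05 × the at-surface value; the
  evaluated range ends at the first drop (or the image bottom).  Neither
  threshold is stated in the source; both are settings and are swept in the
  sensitivity tests (halving/doubling either moves the recovered BRC by
  < 5 %).
- **Depth calibration**: 5 µm air pixels → 5/1.36 ≈ 3.68 µm of tissue.
- **Smoothing**: centred running average, window 5 pixels, shrinking
  symmetrically at the segment edges (a moving average of a linear ramp is
  the ramp, so edges add no bias on unfolded stretches).  Window width
  trades fold-peak rounding (loss ≈ 2a·h(h+1)/w of total variation per
  extremum for slope a/pixel, h = (w−1)/2) against noise rectification
  (floor ∝ 1/w); w = 5 keeps the noiseless bias ≤ ~4 % at 6 rad/mm over the
  0.68 mm evaluated depth while holding the noise floor at ≈ 0.43 rad/mm.
- **Gradient**: Σ|δᵢ₊₁ − δᵢ| over the smoothed folded segment divided by its
  physical span (N − 1 pixel intervals).  No unwrapping: the fold preserves
  every increment except at turning pixels (each fold loses ≤ 2a), which the
  property tests quantify by brute-force comparison of folded and unfolded
  sums.
- **Aggregation**: arithmetic mean over the 5 B-scans (25 µm apart); the
  source states only that a final value was determined per sample.
- **Degenerate inputs**: all-zero columns raise a no-surface error; a
  one-bright-pixel column raises insufficient-depth; 0/0 retardation pixels
  are defined as 0 and masked, since above-surface pixels sit at the noise
  floor.

## Statistics

Per configuration: one-way fixed-effects ANOVA (scipy `f_oneway`), Tukey HSD
(scipy `tukey_hsd`, studentized-range adjusted p), Bartlett variance
homogeneity and per-group Shapiro-Wilk normality as reporting-only checks
(they do not gate the ANOVA, matching how the original analysis used them).
Significance legend: *** p ≤ 0.001, ** p ≤ 0.01, * p ≤ 0.05, ns otherwise.
The ANOVA implementation's type-I error is calibrated under the null at
10⁴ Monte-Carlo replicates (0.05 ± 0.01).

A known limit of reproducing the published significance pattern: with group
moments 3.0 ± 0.5 / 1.7 ± 0.4 / 1.8 ± 0.7 at n = 10/8/8, the per-study
probability of ANOVA p < 0.001 is ≈ 0.91 and of the full
significant/significant/ns Tukey pattern ≈ 0.87; the exact star classes of
the published table (***, **, ns) arise in only ≈ 15 % of fresh studies, so
the ** class on G0 vs G2 reflects that particular sample.  The acceptance
suite states the pattern criterion at the published ≥ 90 % level and lets
the shortfall show rather than widening it.

## Problem sizes and reproducibility

Default B-scans are 256 × 500 pixels; a full three-configuration,
26-specimen study replicate runs in a few seconds on one CPU, and the
acceptance script's 20 indented-arm replicates in under a minute.  All
randomness flows from `numpy.random.SeedSequence` fan-out keyed by
(seed, configuration, grade, specimen, stream), so adding specimens never
perturbs existing ones and every artefact is bit-reproducible from
(config, seed).
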