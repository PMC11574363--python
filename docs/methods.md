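# Methods note

This note documents the models, parameters and numerical choices behind
`sandgait`, and what the synthetic generator does and does not emulate.

## Coordinate conventions

Right-handed lab frame: `x` = direction of progression (signed by
`travel_direction`), `y` = mediolateral, `z` = vertical up with `z = 0` at the
hard lab floor. Positions in metres, times in seconds, angles in degrees,
masses in kilograms, EMG in volts. Markers at 200 Hz, EMG at 1110 Hz by
default.

## Gait events

Heel-strike is the local maximum of `s · (x_heel − x_sacrum)` and toe-off the
local minimum of `s · (x_hallux − x_sacrum)`, with `s` the travel direction.
The relative signal is low-pass filtered at 10 Hz (2nd-order Butterworth,
applied forward–backward, i.e. zero-phase and 4th-order effective) before peak
picking; the minimum peak separation defaults to half the signal's dominant
Fourier period. Peak times are refined by parabolic interpolation through the
peak sample and its two neighbours (plateaus use the plateau centre), giving
sub-frame precision; without this, the 5 ms frame quantization at 200 Hz
dominates the error of short intervals such as swing time. Strides run
between consecutive ipsilateral heel-strikes and must contain exactly one
toe-off; marker gaps longer than 10 frames invalidate overlapping strides
(shorter interior gaps are filled by cubic interpolation).

## Spatiotemporal parameters

Per stride: cycle/stance/swing times straight from the events; duty factor =
stance/cycle; speed = signed fore–aft sacrum displacement over the stride
divided by its duration; stride length = fore–aft heel displacement between
consecutive heel-strikes; stride width = mean absolute mediolateral heel
separation at the contralateral heel-strikes inside the stride; double
support = overlap of the stride's own contact interval (heel-strike to
toe-off) with the contralateral contact intervals. For a symmetric gait this
satisfies `double_support = cycle × (2 × duty_factor − 1)`.

## Foot sinkage

Depth (cm) = substrate surface height − the lowest heel (calcaneus) or
hallux marker height within the stride. Negative values (marker minimum above
the surface) are reported as-is and flagged, never clipped; gaps spanning the
stride minimum yield missing values with a reason.

**Limitation — extreme-value bias.** Taking a raw minimum over ~100+ frames
of a locally flat trajectory is biased downward by roughly twice the marker
noise standard deviation (about +0.1 cm apparent depth at the default 0.5 mm
noise). This is a property of the estimator itself, visible as the ~0.13 cm
"sinkage" reported on a rigid floor; noise-free data recover configured
depths to better than 0.01 cm.

## Centre of mass and energetics

Whole-body CoM from a 13-segment model (feet, shanks, thighs, upper arms,
forearms+hands bilaterally; head, trunk, pelvis). Mass fractions sum to
exactly 1 (feet 0.0145 each, shanks 0.0465, thighs 0.100, upper arms 0.028,
forearms+hands 0.022, head 0.081, trunk 0.355, pelvis 0.142); each segment's
CoM lies a fixed fraction along its proximal→distal axis (classic
cadaver-derived values). A precomputed CoM channel, when present, bypasses
the segmental model.

`E_pot = m·g·z` (g = 9.81 m/s²) and `E_kin = ½·m·|v|²` with velocities from
central differences on the 6 Hz low-passed CoM (2nd-order zero-phase
Butterworth). Per stride, from positive increments over consecutive samples:
`W_v`, `W_f`, `W_ext` are the summed positive increments of `E_pot`, `E_kin`
and their total, and

* recovery `R = 100 (W_v + W_f − W_ext) / (W_v + W_f)` — 100 % for an ideal
  pendulum (constant total energy), 0 % for perfectly in-phase energies;
* relative amplitude `RA = ptp(E_pot) / ptp(E_kin)`;
* congruity `CO` = percentage of samples whose two increments share a sign,
  among samples where both exceed 1e−12 J.

A deliberately un-vectorised brute-force implementation of the same sums
(`synthetic.oracle_exchange`) serves as an independent cross-check; the
pipeline agrees with it within 0.5 (R) and 1 (CO) units on synthetic strides.

## Joint kinematics

Sagittal angles from three joint centres projected onto the x–z plane: hip
(shoulder–hip–knee), knee (hip–knee–ankle), ankle (knee–ankle–toe, offset by
90° so anatomical neutral reads 0). Flexion and dorsiflexion are positive.
Segments shorter than 1 mm yield missing samples. ROM = max − min over the
trial. Cycle normalization interpolates each stride onto 101 nodes
(0–100 %) with a cubic spline (exact on cubics).

## EMG

Chain: 2nd-order Butterworth high-pass at 12 Hz (zero-phase by default;
a single-pass option exists), full-wave rectification, normalization of each
muscle to the participant's maximum rectified amplitude across all their
trials (so max nEMG is exactly 1 per participant), then a trapezoidal time
integral per stride with exact interpolated endpoints (iEMG, unit: 1·s).
Curves for plotting/SPM are 101-bin means of the rectified signal. Electrodes
are modelled on the left lower limb only (biceps femoris, rectus femoris,
vastus lateralis/medialis, tibialis anterior, lateral/medial gastrocnemius,
soleus).

## Statistics

* **LMM** — REML random-intercept models via statsmodels MixedLM: response ~
  substrate + sex + speed with participants as random effects. Fixed-effect
  terms constant in the data are dropped; singular fits (participant variance
  < 1e−10) are flagged and reported as zero. A derivative-free optimizer
  fallback handles rare singular steps in the gradient-based pass.
* **1D-SPM** — node-wise paired t fields over the 101 cycle nodes. Field
  smoothness (FWHM) from unit-variance residual gradients:
  `FWHM = sqrt(4 ln 2 / mean squared gradient)`. The critical threshold
  solves `1 − exp(−(P(T>u) + R₁·ρ₁(u))) = α/2` (Euler-characteristic density
  `ρ₁`, resel count `R₁ = 100/FWHM`) by bisection with an adaptive bracket.
  Substrate pairs are Bonferroni-corrected (α/number of pairs). A max-|t|
  sign-flip permutation threshold (exhaustive when `2^n` fits the budget,
  otherwise seeded Monte Carlo) is provided as a nonparametric alternative;
  the two agree within ~5 % on smooth Gaussian fields, and the RFT
  threshold's empirical family-wise error on such nulls is ≈0.05.
* **ANOVA + Tukey** — hand-computed one-way sums of squares; Tukey HSD
  p-values from the studentized range distribution. Degenerate inputs give
  F = 0, p = 1 (no between-group variance) or F = ∞, p = 0 (no within-group
  variance).
* **Correlograms** — Spearman rank correlations (average ranks for ties),
  t-approximation p-values, variables ordered by their loading on the first
  principal component of the correlation matrix (eigenvector sign fixed so
  its largest-magnitude entry is positive; constant variables sort last).
* **CV** — sample standard deviation over mean of strides pooled per
  substrate.

## Synthetic generator

Defaults model a 21-participant study: 3 hard-floor trials plus 5 trials on
each of three sands per participant, 4 scheduled strides per trial.

| Parameter | Default | Rationale |
|---|---|---|
| heel depth mean (cm) | 2.08 / 2.68 / 4.09 | wetted/dry building sand, play sand regimes |
| hallux depth mean (cm) | 3.43 / 4.26 / 5.23 | same ordering, hallux sinks deeper |
| depth sd (cm) | 0.85 / 1.00 / 0.93 | stride-to-stride variability |
| depth–speed slope (cm per m/s) | 1.5 | faster trials sink deeper within a substrate |
| substrate speed means (m/s) | 1.38 / 1.32 / 1.24 / 1.18 | slower on deeper substrates |
| cycle time (s) | 1.10 ± 0.05 | typical adult walking |
| duty factor | 0.62 | typical walking stance fraction |
| CoM height / vertical amplitude (m) | 0.95 / 0.025 | typical pelvis height and oscillation |
| E_pot/E_kin phase (deg) | 132 | puts recovery R near 58–60 % |
| marker noise sd (m) | 0.0005 | optical capture noise |
| marker / EMG rate (Hz) | 200 / 1110 | study sampling rates |

Construction: heel and hallux markers oscillate fore–aft relative to the
sacrum as pure cosines, so the event rule recovers the scheduled events
exactly; during stance the markers dip below the surface by a half-sine of
the drawn per-stride depth (the depth schedule covers one extra cycle on
each side so partial lead-in/out cycles that still form detectable strides
carry proper depths); the CoM follows a designed path whose vertical
oscillation (2 per stride) and forward-speed fluctuation are offset by the
configured phase, emitted both as a `COM` channel and implicitly through the
13-segment marker set; lower-limb joints follow two-harmonic sagittal
templates via planar forward kinematics; EMG is a burst envelope modulating
band-limited (20–450 Hz) noise, with an envelope-only mode for deterministic
tests. All randomness flows from a single seed through
`numpy.random.SeedSequence` tuples, so studies are reproducible across
processes and platforms.

Ground truth per stride: event times, speed, stride length/width, all
timing quantities, sink depths, joint ROMs, R/RA/CO (from the brute-force
oracle evaluated on the analytic CoM at the marker frame grid) and EMG
envelope integrals.

**What the generator does not emulate:** ground-reaction forces, frontal- and
transverse-plane kinematics, soft-tissue artefact, marker occlusion patterns
(gaps must be injected manually), fatigue or stride-to-stride drift within a
trial (cycle time is constant within a trial), asymmetric gait, and
substrate deformation dynamics beyond the per-stride sink depth.

## Numerical choices

* All filters are Butterworth biquads (`sos` form) applied with
  `sosfiltfilt` for zero phase, except where a causal single pass is
  requested.
* Event peak refinement: parabolic, clamped to ±½ frame.
* Cycle normalization: cubic spline, not-a-knot ends.
* iEMG: trapezoid rule on the sample grid with interpolated stride
  endpoints.
* RFT threshold: bisection to 1e−6 with an adaptive bracket.
* Permutation test: enumerates all sign patterns when `2^n ≤ n_perm`,
  otherwise seeded sampling; vectorised in chunks of 2000 to bound memory.
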