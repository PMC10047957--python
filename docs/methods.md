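# Methods

This note documents the models, conventions and numerical choices behind
`itwgait`, and what the synthetic test bench does and does not establish
about real data.

## Coordinate conventions

The laboratory frame is right-handed: X along the direction of
progression, Z vertical up, Y = Z × X (subject's left). Segment frames
are stored as origin plus orthonormal axes `(x, y, z)` with
`z = x × y`: `x` roughly anterior along the segment, `y` the flexion
axis. The flexion axis is oriented so that **dorsiflexion (toe-up) is a
positive rotation** — for progression along +X this axis points to the
subject's right, and the same lab direction serves both body sides, so
mirroring a trial across the sagittal plane (with medial/lateral label
swap and a side flip) reproduces the angle trace exactly. Note that with
the longitudinal tibia axis pointing up and `y` pointing subject-right,
`z = x × y` points downward; right-handedness, not an "up" z, is the
invariant.

## Frame constructions

**Tibia.** Origin at the ankle-joint centre (inter-malleolar midpoint).
Longitudinal direction toward the knee centre (femoral-epicondyle
midpoint); flexion axis = malleolar line (oriented by side) projected
orthogonal to the longitudinal axis; `x = u × y` with `u` the
longitudinal unit vector.

**Mono-segment foot (Plug-in-Gait, Davis).** Longitudinal axis from CA
(posterior calcaneus) to the variant's forefoot marker — the metatarsal
marker `MT` for Plug-in-Gait, the distal `TOE` marker for Davis. The
sagittal plane contains that axis and the lab vertical
(`y = unit(x × ẑ)`). Only these two markers enter the construction, so
raising CA changes the pitch while any midfoot marker is irrelevant —
and any forefoot-vs-hindfoot motion rotates the axis.

**Oxford hindfoot.** The calcaneal sagittal plane is fitted to the CA /
medial-calcaneus / lateral-calcaneus triad (plane normal = mediolateral
direction). The longitudinal axis runs from CA to a **virtual anterior
calcaneal point**: CA projected 60 mm along the intersection of that
sagittal plane with the horizontal plane of the static pose. At static
calibration this point is frozen in a calcaneus technical frame
(CA→mid-calcaneus and mediolateral axes) and rigidly reconstructed every
frame, making the hindfoot frame a function of the calcaneus markers
only — bitwise invariant to forefoot marker perturbations, and invariant
under arbitrary rigid motions of the whole marker set. Without a
calibration the virtual point falls back to a per-frame construction
using the current lab vertical (then only vertical-axis rigid motions
are exactly neutral). The 60 mm length is arbitrary but harmless: only
the direction of the axis matters.

**Angle.** The tibia-to-foot rotation `R_rel = R_tibia^T R_foot` is
decomposed with intrinsic Y–X–Z Euler angles (flexion first, so the
sagittal angle is offset-subtractable); the leading angle minus the
static neutral offset is reported, wrapped to (−180°, 180°]. Samples
whose second rotation comes within 1° of ±90° are flagged (gimbal
proximity). Static offsets are applied for the Oxford and Plug-in-Gait
models and, by convention, not for Davis — the two mono-segment variants
must differ somewhere to be distinguishable, and offset handling plus
forefoot-marker choice is the configurable difference
(`APPLY_STATIC_OFFSET`, `MONO_FOREFOOT_MARKER`). An emergent and wanted
consequence: Davis reads systematically more plantarflexed angles (its
raw anatomical foot pitch), shifting its foot-contact angle and rocker
classification relative to the other two models.

## Preprocessing

Raw marker *coordinates* (never angles) are low-pass filtered with a
zero-phase Butterworth filter, default cutoff 12 Hz and net order 4,
realized as a forward–backward pass of a 2nd-order design. Zero phase
preserves the timing of kinematic peaks, which several outcomes depend
on; DC gain is exactly 1. Visible runs of a gappy marker are filtered
independently; cycles overlapping a gap are discarded, not interpolated.

Gait events come from the vertical ground-reaction force: foot contact
is the first analog sample rising above 20 N and staying above for
10 ms (debounce); foot off the first subsequent sample falling below
and staying below. Indices map to the marker timeline by the rate ratio
(nominally 1000 → 250 samples/s). The threshold rule is our
operationalization; both threshold and debounce are arguments.

Each foot-contact-to-next-contact span is linearly resampled to 101
samples (0–100% gait cycle); stance ends at the enclosed foot-off
(`stance_end_pct`). Cycles without exactly one enclosed foot-off are
skipped with a warning.

## Cycle-level statistics

- **Representative cycle**: the cycle minimizing the trapezoidal
  integral of |cycle − median waveform| over 0–100% GC, median taken
  pointwise (midpoint rule for even counts); ties break to the lowest
  index.
- **Linear fit method**: each subject's representative curve is
  regressed onto the cohort reference curve (the pointwise median;
  configurable to another reference) as
  `subject = a1·reference + a0`; R² is the squared Pearson correlation
  and the cohort is called consistent when mean R² > 0.5.
- **Scalar parameters**: angle at 0% GC; peak dorsiflexion over stance
  only; peak plantarflexion over the full cycle (its timing is not
  restricted to stance); ROM = peak DF − peak PF; ties take the
  earliest instant.
- **Rockers**: heel rocker ⇔ angle at foot contact strictly above −5°
  AND net 0→12% excursion negative AND the window minimum strictly
  after 0%. The "down-going" clause is operationalized without an
  amplitude cutoff (the net-negative + interior-minimum pair), and all
  three thresholds live in `RockerCriteria`. Premature forefoot rocker
  ⇔ stance dorsiflexion peak strictly before 30% GC.

## Factorial analysis

One complete-case table per parameter: subject × (3 models × 2
conditions). The two-way repeated-measures ANOVA partitions
within-subject sums of squares; each effect is tested against its own
effect-by-subject interaction (df for n = 14: model/interaction (2, 26),
condition (1, 13)). Effect size defaults to partial η² =
SS_effect/(SS_effect+SS_error), with a switch for classical η²; no
sphericity correction is applied by default (a Greenhouse–Geisser-style
correction could be added behind the same interface, but the reported df
are the uncorrected ones). Sums of squares below 1e-12 of the total are
treated as zero: a zero effect against a zero error term reports F = 0,
a non-zero effect against a zero error term is flagged undefined.

Normality is checked per cell with Shapiro–Wilk on cell residuals
(zero-variance cells count as non-normal); if any cell fails at
α = 0.05 the pipeline routes to the aligned rank transform: per effect,
responses are aligned by removing the contributions of all other fixed
effects (estimated from cell/marginal means, leaving subject effects in
the residual), ranked with midranks, and run through the same parametric
ANOVA, keeping only that effect's line.

Post-hocs are paired t-tests with Bonferroni adjustment (p × family
size, capped at 1, compared to 0.05 — equivalent to raw p against
0.05/m): 3 model pairs per family (α_adj ≈ 0.0167), 1 condition pair per
model. A significant interaction triggers simple-effect families (models
within each condition, conditions within each model); otherwise
significant main effects get pooled families. Zero-variance differences
short-circuit to p = 1 (zero mean) or p = 0 (non-zero constant
difference).

## Synthetic gait generator

The generator is the package's study population. A lab → tibia →
hindfoot → forefoot chain is driven by:

- a parametric 101-sample ankle waveform (hindfoot vs tibia): a
  shape-preserving PCHIP interpolant through (0%, angle at FC),
  optionally (t_dip, FC − loading dip) for the heel-rocker dip of
  heel-toe gait, (t_peakDF, peak DF), (t_peakPF, peak PF), (100%, angle
  at FC). Monotone-between-knots interpolation makes the requested
  extrema the global ones, so parameter extraction recovers the inputs;
  an optional Fourier truncation (`harmonics`) smooths further, with
  `harmonics=0` degenerating to a constant;
- a single sagittal **midfoot hinge** between hindfoot and forefoot — a
  plantarflexion bump `−A·(1−cos(2π·pct/100))/2` peaking mid-cycle.
  This is the minimal degree of freedom realizing foot-intrinsic motion;
  its amplitude A is the experiment's dial (default 15° barefoot, 0°
  with the orthosis);
- marker sets for all three models rigidly attached to their segments
  (child-scaled template geometry), isotropic Gaussian marker noise
  (default SD 0.5 mm), a small sinusoidal tibia tilt and constant
  forward progression;
- a stance-gated double-bump vertical GRF (peak 1.2 body weight, 2%
  rise/fall ramps so the 20 N threshold is crossed within about one
  analog sample of the true event), at the 1000/250 samples-per-second
  analog/marker rate structure.

Trials include a quarter-cycle lead-in and tail so filter edge
transients stay outside the analysed cycles and the final foot contact
is detectable.

Cohorts default to 14 subjects with Poisson(6) cycles per subject
clipped to [4, 10]. Per-subject waveform parameters are drawn once from
normal distributions chosen to depict barefoot toe walking (foot contact
≈ −10° ± 3, premature DF peak at ≈ 20% ± 4, peak PF ≈ −16° ± 3) versus
orthosis-corrected heel-toe gait (foot contact ≈ 0° ± 2, DF peak ≈ 12° ±
3 at 45% ± 4, loading dip ≈ 5° ± 1), with clipping that keeps the two
profiles on their respective sides of the rocker thresholds. A null
configuration (`CohortEffectConfig.null()`) equalizes the conditions and
removes midfoot motion for type-I-error checks. Cohorts are
bit-reproducible from a master seed (per-subject seeds spawned from a
`SeedSequence`).

**What the generator does not emulate**: soft-tissue artifact (markers
are rigid on segments; a config hook is reserved), frontal/transverse
joint motion, step-to-step waveform variability within a trial beyond
marker noise, marker occlusions, force-plate targeting failures, and
real anthropometric covariance. Passing tests therefore establish the
*internal correctness* of the pipeline (frames, angles, events,
statistics) and the *mechanistic direction* of the mono- vs
multi-segment contrast — not numerical agreement with any real cohort,
whose means and variances will differ.

## Problem sizes and runtime choices

The default test and acceptance workloads were sized for a single CPU:
single-trial round-trips use 1–4 cycles; oracle comparisons use 100
seeded repetitions; the type-I-error simulation uses 1000 seeded null
tables (n = 14); cohort-level effect-structure checks use 50 seeded
cohorts of 14 subjects (the null-cohort variant runs at 20 seeds in the
unit suite). The acceptance script repeats the cohort analysis 20 times
for its repetition rates.

## Known limitations

- The exact anatomical frame definitions of the published foot models
  (marker offsets, wand corrections, knee-axis and tibial-torsion
  handling, hindfoot inversion conventions, version 4 vs 5 differences
  of the multi-segment model) are not reproduced; the constructions here
  are operational equivalents anchored to the models' defining mechanism
  (which second point orients the foot axis). Angles from real lab data
  will differ by model-specific constants and corrections.
- Mono-segment frames reference the lab vertical, so their angles are
  exactly invariant only under rigid motions preserving verticality;
  this mirrors the models' own dependence on a vertical reference rather
  than being an implementation artifact.
- Only the sagittal ankle component is computed; hindfoot–forefoot and
  hallux angles exist in the generator's ground truth but are not
  clinical outputs here.
- Gait events require a vertical GRF (or externally provided events);
  kinematic event detection is out of scope.
- The ART implementation targets this 3 × 2 within-subject design; it is
  not a general factorial ART.
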