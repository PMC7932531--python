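# Methods

This note documents the statistical model, the parameter choices, the
synthetic-data generator and the numerical details behind `plantarstat`,
and states what the package's tests do and do not establish about real
clinical data.

## Data model

A recording is a sequence of pressure frames (kPa) at a fixed sample rate
(default 50 Hz), either on an irregular matrix of rectangular sensors of
unequal sizes (`SensorRecording`) or on a regular square grid
(`GridSequence`, 5 mm cells by default, 0.25 cm² per cell).  Pressures
respect the measuring device's range: values below 20 kPa are unresolvable
and stored as 0 (keeping per-cell max/mean semantics total, rather than
introducing missingness), values above 600 kPa saturate and are clipped
with a logged count.  Clipping is idempotent.

Coordinates are foot-local millimetres, origin at the posterior-lateral
heel corner, y toward the toes.  Left feet may be mirrored to canonical
right-foot orientation explicitly (`mirror_layout`); nothing is mirrored
implicitly, since every foot is analysed separately.

Because vendor-native export formats are proprietary, the canonical
on-disk format is an open CSV dialect ("PressureCSV": `#`-prefixed header
with layout reference, sample rate and metadata; one row per frame).  The
sensor ordering and coordinate anchoring are this package's own
convention; adapters for other exports can be written against
`SensorLayout`/`SensorRecording` directly.

## Resampling to the regular grid

Default method `area_weighted`: cell value = Σ_s P_s·overlap(s, cell) /
Σ_s overlap(s, cell).  On layouts that fully tile their bounding box this
conserves total force (pressure × area) to floating-point accuracy, and it
is well defined for unequal sensor sizes.  `centroid_bilinear` (linear
interpolation of sensor-centroid values, clamped to ≥ 0) is provided as a
smoother alternative; it does not conserve force.  Cells with no sensor
coverage get 0, not NaN, so downstream statistics stay total.  Both
methods preserve constant fields over the covered region and are invariant
to sensor ordering.

## Stance segmentation

A frame is "in contact" iff at least `min_contact_cells` (default 4) cells
read at or above `contact_pressure_floor` (default 20 kPa, the device
floor).  Maximal contact runs lasting 10–120 frames (0.2–2.4 s at 50 Hz)
become stances; shorter runs are contact artefacts, longer ones standing.
The first and last `trim_steps_per_pass` (default 1) stances of each
walking pass are dropped as gait initiation/termination transients; a pass
is the whole recording unless pass boundaries are supplied.  Contact is
defined by contact *area* rather than total force because area
thresholding is robust to the hard 20 kPa floor.

## Peak maps and the MPPM

Per stance, the peak pressure map takes the per-cell maximum over the
stance's frames.  The mean peak pressure map (MPPM) is the cell-wise mean
of those maps with its sample SD (ddof = 1 — the SD feeds t statistics
with n − 1 degrees of freedom).  Collecting fewer than `min_n` (default
24) stances triggers a warning, not an error: the 24-step requirement is a
power property of the downstream tests (see below), not a validity
condition, and small demonstrations should run.

## Risk-region determination

Cell-wise decision against the 200 kPa risk threshold with
t = (mean − threshold)/(SD/√n) and t_crit the (1 − α) Student quantile at
n − 1 df:

- `not_significantly_below` (default): in the R-ROI unless t < −t_crit.
  A cell whose mean is below 200 kPa but statistically compatible with it
  (high gait variability) is retained — the conservative reading of risk.
- `significantly_above`: in the R-ROI iff t > +t_crit.
- `direct_threshold`: mean ≥ threshold (the naive cut-off).  For every
  input this mask is a subset of the default rule's mask; the property is
  asserted on randomized maps in the test suite.
- `dispersion_band`: mean ≥ threshold or within t_crit·SD of it.  This
  band uses the SD, not the SEM; it is the literal reading of a
  "mean ± SD overlaps the threshold" argument and is deliberately kept as
  a separate rule rather than merged with the SEM-based test, because the
  two disagree (e.g. 170 ± 30 kPa at n = 24 is *significantly below*
  200 kPa by the SEM-based t test, yet inside the SD band).  Which variant
  a given clinical software package computes is rarely documented; all are
  provided and the default is a documented package choice, not a claim
  about any external tool.

Zero-variance cells are decided by direct mean comparison under every rule
(the t is undefined; this is its limit behaviour).  The default applies no
multiple-testing correction across cells — each cell is a clinically
separate decision — but a Bonferroni-across-cells switch exists for
sensitivity analysis.  No anatomical mask is applied at any point: risk
regions fall wherever the statistics place them, and anatomical
interpretation is a downstream, human step.

R-ROI cells are grouped into connected clusters, 8-connectivity by default
(diagonal neighbours merge; 4-connectivity available), and quantified by
total area = cell count × (cell/10)² cm².

## Redistribution between conditions and residual reduction

Per cell, a two-sided paired t test at α on step-paired peak pressures
(step i of one condition with step i of the other; steps from different
walks are not physically matched, so an unpaired Welch option exists).
Significant cells are classified by the sign of the mean difference;
non-significant cells inside the reference R-ROI are "unchanged R-ROI"
cells — residual risk the insole failed to move.  Constant differences
give a degenerate t; the implemented limit is: significant iff the
constant shift is nonzero.

The reduction report compares the reference MPPM averaged over the
reference R-ROI with the alternative MPPM averaged over the residual
R-ROI.  When the alternative condition removes the risk region entirely
("optimal" outcome), the achieved reduction cannot be measured — cells
below threshold carry no quantified risk pressure — but is bounded below
by (reference R-ROI mean − 200 kPa), which is always reported.

## Cohort comparison

The unit of analysis is one foot's total R-ROI area (cm²) per condition.
Area distributions are heavily non-normal (a point mass at 0 from optimal
feet), so the comparison is nonparametric: Friedman across the k
conditions, then all pairwise Wilcoxon signed-rank tests at
α_family / n_pairs (0.05/3 ≈ 0.016667 for three conditions).  Wilcoxon
drops zero differences (classic policy; Pratt's available) and midranks
ties; p is exact by enumeration for n ≤ 25 without tied |differences|,
else the normal approximation with continuity correction.  The Friedman
statistic uses midranks with tie correction (many zero areas ⇒ heavy
ties).  Its chi-square p-approximation was checked against the exhaustive
within-row permutation null: accurate in the significant tail, but
anti-conservative by up to ~0.1 for mid-range p at n ≤ 6 — therefore
`friedman_test(..., method="exact")` enumerates the permutation null for
small tables, and the approximation should be trusted only when p is
small, which is the regime this analysis operates in.  Mean differences
are reported alongside the rank-based p values, as is conventional; note
that means, not rank statistics, are being differenced.

## Power design

The step-count requirement comes from noncentral-t power with
noncentrality d·√n at n − 1 df.  Two-tailed power counts both rejection
regions (the common one-sided shortcut is wrong at large d).  At d = 0.6,
α = 0.05, power 0.80: the one-tailed one-sample threshold test needs 19
steps; the two-tailed paired comparison needs 24, the stricter and
therefore governing requirement; adopting 24 steps improves the threshold
test's sensitivity to d ≈ 0.52 (bisection on the power function to 1e-6).
`required_n_t` brackets geometrically then scans, and tests assert power
≥ target at n and < target at n − 1 over a (d, α, tails) grid.

For the cohort design, the within-subject repeated-measures F power uses
λ = n·k·f²·ε/(1 − ρ), df₁ = (k − 1)ε, df₂ = (n − 1)(k − 1)ε with explicit
repeated-measures correlation ρ and nonsphericity ε, because published
"calculator" results are rarely pinned to one convention; with k = 2 and
ρ = 0.5 it reproduces the paired-t requirement to ±1.  The +15%
nonparametric inflation rule (`nonparametric_inflate`) is the standard
rule of thumb when the final test is a Friedman.

## The synthetic gait generator

`simulate_walk` emulates what the measuring system records during walking,
with ground truth known by construction:

- **Foot field**: a foot-shaped mask (union of heel/midfoot/forefoot
  ellipses, ~100 × 260 mm) with a whole-sole baseline (60 kPa) and
  isotropic Gaussian high-pressure loci at the clinically typical sites —
  heel, five metatarsal heads, hallux — plus a low arch locus.  Default
  amplitudes (150–280 kPa, σ 7–14 mm) were set so that the flat-insole
  super-threshold area is ~20–25 cm² per foot, the magnitude reported for
  at-risk neuropathic feet.
- **Temporal structure**: stance 0.7 ± 0.05 s (physiological comfortable
  walking) at 50 Hz, swing 0.4 s; within a stance the baseline follows a
  half-sine and each locus a half-sine inside its own timing window
  (heel early, metatarsals mid-late, hallux late), so the per-cell maximum
  realizes the template's peak field.
- **Variability**: one multiplicative loading factor per step
  (1 + cv·z, default cv 0.1), per-step Gaussian displacement of each locus
  (default 2 mm), additive sensor noise (2 kPa), then the 20–600 kPa range
  applied after noise so ceiling truncation is exercised.  Everything is
  reproducible from a single seed.
- **Offloading**: `apply_offload` scales locus amplitudes by
  (1 − reduction) and reroutes a configurable fraction of the removed load
  to the arch locus — the net effect of a pressure-deepening custom
  insole, not a model of the insole.
- **Sensor level**: `synthetic_pedar_layout` provides a 99-sensor
  unequal-rectangle layout that fully tiles its bounding box (so force
  conservation is exactly testable), and `sensor_recording_from_sequence`
  samples a grid sequence onto it.

Ground truth: `ground_truth_rroi` is the infinite-steps limit — as n grows
the SEM vanishes and every statistical rule converges to the direct
comparison of the *expected* peak field against the threshold.  The
expected field accounts for locus jitter analytically (a Gaussian bump
with jittered centre has expectation σ² → σ² + j², amplitude ×
σ²/(σ² + j²)).  For redistribution, `detectable_change_masks` draws the
ground-truth boundary at the minimal detectable paired difference at 50%
power, Δ* = t_crit·sd_diff/√n — the point where the paired test's
detection probability crosses one half, the unbiased boundary for
comparing a detected set with an expected set.

At the study conditions (cv 0.1, jitter 2 mm, ~100 steps) the detected
R-ROI agrees with ground truth at mean Jaccard ≈ 0.95 over 20 seeds.
Individual seeds can dip slightly below 0.9: the conservative default rule
retains a ring of near-threshold cells whose per-step SD is inflated by
jitter at steep bump edges — by design — while the infinite-step ground
truth excludes them.

**What passing tests do not show**: the generator does not emulate shear,
centre-of-pressure trajectories, foot deformities, speed drift, sensor
drift/hysteresis, or insole material mechanics.  Recovery results
demonstrate the statistical machinery is correct, not that any particular
clinical effect size will be observed.

## Numerical choices and degenerate inputs

- Sample SDs use ddof = 1 throughout.
- t/F critical values and noncentral distributions come from scipy;
  `detectable_d` bisects to |Δpower| ≤ 1e-6.
- Zero-variance cells: direct mean comparison (classification); constant
  paired differences: significant iff nonzero (redistribution).
- All-constant rows in the Friedman test return chi2 = 0, p = 1 (the tie
  correction degenerates there).
- All-zero Wilcoxon differences return p = 1 with a warning.
- Empty sequences, empty reference risk regions, mixed grids, mismatched
  step counts in paired mode, duplicate feet and negative areas are
  errors, not silent repairs.
- Grid origins snap down to cell-size multiples so grids from overlapping
  layouts share cell boundaries.

## Problem sizes used in the test and acceptance runs

Simulation-based checks use 20 seeds × 100 steps (risk-region recovery),
20 seeds × 26 steps (offloading end-to-end) and 200 steps (variability
calibration); enumeration oracles run at n ≤ 10 (sign-flip Wilcoxon) and
n ≤ 6, k = 3 (Friedman permutations).  These sizes give stable pass/fail
behaviour at well under a minute per check and are the package's chosen
demonstration scale.

## Known limitations

- The PressureCSV dialect is this package's own; no vendor-native binary
  formats are parsed.
- Pairing steps across conditions by step order is a modelling convention;
  steps from different walks are not physically matched (the Welch option
  exists for this reason).
- Pressure-time integrals (how long each cell stays loaded above
  threshold) are not computed; risk is assessed on peak pressure only.
- The repeated-measures power answer depends on the assumed ρ and ε;
  results from other tools are reproducible only when those assumptions
  are stated.
- No ulcer-outcome prediction: R-ROI areas are a biomechanical surrogate.
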