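# Methods

This note documents the models, the synthetic-data assumptions, and the
numerical choices behind `turtlebis`. It describes what the code computes;
every number quoted here is produced by the test suite or the acceptance
script at run time.

## The calibration model

Nonadipose tissue mass (kg) is modelled as an ordinary least-squares linear
function of an impedance index, total body mass and handling time:

```
nonat = β₀ + β₁ · length²/R + β₂ · mass + β₃ · time + ε
```

with `length` the straight or curved carapace length (cm), `R` one of the
sweep-derived resistances (Rinf, R0, R50, Ri) or the 50 kHz reactance Xc50
(Ω), mass in kg and time after capture in hours. Adipose mass is the
difference with body mass, clipped to `[0, mass]` with a flag when clipping
occurs. Candidate indices are compared by the small-sample corrected Akaike
information criterion; the search is exhaustive over the candidate set
rather than path-dependent stepwise, which reaches the same optimum for this
small model family without order effects. AICc uses the Gaussian maximum
likelihood (`σ² = SSR/n`) with `k` counting intercept, slopes and the
variance parameter: `AICc = AIC + 2k(k+1)/(n−k−1)`.

Split validation partitions the cohort at random (seeded) into a fit set of
`ceil(2n/3)` animals and a test set of the remainder — 33/16 at n = 49. The
fitted model predicts adipose mass on the test set for the agreement
analysis. Four published coefficient sets ship as named fixtures
(`prediction_*` for the 2/3 fit group, `final_*` for the full-sample
equations) and are evaluated verbatim, without reconciliation of their
rounded printing.

## Agreement statistics

* **Bland–Altman**: differences `test − reference`; bias = mean, `sd` =
  sample SD; limits of agreement `bias ± 1.96·sd` (multiplier configurable).
  Confidence intervals use the exact t-based variances, `Var(bias) = sd²/n`
  and `Var(limit) = sd²(1/n + 1.96²/(2(n−1)))`. Proportional bias is the
  least-squares slope of differences on pairwise means with a t-based CI.
* **Maximum allowed difference Δ**: the agreement test concludes agreement
  when both limits of agreement lie inside `(−Δ, Δ)` with confidence
  `1 − α`. Its power is approximated with two noncentral-t tail
  probabilities with noncentralities
  `(Δ ∓ |bias| − 1.96·sd) / (sd·√(1/n + 1.96²/(2(n−1))))` against the
  `t_{1−α/2, n−1}` critical value; Δ is the smallest margin reaching the
  target power, found by bisection to 1e−6. The two-sided critical value is
  the variant that reproduces the tabulated Δ = 0.73 kg at n = 49,
  bias 0.06, SD 0.25, 80 % power. With `sd = 0` the limits collapse onto the
  bias and Δ degenerates to `|bias|`. scipy's noncentral t loses accuracy at
  large noncentrality; tails beyond 12 units of the critical value are
  treated as 1 to double precision.
* **Passing–Bablok**: the slope is the shifted median of all pairwise
  slopes, excluding slopes exactly −1, counting slopes below −1 as the
  offset K (this makes the estimator invariant to swapping axes:
  slope → 1/slope). Vertical pairs contribute ±∞; identical points are
  dropped. The rank-based CI uses the normal approximation
  `w = z_{1−α/2}·√(n(n−1)(2n+5)/18)`; the intercept is `median(y − b·x)`
  with its CI from the slope CI bounds. No jackknife.
* **Lin's CCC**: `2·cov/(var_x + var_y + (mean_x − mean_y)²)` with n−1
  moments; by construction `|ccc| ≤ |r|`.
* **MAPE**: absolute percentage errors summarized by their **median** by
  default (the tabulated convention); the mean is exposed as an option.
  Zero reference values raise, naming the offending index.

Agreement is reported on both the kg scale and the percent-of-body-mass
scale (adipose % is the natural measurand for animals spanning a wide mass
range).

## Synthetic cohorts

The generator emulates the study conditions: adipose fraction
`N(0.065, 0.037)` clipped to `[0.005, 0.25]` (population mean 6.5 ± 3.7 % of
body mass; clipping rather than truncated resampling keeps the mean within
~0.1 pp of 6.5 %), handling time `N(1.5, 2.0)` h clipped to the 0–4 h
pre-release window, and a 50/50 wild/captive split. Size: SCL `N(52, 4)` cm
clipped to 44–62 cm, CCL = SCL × U(1.04, 1.10) (no published CCL–SCL
relation; declared, not inferred), body mass via Fulton's K `N(1.4, 0.12)`
clipped to 1.25–1.65. The size window is chosen so that the inverted
calibration below yields a strictly positive impedance index over the whole
joint covariate range — the published equation turns negative for very
small, lean animals at long handling times, a region the study population
does not occupy.

**Impedance** is generated by inverting the calibration model at the
animal's true composition: true nonadipose mass maps to an index through the
generating coefficients (defaults: the final SCL²/R50 equation), the index
to a 50 kHz resistance at the animal's length, and the resistance to a full
Cole parameter set. The Cole model
`Z(f) = Rinf + (R0 − Rinf)/(1 + (j f/f_c)^α)` supplies R0, Rinf, Ri, Xc50
and the phase angle, with nuisance draws for `f_c` (~30 kHz), `α` (~0.65)
and the intracellular/extracellular resistance ratio (~2). Replicate sweeps
(10 per animal) are represented by their arithmetic mean, the aggregation
applied before index computation.

**Noise placement.** The 0.19 kg residual scale (the RMSE of the fitted
equations) is additive on the *criterion response* — the synthetic
CT-derived nonadipose mass — not inside the inverted index. Response-side
noise leaves ordinary least squares unbiased, so the generating coefficients
are recoverable (the Monte-Carlo recovery test demonstrates this at n = 1000
over 200 replicates); noise inside the index would be an errors-in-variables
design that attenuates every coefficient and would make the generator
inconsistent with its own purpose.

## CT phantoms

Phantoms are ellipsoidal bodies on a configurable grid — default
(slices, rows, cols) = (160, 96, 96) at 1.0 mm in-plane spacing, 0.625 mm
spacing between slices and 1.25 mm slice thickness, a desk-scale stand-in
for clinical 512×512×~1600 volumes. Voxel volume uses the spacing *between*
slices, not the thickness: overlapping helical reconstructions would
double-count volume otherwise; thickness is kept as metadata.

Four adipose depots (neck, sub-carapace, mesenteric, hindlimb; equal shares
by default) are filled voxel-by-voxel from each depot centre outward until
the target count `round(target_fraction × body voxels)` is met, so the
voxelized truth fraction matches the target to a single voxel. Anatomy that
confounds thresholding is injected per the false-positive plan: (A) a skin
fold patch and eye spheres, (B) the air-to-lung transition shell, (C) a
pericardial region, (D) gut contents, and the scanner table slab outside the
body. Every structure is isolated by a 2-voxel soft-tissue spacer
(anatomically, adipose does not directly abut airways or gut lumen), which
also keeps threshold candidates of distinct structures from merging into one
26-connected component. HU are drawn from truncated normals per tissue:
adipose `N(−15, 10)` truncated to the population attenuation range
(−32.2, 10.1); soft tissue ≥ +20; lung air ≤ −300; bone ≥ +300; gut contents
overlapping the adipose range; all configurable.

What the phantoms do **not** model: X-ray physics (no beam hardening, noise
texture or helical artifacts), realistic turtle anatomy beyond depot
placement, or partial-volume mixing at tissue boundaries. Passing tests
therefore demonstrate correctness of the segmentation/accounting machinery
and of the statistics, not robustness to scanner physics.

## Quantification

Thresholding selects voxels with `hu_min ≤ HU ≤ hu_max`, inclusive on both
bounds. The attenuation range is either supplied, or estimated from the
in-body HU density: within a soft-tissue search window (−250 to 150 HU) the
histogram (2 HU bins) is smoothed (Gaussian, σ = 6 HU), modes are located,
the mode nearest −15 HU is delimited by the surrounding density valleys, and
the smallest highest-density interval holding ≥ 95 % of that mode's mass is
returned. A unimodal or degenerate density falls back to the printed
population range (−32.2, 10.1), flagged in the result. This
density-mode/quantile estimator stands in for the original under-specified
smoother-based range determination.

False-positive removal is pluggable. *Oracle* mode subtracts the phantom's
ground-truth class masks — the role the trained segmentation network plays
on real scans — and recovers the truth exactly whenever the range covers all
adipose voxels. *Rules* mode applies heuristics: candidate components
disconnected (26-connectivity) from the largest body component are the
table; candidate voxels within 2 voxels of interior air are airway
transitions; candidate components overlapping a supplied gut-region mask are
gut contents. Skin folds, eyes and the pericardium (classes A, C) need
anatomy the rules cannot see and are deliberately not attempted; they are
retained, and only the oracle removes them.

Mass accounting: `at_fraction = |final adipose| / |body|`,
`at_mass = body_mass × at_fraction`, `nonat = body_mass − at_mass`, with a
one-step rounding fixpoint so the two masses sum to body mass bit-exactly.
The fraction denominator is the body mask including internal air; a
soft-tissue-only denominator would be an alternative convention and can be
realized by passing a different mask.

## Pipeline

`run_pipeline` chains the five stages under one config and seed: cohort →
one phantom per animal (the record's truth fraction is replaced by the
voxelized one, and impedance is regenerated from it, so the simulated BIS
and the phantom agree about the same animal) → quantification → calibration
with AICc ranking and split validation → the agreement battery per candidate
index on both scales. The calibration response is the quantified nonadipose
mass plus the criterion-side residual draw; with zero configured noise, an
oracle run with a truth-covering threshold range refits the generating
coefficients to floating-point accuracy (the closed-loop test asserts 1e−6
relative). The default pipeline phantom grid is (64, 56, 56), the smallest
desk-scale grid whose depots can pack the full cohort fraction range; the
manifest records config, versions and a SHA-256 per artifact, and identical
seeds reproduce identical checksums.

## Numerical and design notes

* HU grids are int16 in [−1024, 3071]; sampled HU are rounded before
  clipping, which cannot move a truncated draw outside its range.
* Connected components use 26-neighbour connectivity; the largest body
  component ties break toward the larger voxel count (then the lower label
  index from the scan order).
* The cohort CSV is byte-stable under write → read → write
  (`float_precision="round_trip"`).
* Problem sizes in the test suite (phantoms of 64³-scale grids, 200
  Monte-Carlo replicates at n = 1000, 50 Passing–Bablok oracle instances)
  are chosen to exercise the statistics at meaningful scale while keeping
  the suite fast on a single CPU.

## Known limitations

* Rules-mode false-positive removal is a stand-in for the trained network:
  it handles the table, airway and gut classes and knowingly keeps classes
  A and C.
* The generator's linearity means BIS-vs-CT disagreement in simulation comes
  entirely from the configured residual SD and voxelization; real data add
  physiology the linear model does not capture.
* Published %-scale SD/LOA columns are not internally consistent under
  `bias ± 1.96·SD` arithmetic and are not used as checks; kg-scale summaries
  are.
* DICOM support reads series with spacing metadata via SimpleITK; writing is
  NIfTI-only.
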