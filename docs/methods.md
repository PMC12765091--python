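# Methods

This note documents the conventions, parameter defaults and design
choices behind `oar-sentinel`, in the spirit of a model-description
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

The package judges auto-segmented organ-at-risk (OAR) contours for
radiotherapy planning, with the brain as the motivating anatomy
(17 OARs of the ESTRO-ACROP consensus set, 60 Gy in 30 fractions
prescriptions). It assumes:

- all volumes (masks, dose) already live on a **common voxel lattice**;
  registration is out of scope, and only explicit nearest-neighbour
  resampling is provided. Cross-grid operations refuse with an error
  rather than resampling silently.
- contours are **voxel masks**, exchanged as NIfTI. DICOM-RT polygon
  structures are a non-goal.
- a dose distribution for the evaluation contours is supplied by the
  caller (in the clinic, by a dose-prediction model; in tests, by the
  analytic phantom field). Dose calculation and plan optimisation are
  out of scope.
- fixed units throughout: Gy, mm, mm³. Voxel indices are 0-based, axis
  order (x, y, z); world coordinate = origin + index × spacing; a voxel
  is the closed box of edge `spacing` centred on its centre.

## Geometric layer

**DSC** is computed on voxel counts. When both masks are empty it is
undefined (`None`), never a number.

**HDD95** pools the directed surface distances in both directions and
takes the 95th percentile with linear interpolation between order
statistics. The directed max-of-two-percentiles variant exists behind
`directed=True`; neither variant is claimed to reconstruct any
particular clinical system's convention — the pooled-symmetric form is
simply the most common in segmentation QA. Surfaces are occupied voxels
with an exposed face (6-connectivity); distances are between voxel
centres, which biases HDD95 by up to half a voxel diagonal relative to
sub-voxel mesh distances. On masks up to 10³ voxels the implementation
is checked exactly against an O(n²) all-pairs oracle.

**Morphology** realises an isotropic Euclidean ball of radius `r` mm by
thresholding the anisotropic-spacing Euclidean distance transform:
dilation keeps voxels with distance-to-set ≤ r, erosion is the
complement dual. This is exact in mm on anisotropic lattices, unlike
repeated structuring-element passes. Note the distance transform sees
only the array: a mask touching the array boundary erodes as if the
outside were foreground.

An empty evaluation mask is a QA finding, not an exception: both
geometric channels become undefined and are forced red downstream.

## Dose layer

Mean and max dose are arithmetic mean and maximum over occupied voxels
(max dose is the voxel max, not D0.03cc; a near-max `dose_at_volume` is
provided separately). The cumulative DVH uses 0.1 Gy bins by default on
a percent-volume axis; integrating the curve recovers the mean to
within one bin width (asserted on every fixture).

**Dose sensitivity** dilates and erodes the evaluation contour by
organ-specific extents and recomputes both dose statistics. The
reported delta is, by default, the worst-case absolute deviation of
either variant from the evaluation contour's own metric — the
conservative choice for QA, made because "difference of the over/under
segmentations" admits two readings. The alternative span
(|dilated − eroded|) is always computed and written alongside
(`span_mean_gy`, `span_max_gy`). If erosion empties a small structure,
no dose is fabricated for the empty set: deltas fall back to the
dilated side and the record carries a vanished-structure warning. Max
dose over nested sets must nest (eroded ≤ original ≤ dilated); this is
asserted wherever all three are defined. No analogous claim is made for
mean dose — it is false in general.

## Decision matrix

Four channels: DSC, HDD95, constraint-selected dose (mean or max per
the organ's clinical constraint), and the delta matching that
statistic. This particular choice of four inputs is an interpretation
fixed by this package — they are exactly the four quantities the two
estimators output. Points: green 0, yellow 1, red 3; total ≥ 3 flags.

Boundary handling is safety-first: the dose channel is red **at or
above** `constraint × (1 − red_within_or_exceed)` (so with the default
margin 0, a dose exactly at the constraint is red), and delta-channel
ties also escalate. The geometric channels use the strict forms
(`dsc < red_below`, `hdd > red_above`). Undefined channels are red.

The critical-event rule is two conditions, either sufficing:
*proximity* (dose within `proximity_margin` of the constraint, or
above) and *impact* (dose difference > `delta_threshold_gy`). The
estimator side widens both by an additive `safety_margin_gy` (proximity
cut lowered, delta threshold reduced), so with zero margin it reduces
exactly to the reference rule — an identity the tests assert. The final
flag is either the traffic-light total alone (`score_only`) or its OR
with the critical estimate (`score_or_critical`); the default is the
OR, because the assistant's design goal is high sensitivity and the two
layers are deliberately complementary.

**Numeric thresholds are configuration, not reconstructions.** The
shipped policy file (17 brain OARs) uses defaults of the right clinical
order — DSC yellow < 0.85 / red < 0.70 (0.80/0.60 for small organs),
HDD95 yellow > 3 mm / red > 6 mm (2/4 mm for small organs), dose yellow
within 10% of the constraint / red at-or-above, delta yellow ≥ 1 Gy /
red ≥ 3 Gy, constraint doses from common brain planning practice — but
any deployment must set its own. Every report records a hash of the
threshold set used.

## Validation harness

Flags are compared with per-structure reference criticality labels on
(case_id, organ_id) keys; misalignment and duplicate keys are errors.
Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are reported as
undefined (`None`) when their denominator is zero, never coerced. The
per-structure table is the unit of reproducibility: the summary and the
false-negative listing are recomputable from it.

A note on the motivating study's printed tallies: 507 structures with
180 reference-critical, 173 of them flagged, yields sensitivity
173/180 ≈ 0.96 with 7 false negatives — arithmetic the acceptance suite
reproduces. The same study reports specificity 0.55 alongside 317
flagged structures (61%), which implies 144 false positives, 183 true
negatives and a specificity of 183/327 ≈ 0.56; the package reproduces
only the arithmetic that is internally consistent and leaves the
0.55-vs-0.56 discrepancy as stated.

## Synthetic phantom study

The generator emulates the *structure* of a 30-case brain QA study, not
its anatomy:

- grid 64³ at 2 mm isotropic (128 mm cube); one spherical PTV of radius
  15 mm, centre jittered ±4 mm per case;
- 17 organs per case, spheres or mildly squashed ellipsoids with radii
  6–12 mm, placed at seeded random directions with a surface-to-PTV-
  surface gap of 4–28 mm;
- analytic dose: prescription 60 Gy inside the PTV, then
  `background + (prescription − background) · σ((midpoint − d)/steepness)`
  with midpoint 20 mm, steepness 5 mm, background 2 Gy, where `d` is the
  distance-transform distance to the PTV. The field is monotone
  non-increasing away from the PTV — the controllable stand-in for a
  predicted dose distribution with a realistic falloff shape;
- injected errors per structure: none (35%), minor 1–4 mm (30%),
  moderate 4–8 mm (20%), gross ≥ 8 mm (15%). Kinds: whole-voxel shift,
  mm-calibrated expand/shrink, seeded surface blobs (add/remove), and
  axial truncation. Reference criticality labels are computed during
  generation by the reference critical-event rule on true-vs-injected
  constraint dose metrics (a vanished contour is critical by
  definition), and are recomputable from the emitted volumes;
- three of the 30 default cases drop one organ, emulating incomplete
  structure sets (30 × 17 − 3 = 507 structures).

**Gross errors** are defined as kinds {shift, expand, shrink} at
magnitude ≥ 8 mm. The bound is chosen analytically: for organ radii
≤ 12 mm, the worst case (a 12 mm sphere shifted 8 mm) has analytic DSC
≈ 0.52, comfortably below every shipped DSC red threshold, so a gross
error always produces at least one red channel (3 points → flagged)
irrespective of dose. Blob and truncation edits are local — they can
leave global overlap high — and are deliberately *not* in the gross
class; they exercise the dose channels instead. This is what the
parameter-recovery property shows: on the constructed gross-in-falloff
subset the assistant's sensitivity is 1.0 *by construction*, which
validates the plumbing, not clinical performance.

What the phantoms do **not** emulate: real organ shapes and adjacency,
image appearance, anisotropic clinical lattices, TPS-grade dose (no
beam geometry, no re-optimisation after a contour change), or realistic
error statistics. Passing tests therefore demonstrate correctness of
the metrics, rules and harness — not clinical sensitivity/specificity,
which can only come from clinical data and plans.

## Numerical choices and degenerate inputs

- grid compatibility tolerance 1e-6 mm; NIfTI round-trips preserve
  geometry to that tolerance (float32 data on disk).
- nearest-neighbour resampling maps each target voxel centre to
  `floor(index + 0.5)` of the fractional source index, so half-way ties
  round toward the higher index deterministically.
- masks binarize at > 0.5 on read; dose volumes must be finite and
  non-negative (validated with the offending voxel count).
- percentiles use linear interpolation (`numpy.percentile` default).
- seeded randomness everywhere: study generation is a pure function of
  its master seed, with per-case and per-error child seeds below 2³¹;
  regenerated datasets are byte-identical.

## Known limitations

- Point-cloud HDD95 (voxel-centre) rather than mesh distances; at 2 mm
  isotropic spacing the bias can reach ≈ 1.7 mm in the worst corner
  case.
- The delta-dose probe is isotropic; direction-specific contouring
  errors can be understated, which is why decisions are additionally
  gated by dose thresholds relative to the organ constraint.
- `evaluate` processes one case per invocation; batch orchestration is
  left to the caller (the validation API handles multi-case studies
  in-process).
- Thresholds ship as editable defaults; nothing in this package learns
  them from data.
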