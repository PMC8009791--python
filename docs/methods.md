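# Methods

This note records the modelling choices, conventions and numerical details
behind `cranioquant`, in the order the pipeline runs.

## Reference plane and outline extraction

The measurement plane is anchored on three external landmarks — left
porion, left exocanthion, right exocanthion, all in mm — and translated
40 mm (configurable, `offset_mm`) along the landmark-plane normal. Two
conventions are deliberate:

- **Normal orientation.** The landmarks alone do not determine which side
  of their plane is superior. When a head representation is available its
  sample points orient the normal (the cranium lies above the
  porion/exocanthion plane, so the normal points to the side holding the
  bulk of the head); without one, the normal's largest-magnitude component
  is made positive, a convention that matches axis-aligned scanner frames.
- **Offset direction.** The 4 cm is measured along the landmark-plane
  normal, not along the scanner z-axis. For well-positioned acquisitions
  the two nearly coincide; users comparing against other implementations
  should check which convention those use.

The in-plane frame takes anterior = projection of the porion→exocanthion
midpoint vector, and left = normal × anterior, giving a reproducible
forehead direction for curve alignment.

Cross-sections of meshes use exact plane–triangle intersection (trimesh);
binary volumes are resampled on the plane (trilinear) and contoured at the
0.5 iso-level with marching squares, which gives sub-voxel boundary
placement. When the intersection has several closed loops (ears, noise),
the largest-area loop is kept: at +4 cm the cranial vault dominates. Open
or empty intersections are errors, never silently patched.

The curve center is the **area centroid** of the enclosed region (polygon
moments), not the vertex mean; the two differ whenever vertex density
varies along the outline, and the tests guard this distinction explicitly.

## The radial curve

Distances from the centroid to the outline are sampled at
`n_samples = 360` uniform angles (1°), which localizes the 1.1/0.9 level
crossings used for abruptness to better than half a degree. Rays are
intersected with every polygon edge using a half-open edge interval with a
1e-9 tolerance so a ray through a shared vertex counts exactly once. If a
ray crosses the boundary more than once (the outline is not star-shaped
about the centroid), the outermost crossing is used and the count of such
rays is recorded as a warning.

Normalization divides by the circular mean radius, making the curve
dimensionless with mean exactly 1 and scale-invariant. This is the only
normalization consistent with control-cohort values straddling 1 (occiput
≈ 1.1, forehead ≈ 1.15, sides ≈ 0.85); the mean radius in mm is retained
in the curve's provenance.

Alignment shifts the curve by a whole number of samples so θ = 0 falls on
the occipital maximum, searched in the posterior quadrant of the
anatomical frame. Starting the curve at the occiput makes the monotone
segments traverse in the fixed order first-descent (occiput), first-ascent
(forehead), second-descent (forehead), second-ascent (occiput). A flat
curve (peak-to-peak < 1e-6) has no meaningful maximum and is aligned by
the frame alone, with a warning.

Optional smoothing is a periodic 5-sample moving average, **off by
default** — phantoms are smooth; real outlines may need it — and recorded
in the curve provenance when used.

## Curve variables

Extrema are searched in the four quadrants of the aligned curve, centered
at θ = 0 (occiput O), π (forehead F) and ±π/2 (lateral troughs). Which
lateral quadrant is the subject's left follows the outline frame's left
axis; the two troughs are near-symmetric in practice, and the assignment
is recorded. An extremum landing on a quadrant boundary triggers a
misalignment warning.

Derived variables are exact arithmetic: width = R/2 + L/2, prominences
O − width and F − width. The forehead–occiput difference is reported as
|F − O| with the signed value alongside: cohorts can have mean O > mean F
while per-patient differences are reported positive, so the magnitude
convention is the only one consistent with both.

Abruptness of a segment is ±0.2 divided by the angular distance between
the segment's linearly interpolated crossings of y = 1.1 and y = 0.9;
descents are negative, ascents positive. Choices:

- Angles are radians on [0, 2π); the angular span is reported alongside
  each slope so any other X-axis unit can be recovered.
- A sample exactly at a level counts as the crossing (first touching
  sample on ties).
- With ripple, a level may be crossed several times within a segment; the
  1.1 crossing nearest the segment's peak end and the 0.9 crossing nearest
  its trough end are used, measuring the full shoulder of the peak.
- A segment that never reaches a level (mild, near-circular heads) has
  **no** abruptness: it is reported missing with a reason code, never
  extrapolated.

## Severity scoring

- **Rank-sum score**: width = R + L ranked so the narrowest skull gets the
  largest rank N; peak sum F + O ranked so the largest gets N. Ties take
  average ranks, which preserves each rank vector's total N(N+1)/2 and
  hence the cohort mean score N + 1 regardless of the data. The score is
  only defined relative to a cohort (N ≥ 2).
- **Severity index**: (O − 1.1) + (F − 1.15) + (1.70 − (R + L)). The
  "width of skull" here is the *sum* of both sides (control reference
  2 × 0.85 = 1.70), distinct from the tabulated width R/2 + L/2; both
  notions carry unambiguous names in the code (`width_sum` vs `width`).
  Components are not floored at zero — the formula is applied literally,
  and the per-component values are reported so either aggregation
  convention can be inspected. Classes: mild < 0.20 ≤ moderate < 0.35 ≤
  severe, boundaries inclusive on the severe side; the cut-offs are
  configurable but the defaults are the published ones.
- **Cranial indices**: traditional CI from the outline's extents along and
  across the anterior axis; curve CI = 100 × (R + L)/(F + O). Because the
  curve is cut 4 cm above the landmark plane rather than at the maximal
  anteroposterior extent, the curve CI can sit below the traditional CI on
  strongly peaked heads; the phantom sweep test checks this direction.

## Intracranial volume

The Cavalieri estimate: foreground area per analyzed axial slice × slice
spacing, summed, reported in mL. No between-slice interpolation is
applied. A voxel-count method (count × voxel volume) is kept as a mutual
check; on an axis-aligned binary grid the two are algebraically identical.
The analysis range (start just above the foramen magnum, end just beneath
the vertex) is the caller's responsibility via slice indices. A
slice-wise binary hole-fill utility is offered for masks with small
interior defects; the analysis itself assumes closed regions.

Normative classification interpolates mean and SD linearly at the
subject's age (no extrapolation outside the tabulated range), computes
z = (ICV − mean)/SD and assigns one of seven bands with steps at 0, ±1 and
±2 SD. "At mean" is |z| < 0.05 by default (configurable; the band is a
presentational convention with no canonical tolerance), and the outer
bands are strictly beyond ±2. The shipped normative table is **synthetic**
(a saturating growth model with SD = 8 % of mean, shaped like published
infant growth references); real reference data must be supplied for any
clinical use.

## Statistics

The overall visual score averages each of the six items over raters, then
sums the six averages (range 0–12). Interrater reliability is ICC(A,k) —
two-way random effects, absolute agreement, average measures — computed
from the two-way ANOVA mean squares as
(MS_rows − MS_err) / (MS_rows + (MS_cols − MS_err)/n). A grid with no
between-subject variance leaves the coefficient undefined and is reported
as such. The test suite cross-checks the implementation against both a
longhand sums-of-squares decomposition and an independent library
implementation.

Pearson's r carries a two-sided p-value from the t transform
t = r√((n−2)/(1−r²)); no multiple-testing correction is applied.
Interpretation labels use lower-inclusive bins — ICC (Landis–Koch): poor /
fair / moderate / good / excellent with edges at 0.20/0.40/0.60/0.80;
|r|: negligible / low / moderate / high / very high with edges at
0.30/0.50/0.70/0.90. Published verbal scales print abutting ranges
("0.61 to 0.80", "0.81 to 1.00"), so the half-open convention at the
shared edges is a choice; both bin sets are configurable.

## The phantom generator

A phantom outline is an ellipse (anteroposterior along x, anterior at
angle π) plus wrapped-Gaussian bumps: frontal boss at θ = π, occipital
bulge at θ = 0, negative temporal pinches at ±π/2. Bump amplitudes are
fractions of the mean ellipse radius, so a dial of 0.1 raises the
normalized curve's peak by roughly 0.1; σ = 0.5 rad makes the bump flanks
cross the 0.9/1.1 levels over a resolvable angular span. Radial Gaussian
noise (mm, per vertex) is optional and seeded; all outputs are
bit-reproducible given the spec.

Head volumes stack copies of the outline scaled by √(1 − (z/c)²), giving
an exact ellipsoid for zero dials; the continuous solid's volume (base
polygon area × 4c/3) is attached as ground truth, and voxelization marks
voxel centers inside the scaled polygon. Rater tables draw a latent
subject-item score that each rater reports with probability `agreement`,
else uniformly at random — agreement 1 gives identical raters (ICC = 1),
agreement 0 removes the subject effect (ICC ≈ 0).

`make_cohort` maps a single severity dial s ∈ [0, 1] to coupled
elongation, narrowing and bump amplitudes (with small seeded jitter to
decorrelate width from peak height). The mapping was set so the default
cohort sweeps the feature ranges reported for scaphocephaly cohorts —
severity index roughly 0–0.7, curve CI roughly 75 down to 55, peaks 1.1 to
1.36 — and is not adjusted per analysis.

**What the phantoms do not emulate**: real skull anatomy, CT intensities,
soft tissue, segmentation noise, asymmetry beyond the seeded jitter, or
ears and other secondary intersection loops. Passing tests therefore
establish the correctness of the geometric and statistical machinery under
known ground truth, not performance on clinical images.

## Problem sizes in the test and acceptance runs

Default runs use 360-sample curves, 21-phantom cohorts, a 1 mm digital
sphere of radius 50 mm (~0.5 M foreground voxels) for the volume oracle,
and 2 × 10⁶ Monte-Carlo points for the centroid oracle; these sizes hold
every oracle's error well below its tolerance while keeping a full run in
seconds.

## Known limitations

- The curve normalization (circular mean) reproduces the expected
  control-value scale but other UCSQ implementations may normalize
  differently; the mm scale factor is always recorded so curves can be
  re-normalized.
- Slices for ICV follow the voxel grid's z-axis, not the landmark frame.
- R/L assignment depends on the recorded outline frame; for imported
  outlines without frame metadata the default assumes the phantom
  convention.
- The rank-sum score is cohort-relative by construction: it cannot compare
  subjects across cohorts, only order them within one.
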