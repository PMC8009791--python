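# cranioquant

Quantifying the severity of **scaphocephaly** — the long, narrow head shape
caused by premature fusion of the sagittal suture — from the geometry of the
cranial outline.

The traditional clinical measure, the cranial index
CI = biparietal width / occipitofrontal length × 100 %, reduces the whole
head to two diameters and misses exactly the features that characterize
scaphocephaly: frontal bossing, occipital bulging and temporal narrowing.
`cranioquant` implements an outline-based alternative, the UCSQ (Utrecht
Cranial Shape Quantificator) pipeline, which turns the full cranial contour
into a dimensionless radial curve and reads severity from that curve.

## Method

Three external soft-tissue landmarks (left porion, left and right
exocanthion) define a reference plane; the cranial cross-section is taken
4 cm above it. From the section's center of mass, the distance to the
outline is sampled at every angle θ, normalized by the circular mean
radius, and phase-aligned so θ = 0 sits at the occipital maximum. The
resulting "sinusoid" curve y(θ) has mean 1 and, for scaphocephalic heads,
the monotone segment order descent–ascent–descent–ascent.

From the aligned curve the pipeline extracts:

- the extrema **F** (forehead maximum, near θ = π), **O** (occiput maximum,
  θ ≈ 0) and the lateral trough minima **R**, **L**, with positions
  X_F, X_R, X_L;
- derived variables: skull width R/2 + L/2, occiput and forehead
  prominences O − R/2 − L/2 and F − R/2 − L/2, and |F − O|;
- the abruptness of each monotone segment (D_o, A_f, D_f, A_o): the slope
  Δy/Δθ between the segment's crossings of y = 1.1 and y = 0.9.

Severity is then scored three ways:

1. **Cohort rank-sum score** — skull width (R + L; narrower ⇒ higher rank)
   and peak sum (F + O; larger ⇒ higher rank) are each ranked 1…N across a
   cohort and the ranks added. Scores span 2…2N; rank-sum conservation
   fixes the cohort mean at N + 1 (22.00 for N = 21).
2. **Severity index** — (O − 1.1) + (F − 1.15) + (1.70 − (R + L)), the
   deviation from control reference values, classified
   mild < 0.20 ≤ moderate < 0.35 ≤ severe.
3. **Cranial index** — traditional (outline extents) and curve-derived
   (100 × (R + L)/(F + O)).

The package also computes **intracranial volume** from binary masks by
Cavalieri slice summation, classified into SD bands against an age- and
sex-specific normative table, and provides the accompanying statistics:
visual-score aggregation (six items × three raters → 0–12), interrater
ICC(A,k) (two-way random, absolute agreement, average measures) with
Landis–Koch labels, and Pearson correlation with strength labels.

A parametric **phantom generator** (ellipse + Gaussian deformity bumps with
known analytic properties) stands in for patient CT data, so every stage is
testable end to end.

## Worked example

```python
import cranioquant as cq

spec = cq.PhantomSpec(
    base_length_mm=172, base_width_mm=112,
    frontal_bossing=0.03, occipital_bulge=0.04, temporal_narrowing=0.03,
)
outline = cq.make_outline(spec)
curve = cq.outline_to_curve(outline)        # normalized, aligned radial curve
f = cq.extract_features(curve)
value, cls = cq.severity_index(f)
```

prints (via the obvious `print` statements):

```
mean radius      : 68.7 mm
F (forehead max) : 1.29
O (occiput max)  : 1.29
R, L (troughs)   : 0.79, 0.79
width R/2 + L/2  : 0.79
abruptness Do,Af,Df,Ao: -0.47, 0.46, -0.46, 0.47
severity index   : 0.45  (severe)
CI (traditional) : 61.08
CI (curve)       : 61.08
```

Reading: both peaks reach 1.29 × the mean radius while the sides dip to
0.79, a strongly elongated head; the severity index 0.45 exceeds the 0.35
cut-off (severe), and both cranial indices agree near 61 %.

The same chain is available from the shell:

```bash
cranioquant phantom --length 172 --width 112 --bulge 0.04 --bossing 0.03 \
    --narrowing 0.03 --out outline.csv
cranioquant curve --outline outline.csv --out curve.csv
cranioquant features --curve curve.csv --out features.csv
cranioquant severity --features features.csv --out severity.csv
```

plus `icv`, `stats` and `run` subcommands (see `cranioquant --help`).

## Limitations

Phantoms are smooth analytic shapes, not skulls: passing tests demonstrate
the correctness of the geometry, scoring arithmetic and statistics, not
clinical performance. The normative volume table shipped for testing is
synthetic; supply real reference data for any clinical comparison. The
4 cm offset is measured along the landmark-plane normal, and curve
normalization uses the circular mean radius — both documented conventions
that users of other implementations should verify against their own.
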