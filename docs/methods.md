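# Methods

## Vector model

An astigmatic correction (magnitude *M* in diopters, axis *θ* in
degrees) is 180°-periodic, so it is decomposed on a doubled-angle plane:
X = M cos 2θ, Y = M sin 2θ. On that plane astigmatism vectors add and
subtract componentwise, and the inverse map is M = √(X² + Y²),
θ = ½·atan2(Y, X) wrapped into (0, 180]. The zero vector maps to
magnitude 0 with conventional axis 180; the 0° meridian is likewise
reported as 180 (so −2.00 × 90 converts to +2.00 × 180, matching
clinical printing convention). All "X/Y direction" statistics live on
this doubled-angle plane.

Per eye, with the surgical target taken to be emmetropia (the input
format carries no target column):

- TIA = preoperative vector (normalized to positive cylinder, OS axes
  mirrored);
- SIA = preop − postop in doubled-angle rectangular coordinates;
- DV = TIA − SIA, which under emmetropia reduces algebraically to the
  postoperative vector — an identity the property tests verify;
- CI = |SIA| / |TIA|, undefined (reported as `None`, never an error)
  when |TIA| = 0.

The SIA sign convention is preop − postop. Some literature defines the
achieved change with the opposite sign; the convention used here is
self-consistent with DV = TIA − SIA = postop and is applied verbatim
throughout.

### Normalization order

Both readings are first converted to positive cylinder, then OS axes
are mirrored (θ → 180 − θ), then TIA/SIA/DV/CI are computed. The two
axis maps commute mod 180, so the order does not affect results; the
mirror is applied before *all* computation and plotting so individual
points and averages live in one consistent frame.

### Cohort summaries

X/Y means are arithmetic; standard deviations use the sample (n − 1)
denominator (cohorts are samples; this matches common clinical
reporting) and are defined as 0 for n = 1. The vector mean is the polar
vector recovered from (mean X, mean Y). The CI population is summarized
by its geometric mean (ratios multiply, not add); undefined CIs
(zero-TIA eyes) and CI = 0 values (log undefined) are excluded and
counted, and zero-TIA eyes otherwise remain in the TIA/SIA/DV analyses
with magnitude 0 — eyes with 0.00 D of astigmatism are never
auto-discarded.

### Orientation sectors

Against-the-rule: (0, 30) ∪ (150, 180]; with-the-rule: (60, 120);
oblique: the rest. Axes exactly on a band boundary (30, 60, 120, 150)
are labelled oblique by default — the shaded bands are described by
their interiors and exact boundary hits are rare measurement artifacts —
but the classifier exposes a `boundary="shaded"` policy that assigns
them to the adjacent shaded band instead. The three labels partition
(0, 180] with no gaps or overlaps.

## Input handling

The reference dialect is headerless five-column XLSX; a CSV dialect is
provided for convenience. Deliberate strictness choices:

- A header-looking first row is an error (with a "remove header row"
  hint), never silently skipped — silent skipping hides data loss.
- Comma decimals ("1,50") are rejected with an explicit message rather
  than discarded as unparseable.
- A wrong column count is a format error naming the offending shape.
- Each discarded row (missing/blank/non-numeric cell, eye label other
  than OD/OS, magnitude ≥ 30 D, axis outside [0, 180]) is logged with
  its 1-based row number and the offending cell, and counted, so that
  rows in file = records kept + rows discarded.

Round-trip guarantee: a written dataset re-reads equal, field for
field. CSV serializes floats at full `repr` precision and is bit-exact
for any value; XLSX carries 15 significant digits (Excel's numeric
precision), which is bit-exact for all clinically quantized data
(0.25 D / 1° steps). XLSX workbook timestamps are pinned to a fixed
date so identical datasets serialize byte-identically.

## Synthetic cohorts

The generator emulates three demonstration cohorts — with-the-rule
(axes near 90°), against-the-rule (near 0°/180°), oblique (near 45°) —
of 25 eyes each, and is built backwards from a known ground truth so
the analysis can be closed-loop tested:

1. draw laterality (OS with probability `os_fraction`, default 0.5) and
   a preoperative magnitude from a normal truncated below at 0.25 D
   (mean 1.50 D, SD 0.75 D — a typical surgical cohort's cylinder
   range);
2. draw the preoperative axis from a wrapped normal around the type's
   center (90/180/45°, SD 4° — tight enough that ≥95% of eyes classify
   into the intended sector) in the *analysis* frame, un-mirroring on
   emission for OS eyes so analyzed axes center correctly regardless of
   laterality;
3. set the achieved treatment to `correction_ratio` (default 0.95, a
   realistic mild undercorrection) times the intended magnitude, applied
   at the intended axis perturbed by Gaussian noise (SD 2°), and obtain
   the postoperative vector by doubled-angle subtraction;
4. round magnitudes to 0.25 D steps and axes to whole degrees (clinical
   refraction granularity) and emit in negative-cylinder notation (the
   common clinical convention); both are configurable.

Rounding happens after outcome construction, so the correction ratio is
recovered *exactly* only with rounding disabled; exact-recovery tests
set `round_clinical=False`. With zero axis noise every defined CI equals
the ratio to floating-point precision; with 5° noise and n = 500 the
geometric-mean CI lies within ±0.02 of the ratio across seeds.

What the generator does **not** model: spheres and spherical
equivalent, vertex-distance effects, healing dynamics, and
within-patient correlation between fellow eyes. Passing closed-loop
tests therefore demonstrates the correctness of the vector arithmetic
and of parameter recovery under idealized independent eyes, not the
clinical realism of any particular cohort.

## Plotting

Upper-semicircle polar canvas, 0° at the right, 180° at the left, as
clinicians read corneal axes. Shaded sectors (blue ATR, red WTR, white
oblique), black radial line per eye ending in a blue circle marker, red
diamond at the vector mean on TIA/SIA/DV only — reporting standards omit
it on the CI graph. The radial limit is the smallest 0.5 D step covering
all points (for CI, 0.5 then doubling, since CI is a ratio). Each CI
point is drawn at its eye's TIA axis (the intended-treatment meridian);
that placement is a documented convention isolated in one function.
Styling (colors, fonts, 0.55 sector alpha, call-out at the upper right)
is fixed on purpose so figures from different studies remain directly
comparable. Export is TIFF at 300 dpi by default into a folder named
after the data file's stem; rendering a fixed spec is deterministic,
producing byte-identical buffers.

## Numerical choices and tolerances

- Axis wrapping uses `fmod(·, 180)` with 0 mapped to 180; all axis
  comparisons in tests treat 0/180 as one meridian.
- Vector round trips (polar → rect → polar) are exact to 1e−9 D in
  magnitude and 1e−7 degrees in axis; the SIA magnitude matches the
  law-of-cosines closed form √(M₁² + M₂² − 2M₁M₂cos 2Δθ) to 1e−9.
- Summation uses `math.fsum` for cohort statistics.
- Degenerate inputs: zero vectors carry axis 180; CI of a zero-TIA eye
  is `None`; an all-excluded CI population raises with an explanatory
  message, as does an empty vector collection.
- Printed summary precision: magnitudes 0.01 D, axes 1°, CI 0.01.

## Limitations

Only TIA, SIA, DV and CI are computed — no flattening/torque,
angle-of-error or index-of-success extensions, no vertex-distance
(spectacle-to-corneal-plane) conversion, no sphere or spherical
equivalent, no hypothesis tests, no double-angle plots, and no
vector-analysis tables. The emmetropic-target assumption is structural:
the five-column input format has no target column.
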