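# Methods

## Scope and model

echorange treats a quantitative ultrasonography study as a triple: a set
of 8-bit grayscale frames (one per subject), a polygonal ROI per frame,
and a per-subject table of group labels and numeric output variables
("markers"). All echotexture statistics are first-order: they depend only
on the histogram of ROI pixel intensities, never on spatial arrangement.

The pipeline order is convert → normalize → mask. Grayscale conversion
uses Rec.601 luma weights (0.299, 0.587, 0.114), rounded to the nearest
integer. Normalization is the per-image affine map
`G_i = T (f_i − f_min) / (f_max − f_min)` with `T = 255` by default,
rounded to the nearest integer with ties away from zero and clamped to
`[0, T]`; a single-valued image is rejected as degenerate. `f_min/f_max`
default to the per-image extremes; cohort-wide extremes can be passed
explicitly (`global_minmax`) when frames must stay mutually comparable.
The map is idempotent on integers and order-preserving.

ROI rasterization marks a pixel inside iff its center satisfies the
even-odd rule; the crossing test counts an edge only when the horizontal
ray passes strictly to the right of the center, which makes left/top
edges inclusive and right/bottom edges exclusive, so abutting polygons
partition pixels exactly. Coordinates are 0-based with `x` = column and
pixel `(r, c)` centered at `(c, r)`.

## Statistics

Band and whole-ROI SDs are population SDs (divide by `n`), the convention
of bitmap-analysis software; `ddof=1` switches to the sample form. Empty
bands report missing (NaN) NPV/SD rather than zeros — a subject without
pixels in a band contributes no value, and missing cells propagate as
empty CSV fields. The banding identities (EI% sums to 100 over an
exhaustive band spec, count-weighted band NPVs reconstruct the whole-ROI
mean, within- plus between-band variance reconstructs the whole-ROI
variance) are enforced in the test suite at 1e-9.

Pearson correlations use the product-moment formula with a two-tailed p
from `t = r√(n−2)/√(1−r²)` on `n−2` degrees of freedom (`p = 0` at
|r| = 1); zero-variance inputs raise instead of returning NaN. The group
comparison is the classical pooled-variance Student t (Welch available
behind a flag), with per-group SEMs. Cohort-level correlations pool both
groups; subjects missing a value are excluded pairwise and cells with
fewer than 3 complete pairs stay missing. No multiplicity correction is
applied to band-level tables; the permutation test below is the remedy
for the searched maximum, which is where selection actually concentrates.

## Range search

All `(L+1)(L+2)/2` contiguous intensity intervals are enumerated
(32,896 at L = 255). Per-subject cumulative pixel-count and intensity-sum
tables indexed by intensity make any in-range count/sum a table
difference; since pixel sums are integers far below 2^53, the resulting
means are bit-identical to naive recomputation, and the exhaustive scan
is a handful of vectorized matrix products.

The objective is max |r|: strong negative correlations are as meaningful
as positive ones. Admissibility: a subject enters a range only with at
least `min_pixels_per_subject` (default 1) in-range pixels; ranges
keeping fewer than 3 subjects are skipped; strict mode requires all
subjects. The vectorized scores are used to shortlist candidates within
1e-6 of the maximum, which are then re-scored with the exact Pearson
kernel so the selection never depends on the vectorized formula's
rounding; ties within 1e-9 of the best |r| are broken toward the narrower
interval, then the smaller lower bound, and the full tie list is
reported. The reported r therefore equals `pearson()` applied to the
per-subject range means exactly. EI% and in-range SD of the selected
range are computed per subject for reporting alongside the NPV.

Analyses that hunt for a planted or biologically localized range (the
recovery tests, the study-design emulation, the worked examples) run in
strict mode. With pairwise exclusion at the 3-subject floor, a
near-empty high-intensity range can retain exactly three subjects whose
one-or-two-pixel means correlate almost perfectly by chance; over tens of
thousands of ranges such fragile candidates dominate any genuine signal.
Requiring every subject to contribute removes that failure mode without
touching the statistics of well-populated ranges.

### Permutation inference

`max_r_permutation_test` shuffles the output variable across subjects
with a seeded generator and reruns the identical search on each shuffle;
`p = (1 + #{null max |r| ≥ observed}) / (n_perm + 1)` is a valid
family-wise p for the selected range. The prefix tables and range
matrices are y-independent and built once, so each permutation costs
three small matrix-vector products. On null cohorts these p-values are
uniform (KS-tested in the suite) while the naive p of the searched
maximum rejects at far above the nominal rate.

### Scattered sets

The per-subject mean over a *single* intensity value is that value
itself — constant across subjects — so no singleton has a defined
correlation and a greedy build-up cannot start from one intensity. The
scattered-set search therefore scores every two-intensity set
exhaustively, starts from the best pair (ties to the lexicographically
smallest), and then greedily adds the intensity that most increases |r|,
stopping at a 1e-9 improvement tolerance or a size cap. Exhaustive
subset search over 2^256 sets is impossible; the greedy trace (each
accepted intensity with the score after adding it) keeps the heuristic
auditable.

## Synthetic cohorts

The generator emulates a 12-subject, two-group (6 sham / 6 surgery)
imaging study. Defaults, with rationale:

- **Background**: per-pixel Gamma(shape 4, scale 16) intensity, rounded
  and clipped to [0, 255] — a heavy-tailed stand-in for B-mode speckle
  brightness with mean ≈ 64. Images are 110×110 with an octagonal ROI of
  ≈ 8,750 pixels.
- **Per-subject echogenicity jitter** (`background_jitter = 0.2`,
  log-normal on shape and scale): real muscles differ in overall
  echogenicity independently of any focal signal. This heterogeneity is
  load-bearing: with an i.i.d. background, the mean of *any* interval
  containing the planted range is an affine function of the planted mean
  and — Pearson being affine-invariant — carries an identical
  correlation, so no search could localize the signal even in principle.
- **Planting by redraw**: pixels whose background value falls in the
  planted range (86–101 by default) have their values redrawn from a
  normal centered at
  `center + plant_amplitude · half_width · tanh(latent/2)`
  (`plant_amplitude = 0.15`), recentered so the realized in-range mean
  equals the target exactly. Counts are untouched, so the range's EI%
  and SD carry no group signal — only its NPV does, which is precisely
  the contrast the toolkit is supposed to detect.
- **Per-subject spread jitter** (`spread_jitter = 0.5`, log-normal on the
  redraw SD, `plant_spread = 0.35` of the half-width): without it, every
  narrow strip inside the planted range is a deterministic monotone
  function of the latent and ties with the full range; the jitter makes
  strip-level means noisy while the recentering keeps the full-range
  mean pinned.
- **Latent severity**: standard normal per subject plus
  `group_effect = 4` (latent SD units) for surgery subjects. The tanh
  link saturates, so this produces a clear range-NPV group separation
  while the amplitude stays small. The group t-statistic on the planted
  range NPV is amplitude-invariant (gap and within-group spread scale
  together), but band-level leakage is not — a small amplitude is what
  keeps 50- and 25-wide band NPVs statistically silent while the range
  NPV separates cleanly.
- **Markers**: each coupled marker is
  `baseline · (1 + 0.4 · (ρ·m̃ + √(1−ρ²)·ε))`, with `baseline`
  log-normal, `m̃` the standardized realized in-range means and ε
  i.i.d. normal. The linear-Gaussian link pins the population Pearson
  correlation at the coupling target ρ (default 0.9) exactly, and at
  ρ = 1 the marker is exactly affine in the in-range mean so the search
  reaches |r| = 1. Surgery/sham fold changes land near 2. Null markers
  are independent log-normals. A floor at 2% of baseline keeps rare deep
  noise draws positive; it is never active at ρ = 1.
- **Distractor ranges** (20–40 and 130–160): independent latent
  directions with no group effect and no marker coupling — stand-ins for
  the many biological sources of echotexture variation a real muscle
  carries. Without them a null marker that chance-correlates with the
  single structured direction would select a group-affected range.
- **Anchors**: each frame carries one black and one white pixel in the
  top corners, outside every default ROI, so frames span the full 8-bit
  range and per-image min-max normalization is the identity on them (the
  frames are generated directly on the post-normalization scale).

All randomness flows from one seed through named substreams (images,
latent, markers, noise). `generate_null_cohort` forces every coupling to
zero; passing `group_effect = 0` as well yields a fully signal-free
cohort for calibration runs.

What the generator does **not** emulate: spatially correlated speckle
(pixels are i.i.d. given the histogram), attenuation/depth gradients,
anatomy (septa, fascicle boundaries), scanner point-spread functions, and
operator variability. Tests passing on these cohorts demonstrate the
correctness and calibration of the algorithms — exact search, valid
selection-adjusted inference, banding identities — not that any
particular tissue will carry a recoverable range signal.

## Problem sizes in the test and acceptance runs

Oracle-equivalence checks use 20 random cohorts (L = 31, 10 subjects,
500 pixels). Planted-range recovery uses 50 default cohorts
(12 subjects, ≈ 8,750 ROI pixels); the recovery criterion — selected
range within Jaccard ≥ 0.5 of truth in at least 40/50 seeds — was
calibrated once against this generator at coupling 0.9 and then frozen.
Null calibration uses 200 cohorts at 64×64 pixels with 199 permutations
each; the study-design emulation uses 12 default cohorts. These sizes
keep the whole suite at a few minutes on one CPU while leaving each
Monte-Carlo estimate well-resolved.

## Known limitations

- The range search is exhaustive only over contiguous intervals; the
  scattered-set extension is greedy and can miss jointly-optimal
  intensity sets that no pair anticipates.
- Pairwise-exclusion mode compares correlations computed on different
  subject subsets; |r| values across ranges are then not strictly
  commensurable (strict mode avoids this).
- The permutation test assumes exchangeability of the output variable
  across subjects under the null; with strong group structure in the
  images, a group-stratified shuffle would be the conservative variant
  and is not currently implemented.
- At n = 12 the sampling noise of r is large; even a true coupling of
  0.9 yields selected ranges that occasionally drift off the planted
  interval. This is a property of the design, not of the implementation.
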