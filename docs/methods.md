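# Methods

This note documents the models, parameter choices and numerical
conventions behind `pvs_sas`, and what the synthetic-data tests do and
do not establish about real data.

## Imaging model and geometry

The pipeline targets axial T2-weighted turbo-spin-echo acquisitions at
7T: 0.2 × 0.2 mm in-plane spacing (interpolated from 0.4 × 0.4 mm),
2 mm slice thickness with a 0.6 mm inter-slice gap.  All computation is
per-slice 2-D: perivascular spaces are treated as independent objects
on each slice, with no 3-D linking across slices.  Indexing is
`(row, col, slice)`, 0-based, half-open; physical position is index ×
spacing.  NIfTI headers carry only the slice *pitch*, so the
thickness/gap decomposition is supplied through configuration (default
2 + 0.6 mm).

## White-matter mask preparation

The mask (produced externally from a T1 segmentation) is prepared in a
fixed order:

1. **Hole filling** — enclosed background components strictly smaller
   than 200 px are filled.  These are partial-volume islands of gray
   matter inside white matter; the strict inequality follows the
   documented cutoff.  The operation is idempotent.
2. **Smoothing** — Gaussian blur of the 0/1 field at σ = 1 px,
   re-binarized at 0.5.  The 0.5 level approximately conserves mask
   area; no other level was documented.
3. **Interior region** — pixels whose Chebyshev distance to the
   nearest background exceeds 8 px (erosion by a 17 × 17 square).
   Detections are gated on the interior *after* filtering rather than
   eroding the image before filtering: filtering the full slice and
   keeping objects that intersect the interior is order-independent
   and reproducible.  The square (Chebyshev) metric matches the square
   structuring elements conventional in the originating environment.

## Intensity normalization

Frangi's structureness weight β₂ and the downstream vesselness
threshold only have meaning on a fixed intensity scale, so each slice
is affinely rescaled from its in-mask percentiles: the 1st percentile
maps to 0 and the 99th to 1, with only the lower tail clipped.

Two properties drove the anchor choice:

- MRI-visible perivascular spaces occupy roughly 1–2% of white-matter
  pixels (consistent with ~2 × 10³ objects against a ~0.5 dm³
  compartment), so the **99th percentile sits at the top of the tissue
  distribution, below the CSF-bright structure cores**.  Those cores
  then map above 1 and the ridges present their full contrast to the
  filter.  An anchor above the structure fraction (e.g. 99.9%) lands
  *inside* the brightest structures and caps normalized ridge amplitude
  at ~1 — where the theoretical maximum response of an ideal Gaussian
  ridge under β₂ = 0.35 and γ = 2 normalization is ≈ 0.454, i.e. at
  the detection threshold itself, making detection knife-edge.
- The top is left **unclipped** on purpose.  Clipping at 1 flattens
  structure cores into plateaus whose interior curvature vanishes at
  the 1.4–3.2 px scales, which measurably destroys detection; real MRI
  does not saturate, and the curvature of the brightest structures is
  exactly the signal of interest.  The lower clip at 0 is harmless
  (background noise floor).

Both percentiles are configurable (`normalize:` block).  A constant
in-mask slice is rejected as a degenerate intensity range.

## Vesselness filter

Gaussian-derivative Hessians are computed separably with reflective
boundary handling, multiplied by σ² (γ = 2), eigen-decomposed in
closed form per pixel and ordered by magnitude.  The second-derivative
kernels are projected to an exactly zero DC component — truncated
sampled kernels otherwise respond to constants at the 1e−4 level —
which makes vesselness exactly invariant to intensity offsets and
constant images yield identically zero curvature.

Filter defaults follow the published operating point: scale range
1.4–3.2 px with step 2, β₁ = 0.95, β₂ = 0.35, threshold 0.4.  The
step parameter is read as the increment of an arithmetic scale
progression whose upper endpoint is always included, giving the
two-scale list {1.4, 3.2}; a strict progression would degenerate to a
single scale, contradicting the notion of a scale *range*.  Those σ
(0.28–0.64 mm) match ridge half-widths of the PVS calibre at 0.2 mm
spacing.  Polarity defaults to bright-on-dark (PVS are CSF-filled and
hyperintense on T2); the switch is exposed.  R_B is defined as 0 where
λ₂ = 0; the S = 0 clause then forces V = 0.

## Segmentation

Vesselness > 0.4 (strict) inside the white-matter interior is labeled
with 8-connectivity (thin oblique cross-sections fragment under
4-connectivity); object ordering is deterministic (row-major by first
pixel).  The intensity-outlier filter pools all candidate objects of a
subject, computes the mean and sample SD of their mean normalized
intensities, and retains objects within k = 2 SD (two-sided).  The
filtered population is the candidates' own mean intensities, not all
white-matter pixels — the rule addresses objects, and that reading
makes it scale-free.  Guards: with fewer than 3 candidates or zero
spread, all are retained.  Edit lists support only removal, matching a
review protocol in which no markings are ever added; minimum object
size defaults to 1 px (no documented minimum).

## Quantification

Per object: area = pixels × 0.04 mm²; volume = area × 2 mm (the
excited slab; the gap contributes no signal), equivalent diameter
√(4·area/π) (so π/4·d² equals the area exactly), and long/short axes
from the ellipse with the region's normalized second central moments,
evaluated at the physical spacing.  Per subject: count, total volume
(exactly-rounded summation, hence order-invariant), medians (midpoint
convention), white-matter volume = mask pixels × pixel area × pitch
(2.6 mm — the full coverage including the gap), and density = count
per cm³ of white matter, with the raw per-mm³ ratio also exposed.
Object volume excludes the gap while compartment volume includes it;
mixing the two conventions would bias density by 30%.

## Overlap validation

Bounding boxes are tight, axis-aligned, half-open.  Two markings on one
slice are consistent when their boxes, each dilated by the tolerance
(default 4 mm = 20 px), intersect (closed); equivalently the per-axis
gap is ≤ 2 × tolerance.  A single-dilation variant is a config switch.
Matching is many-to-many: any overlap marks both objects as matched, so
counts are monotone in tolerance and symmetric under swapping the two
sets.  Sensitivity is the matched fraction of the reference set; the
matched fraction of the candidate set is reported as **precision** —
object detectors have no countable true negatives, so no true
specificity exists; the conventional alias is kept on the result object
for comparability.  Voxel agreement reports Dice, Jaccard and both
directed overlap fractions; all are flagged absent when undefined.

## Statistics

Shapiro–Wilk (Royston's AS R94 approximation, 3 ≤ n ≤ 5000) gates each
correlation at α = 0.05 (no α was documented; 0.05 is the convention):
Pearson when both margins pass, Spearman (midranks under ties)
otherwise.  Partial correlations residualize both variables — and, for
Spearman, their ranks and the covariates' ranks — on an intercept plus
covariates by least squares and correlate residuals; p-values use
t = r√(df/(1−r²)) with df = n − 2 − k.  Gender enters as a 0/1
covariate.  Group tables use pooled-variance two-sided t-tests
(pooled, not Welch, reproduces the published age comparison p = .127
from its summary statistics) and Yates-corrected 2 × 2 χ² (the
corrected statistic reproduces the published gender p = .707; the
uncorrected one gives .499).  No multiple-testing correction is
applied, matching the source analysis; reports annotate the number of
tests run.

## Synthetic phantoms

Each slice holds an elliptical white-matter compartment at a uniform
baseline, a bright CSF-like rim just outside it (exercising the
boundary-margin logic that suppresses rim false positives), and bright
line segments of Gaussian cross-section placed by rejection sampling
(centerline separation ≥ 1.2 mm, fully inside the ellipse with a
2.5 mm margin), plus white Gaussian noise.  Truth labels mark each
structure's half-maximum support, so labeled width = FWHM = 2.355 σ_w.

Default conditions, with their provenance:

| parameter | default | basis |
|---|---|---|
| in-plane spacing / thickness / gap | 0.2 mm / 2 mm / 0.6 mm | target acquisition |
| WM ellipse semi-axes | 28 × 40 mm (~3500 mm²) | 0.49 dm³ WM over 54 gapped slices |
| structures per slice | 20 | evaluation condition |
| width σ_w | 0.25–0.45 mm | measured PVS short axes ≈ 0.6–1.1 mm FWHM |
| length | 1–4 mm | PVS long-axis calibre |
| amplitude | 3.2–3.9 × WM baseline | CSF:WM ≈ 4–5 at TE ≈ 59 ms (WM T2 ≈ 47 ms, CSF T2 > 1 s) |
| noise σ | baseline/10 | white-matter SNR 10, standard convention |

Noise is Gaussian, not Rician: at WM SNR 10 the Rician correction is
< 1%, and the Gaussian model keeps the generator analytic.  Segments
are straight; the filter's response is local, so in-plane curvature
does not affect what the tests probe.  The phantom does **not**
emulate bias fields, motion, white-matter hyperintensities,
through-plane partial volume, or anatomy-dependent mask topology —
passing detection tests on phantoms demonstrates the algorithm's
correctness at its operating point, not clinical accuracy on patient
scans.

The cohort generator draws (age, trauma-experienced count,
trauma-horror count, total PVS volume) from a Gaussian copula with
latent correlation r = 2·sin(πρ/6) for each target Spearman ρ
(trauma–volume default 0.5, age–volume 0.5, between trauma counts
0.8; trauma ⟂ age).  Marginals per group follow the published
two-group summary table: truncated-normal ages, zero-inflated Poisson
trauma counts, log-normal total volumes, normal nuisance volumes.  The
target is a *within-group* quantity; because groups differ in trauma
but not volume marginals, the pooled coefficient is attenuated
~10–15% (ordinary stratum-mixing attenuation), and count ties cost a
further ~2–3%.  Brain (1.1 × 10⁶ mm³) and CSF (1.5 × 10⁵ mm³) volumes
are typical adult values used as covariate fodder.

## Numerical conventions and degenerate inputs

- Strict `>` at the vesselness threshold; ties have measure zero.
- Medians use the midpoint convention; empty measure sets are `None`,
  never 0.
- Empty reference or candidate sets yield absent (None) rates; both
  masks empty yields absent overlap metrics.
- Sample SD (ddof = 1) in the outlier filter and group tests.
- `fsum` for volume totals: exactly rounded, order-invariant.
- Seeds: every stochastic component takes an explicit seed;
  `numpy.random.default_rng` throughout.  Pipeline outputs are
  byte-identical across reruns of one config + seed.

## Problem sizes in the test and acceptance suites

Detection is evaluated on 10 slices × 20 structures (432 × 512 px
slices, ~88 k-pixel masks); oracle equivalence on 10 random 64 × 64
fields (filter) and 100 random instances up to 50 objects per side
(matcher); correlation recovery at n = 500 subjects; convergence
checks at n = 10⁴.  These sizes give each check sub-percent sampling
noise relative to its acceptance band while keeping the full suite
under a minute of compute.

## Known limitations

- Per-slice 2-D analysis undercounts nothing but *splits* structures
  crossing slices; measures are therefore per-marking, not per-vessel.
- The density unit (count per cm³) is one of several in circulation;
  the raw per-mm³ ratio is exposed for cross-study comparison.
- The outlier filter assumes a roughly unimodal candidate-intensity
  population; heavy contamination (e.g. large hyperintense lesions)
  would shift μ and s and weaken it.
- The reviewer mechanism is list-based and non-interactive by design;
  it reproduces the audit trail, not the ergonomics, of a GUI.
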