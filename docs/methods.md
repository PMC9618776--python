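# Methods

This note documents the measurement procedures, the synthetic data model, the
numerical choices behind them, and their known limitations.

## Nuclear circularity

For a single-nucleus binary mask, area is the foreground pixel count scaled by
the squared pixel size, and circularity is the shape factor `4πa/p²` — 1 for a
circle, below 1 for anything else. The quantity is entirely determined by the
quality of the perimeter estimate `p`: counting boundary pixels of a digital
circle overestimates its perimeter by roughly 27% (the staircase effect),
which would depress circularity of a perfect circle to ~0.63.

The estimator used here:

1. smooth the binary mask with a small Gaussian (σ = 0.8 px, constant-mode
   padding);
2. extract the 0.5 iso-contour with marching squares (subpixel vertices);
3. low-pass the closed contour with a circular moving average whose window
   grows with contour length (`max(3, round(n/150)) | 1` points), removing
   marching-squares quantization wiggle without flattening genuine corners of
   small objects;
4. sum the polygon segment lengths.

On rasterized test shapes this lands at 0.9975 for a radius-100 circle,
0.7983 for a 100-px square (continuous value π/4 ≈ 0.7854; the ~1.6%
excess is corner rounding by the smoothing, which is why the smoothing
scales are kept small), and 0.8386 for a 2:1 ellipse (Ramanujan-perimeter
value 0.8413). Rotating an ellipse moves the result by <0.2%; at fixed area,
measured circularity is strictly monotone in the axis ratio over 1–4; for
circles the error decreases with radius from 20 to 200 px. Measured values
are *not* clamped at 1 — an estimator overshoot (bounded in validation by
+0.02) stays visible as a QC signal rather than being silently hidden.

Preconditions are enforced, not assumed: exactly one 4-connected foreground
component, at least 9 px, not touching the image border; each violation
raises a distinct error. Time-lapse series report one record per frame
(`time = (frame − t0) · interval`, default 7-minute intervals, with an
annotatable t = 0 event frame such as the moment of basal extrusion); a
failing frame is flagged with its index and NaN values rather than aborting
the series.

Group summaries use the sample (n−1) standard deviation and SEM = SD/√n;
a singleton group's SD is reported as missing, never 0.

Whether nuclear masks should be drawn on a single optical section or on a
projection is an acquisition-side decision; this implementation measures
whatever 2D mask it is given and records nothing else.

## Cell density

`density = nuclei / area` over a maximum intensity projection of a thin
substack taken a fixed depth window below the tissue surface. Depths are
specified in µm and converted to slice indices by flooring against the
z-step, with half-open windows: [19, 21) µm at 0.5 µm steps is exactly 4
slices, [15, 20) µm is 10. The surface depth comes from annotation (or the
generator's ground truth); an automatic mode takes the first z-slice whose
membrane-channel mean exceeds the top-slice mean + 3 SD.

Nuclei are counted by their centroids — a nucleus belongs to the ROI iff its
centroid lies on an ROI pixel (boundary pixels included). The centroid rule
is unbiased for nuclei straddling the ROI edge and makes counts additive
over disjoint ROIs. Centroids are either supplied (manual annotation) or
detected as Laplacian-of-Gaussian blobs band-passed around the expected
nucleus radius; on well-separated synthetic nuclei (spacing ≥ 4 radii) the
detector's recall and precision both exceed 95%. Cells-per-somite counts are
the same counting operation over a one-slice window.

## Invasion scoring and marker positivity

A cell is *invaded* iff its centroid z is strictly greater (deeper) than the
epithelial surface depth at its (y, x); exactly at the surface counts as
surface, and positions where the surface map is undefined yield `unassigned`
with a warning — unassigned cells never enter a percentage. Cells flagged as
excluded (e.g. annotated reporter mis-expression) are removed before any
counting.

Marker positivity is called as mean intensity within the cell footprint
strictly above background mean + k·SD (default k = 2, exposed in the CLI).
Published scoring of this kind is typically done by eye; the explicit
threshold is a reproducible proxy, and outputs record the rule and k so the
proxy is auditable. With positive/negative intensity distributions separated
by ≥ 6 background SDs — the regime the generator emulates — the called
fraction converges to the generative fraction (checked at n = 100 and 1000,
within 3 percentage points at n = 1000).

Percentages are per embryo: positive invaded cells over all non-excluded
invaded cells, × 100. An embryo with an empty denominator is omitted with a
warning, not scored 0%. The statistical unit is the embryo for percentage
readouts and the cell for nuclear circularity, mirroring the mixed
convention of the experimental literature this pipeline serves; cohort-level
summaries state their n explicitly.

## Internal cell masses and embryo area

Masses are detected on the whole-embryo reporter MIP: threshold
τ = mean + k·SD with k = 4 by default, both statistics computed over the
full projected image (population SD). Components (8-connectivity by
default) smaller than 0.0025 mm² are ignored — the floor exists to exclude
single cells, and the boundary case exactly at the minimum is kept since
only strictly smaller objects are dropped. An exclusion mask removes
annotated mis-expressing cells before labeling. The detected mask is
invariant to adding a constant to the image or multiplying it by a positive
factor, and raising the minimum area can only reduce the mass count.

Whole-image threshold statistics read the procedure literally; they are only
meaningful while bright signal occupies a small fraction of the field (a few
percent — beyond that the signal inflates the SD and the threshold chases
it). For crops where the embryo fills the frame, `threshold_domain="roi"`
restricts the statistics to an embryo ROI instead.

Each mass can be confirmed *internal* by comparing the reporter channel's
intensity-weighted z centre of mass over the mass footprint against the mean
epithelial surface depth there; a surface map undefined over more than half
the footprint leaves the mass unconfirmed with a warning.

Embryo lateral area is segmented from a boundary-marker MIP at mean + 2 SD,
keeping the largest component and filling holes; segmentation fails loudly
on blank images or when the component hugs most of the border. A manual
outline polygon is accepted as the alternative and integrated by its
shoelace area (via shapely).

## Nonparametric statistics

The test statistics and the exact Mann–Whitney null distribution are
computed in-package; scipy supplies rank assignment and the reference
normal/chi-square distribution functions, and scipy's own tests serve as
independent cross-checks in the test suite only.

- **Mann–Whitney U**: U = min(U_x, U_y) with U_x = R_x − n_x(n_x+1)/2.
  For combined n ≤ 20 without ties, the exact two-sided p doubles the lower
  tail of the enumerated U distribution (Gaussian-binomial recurrence),
  capped at 1. Otherwise a normal approximation with tie-corrected variance
  `n₁n₂/12 · ((N+1) − Σ(t³−t)/(N(N−1)))` and a 0.5 continuity correction is
  used. Identical pooled samples give p = 1. The exact mode matches
  brute-force enumeration over all rank interleavings for every tie-free
  input tested (combined n ≤ 12, exhaustively enumerated); the null
  rejection rate at α = 0.05 is ~0.049 over 10,000 two-sample replicates at
  n = 24/25. Whether exact or asymptotic p-values are wanted can be forced
  via `mode`; `auto` is recorded semantics, not hidden state.
- **Kruskal–Wallis** (≥ 3 groups): H with the tie-correction divisor
  `1 − Σ(t³−t)/(N³−N)`, p from chi-square with k−1 df. All-identical data
  gives H = 0, p = 1; two groups are redirected to Mann–Whitney.
- **Holm–Šidák**: sorted ascending, adjusted p_(i) = 1 − (1 − p_(i))^(m−i+1),
  running-maximum monotonicity, capped at 1, returned in input order.
- Stars follow the 0.05/0.01/0.001 legend convention, applied to adjusted
  p-values when an adjustment was made.

Two-sided p by tail doubling is a convention choice; the symmetric null of U
makes it equivalent to the two-tail sum except at the distribution centre,
where capping at 1 resolves the overlap.

## Synthetic data model

The generator emulates the statistical structure the analysis assumes, in
two imaging regimes: cell-level stacks (0.5 µm z-steps, sub-micron-to-1 µm
pixels, nuclei tens of pixels across) and whole-embryo fields (~1 µm pixels,
millimetre extent) for mass detection and embryo area.

An embryo stack carries five channels — nuclear, membrane, reporter, marker,
boundary — over a flat periderm plane at a configurable depth (default 5 µm).
The surface geometry is deliberately a plane, not a curved sheet: every
consumer of the surface needs only above/below semantics. Nuclei are
anti-aliased filled ellipses (ellipsoids across z, 4 µm z semi-axis) at
uniform random orientations in [0, π), placed by rejection sampling with a
minimum spacing (bounded attempts, then a density error). Per-population
circularity targets (surface 0.94 ± 0.05, invaded 0.83 ± 0.05 by default,
n = 25/24) are converted to axis ratios by numerically inverting the
analytic ellipse circularity (Ramanujan perimeter, Brent's method); the
ground-truth table stores the analytic area πab, perimeter and circularity
per nucleus. Binary masks are produced by area-preserving binarization —
the N highest-coverage pixels with N = round(total coverage) — because plain
0.5-thresholding biases small curved objects' pixel areas upward by a few
percent. Rendering refuses nuclei whose minor axis would fall below 3 px.

Marker positivity is Bernoulli per cell with a per-population fraction
(defaults 0.05 surface / 0.29 invaded); positive and negative marker
amplitudes are separated by far more than the calling threshold. Internal
masses are bright discs (~8 µm thick plugs beneath the surface) whose
amplitude is set well above what a mean+4SD threshold can reach in the
rendered field — the planting contract, that every planted mass's peak
exceeds the post-noise image mean + 4 SD, is verified by test. Mass
amplitude exceeds single-cell reporter amplitude because a mass is a 3D
aggregate of labelled cells collapsing onto one MIP footprint. Additive
Gaussian noise (SD 10 on a background of mean 100) is applied last; an
optional Poisson-like signal-dependent term is off by default since nothing
downstream depends on the noise being signal-dependent.

All randomness flows from explicit integer seeds through numpy Generators;
identical (config, seed) reproduces stacks and tables bit for bit, and the
end-to-end runner writes byte-identical CSVs on identical runs (metadata
headers contain the seed and parameters, never timestamps).

What the generator does **not** model — and therefore what passing tests do
not establish about real data: optical PSF blur and axial anisotropy of real
confocal stacks, curved periderm geometry, touching/overlapping nuclei,
intensity inhomogeneity across the field, autofluorescence structure, and
segmentation error in manual masks (synthetic masks are exact rasterizations
of the true geometry). The pipeline's correctness is established on its own
stated contracts; its accuracy on real microscopy inherits the quality of
the inputs (masks, surface annotations, channel registration).

## Problem sizes and runtime choices

Validation uses problem sizes chosen to estimate each quantity comfortably
on a laptop-class single core: 50 seeded whole-embryo fields (1024² px,
1–2 masses each) for the detector contract plus 50 pure-noise fields;
10,000 replicates for null calibration; 1,000 replicates for cohort power;
25/24-nucleus cohorts (8 replicates in the acceptance script) for parameter
recovery; 3–8 synthetic embryos per cohort for end-to-end runs. Mass-field
sizes keep planted signal below ~5% of pixels, inside the whole-image
threshold's working regime documented above.

## Known limitations

- The perimeter estimator's smoothing rounds corners slightly (~1.6% high on
  a square's circularity); polygonal nuclei are not a realistic morphology,
  so the circle-accurate tuning is the right trade.
- Exact Mann–Whitney is implemented for tie-free data only; tied data uses
  the corrected normal approximation regardless of sample size.
- The LoG counter assumes roughly round, non-touching nuclei; clumped nuclei
  would need a watershed-style splitter that is out of scope.
- Whole-image mass-threshold statistics degrade when bright objects occupy
  more than a few percent of the field (use the ROI domain option there).
- Neuron-like morphology and anatomical region labels (yolk/tail/head) are
  consumed as annotation columns; no shape or anatomy classifier is fit.
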