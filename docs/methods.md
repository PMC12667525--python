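# Methods

## The measurement model

Each organoid is acquired as a two-channel Z-stack (fibrosis reporter,
nuclear stain), 1–64 planes, unsigned 16-bit. The analysis operates on
per-channel maximum-intensity projections (MIP) only; plane-wise
segmentation is deliberately not implemented, since the per-object
readouts (total fluorescence, counts, areas) are defined on the
projection. Coordinates are pixel-centered, 0-based (row, col); masks
are per-pixel binary. Intensities are used as recorded — no background
subtraction by default (an optional rolling-ball correction exists
behind `SegmentationParams.rolling_ball_radius`).

## Segmentation

Per channel: Gaussian smoothing (σ = 0.5 px) → global Otsu threshold →
half-max refinement → morphological opening (disk radius 1) → removal of
components below 12 px. A constant image yields an empty mask with a
`no_threshold` flag rather than an error.

*Half-max refinement.* Global Otsu systematically under-thresholds
images whose foreground occupies a small pixel fraction: the dominant
background class pulls the threshold down, dilating every object by a
band proportional to the total blur. The refinement re-sets the
threshold to the full-width-at-half-maximum level,
`t = b + (p − b)/2`, where `b` is the median background intensity and
`p` the foreground plateau estimated as the 25th percentile of the
eroded-foreground ("interior") pixels. The low quantile makes the
plateau estimate robust to regions where overlapping structures sum to
above the single-structure level. For a step edge blurred by any
symmetric PSF the half-max contour passes through the true boundary, so
mask areas are recovered almost unbiasedly (≤ ~3% error on noise-free
simulated organoids, ≤ 15% under full noise). The refinement assumes
plateau-like foreground and is therefore applied to the fibrosis
channel only; nuclei are center-peaked, and their masks use the plain
Otsu split.

*Organoid footprint.* The organoid ROI is the filled convex hull of the
union of both channel masks; it is the denominator for area-fraction
and density features. There is no third (brightfield) channel to
delineate the organoid independently.

## Nuclei counting

Nuclei overlap in projection, so connected components undercount. The
count is the number of watershed basins seeded at local maxima of the
smoothed nuclei MIP (σ = 0.7 px, minimum seed separation 1 px,
plateau maxima collapsed to one seed) restricted to the nuclei mask.
This relies on nuclei being brightest at their centers, which holds for
DNA stains and is how the simulator renders them. At the default
simulated density (100 nuclei, 90 px organoid radius, full noise) the
count is within ±10% of truth for ≳95% of organoids with a mean bias of
about −4% (residual merging of centers that project within ~2 px of
each other); across screens the counted/true Pearson r exceeds 0.99.
Counting degrades gracefully with noise: at 4× the default read noise
the mean bias is ≈ −13%, driven by mask shrinkage rather than spurious
peaks.

## Features, matrix, scaling, selection

Eighteen features per organoid: fibrosis channel — integrated intensity
(IntDen), mean/SD/95th-percentile intensity in mask, mask area, area
fraction of the organoid ROI, component count, largest component area,
mean component eccentricity; nuclei channel — count, mask area, mean
per-nucleus area, mean intensity, count density; geometry — ROI area,
equivalent diameter, solidity; cross-channel — IntDen per nucleus.
IntDen is summed over the fibrosis mask dilated by 1 px so signal the
PSF spreads just past the half-max boundary is still counted; all other
statistics use the mask itself. Organoids with an empty footprint are
dropped (and logged), not imputed.

The matrix stores organoids as rows. Z-scoring uses the sample SD
(ddof 1), is global across the screen by default (per-batch behind a
flag), zeroes and flags constant columns (constancy judged at a 1e-12
relative tolerance to absorb float accumulation), and is idempotent.
Feature selection keeps features whose between-treatment variance (the
variance across treatments of per-treatment mean z-scores) exceeds the
given quantile (default 0.25) of all features' values; constant features
are always dropped, quantile 0 keeps every non-constant feature, and at
least two features always survive. Between-treatment rather than pooled
variance implements the idea that features which do not respond to
treatment carry no profiling signal, and makes the threshold a
reproducible quantile rather than a judgment call.

## Profiling

Treatment similarity is computed at treatment level, in two ways: (a)
Pearson correlation between mean z-scored feature vectors; (b) k-means
phenotype clustering of all organoids followed by Pearson correlation
between per-treatment cluster-percentage rows. k-means is Lloyd's
algorithm with k-means++ and 10 restarts (scikit-learn); with
`k="auto"` the mean silhouette is maximized over k ∈ [2, 12], ties
broken toward smaller k for parsimony, inertia reported alongside as a
diagnostic. Undefined correlations (zero-variance vectors) are set to 0
with a warning so the matrix shape is stable for plotting. Heatmap
ordering is the leaf order of average-linkage hierarchical clustering
on distance 1 − r; the linkage choice is recorded in the run manifest.

## Efficacy and toxicity statistics

Fibrosis (IntDen) and cell number (nuclei count) are normalized per day
to the mean of the control group at that day, which cancels
multiplicative gain and makes NC average exactly 1 by construction.
Days without control observations are excluded with a warning; a zero
control mean raises an error. The replication unit is the organoid by
default, with batch recorded; a batch-mean mode aggregates first for
designs where the batch is the honest unit. Per (treatment, day) the
normalized values are compared to the reference with Welch's t-test;
Benjamini–Hochberg adjustment runs across all comparisons of the run;
tiers are ns/*/**/***/**** at adjusted p < 0.05/0.01/0.001/0.0001 — a
deliberately monotone scheme. A comparison of identical data reports
effect 1 and p = 1. Toxicity is flagged when mean normalized cell
number falls below a threshold (default 0.7, a configurable convention,
not an estimated constant) *and* the drop is significant at adjusted
p < 0.05.

## The simulator

What it emulates: a circular organoid footprint; a Poisson number of
nuclei with mean `n_nuclei_mean × (1 − toxicity_effect)`, placed
uniformly in the organoid cylinder with a minimum 3D center spacing of
one nucleus radius (so nuclei overlap in projection but counting stays
solvable — a configurable spacing factor produces well-separated
fixtures); nuclei rendered as center-peaked spheroids (parabolic radial
profile, max-composited); a fibrosis channel of random-walk filaments
(Poisson count, rate `12 × fibrosis_effect`) plus elliptical blobs
(rate `4 × fibrosis_effect`) at constant amplitude, additively
composited so the expected integrated intensity is exactly linear in
`fibrosis_effect`; image formation as PSF blur (per-plane Gaussian,
σ = 1 px) → constant background (100) → Poisson shot noise → Gaussian
read noise (SD 25) → clip to 16 bits; and a per-batch multiplicative
gain drawn once per batch from lognormal(0, 0.1).

Ground truth (nuclei count, fibrotic area, integrated fibrosis
intensity) is recorded from the pre-blur, pre-noise label/amplitude
arrays, including the batch gain. Rendering can be skipped
(`render=False`) for statistics-heavy studies; the RNG is split into
independent substreams (placement / fibrosis / noise) so the truth is
bit-identical with rendering on or off. Per-organoid seeds are derived
by SHA-256 hashing of (batch, treatment, day, replicate) into a
SeedSequence spawn key, making every organoid independent of generation
order.

Deliberate simplifications, and what they mean for the tests: the
fibrosis channel is rendered z-uniform (each element spans the stack
depth). The pipeline consumes only the MIP, and a z-uniform signal is
the structure for which projection loses nothing; this is what makes
the linearity of integrated intensity exact rather than approximate.
Axial structure of the collagen network, realistic organ morphology,
light scattering, uneven illumination and multi-organoid fields are all
out of scope — so passing tests certify the measurement chain under the
stated statistical structure, not performance on arbitrary real
microscopy. Imaging modality parameters the source screens do not state
(plane spacing, magnification, bit usage) are exposed as configurable
defaults (`z_step_px = 2`, 1 µm pixels, amplitudes ≈ 3000 counts), not
inferred.

## Numerical and reproducibility choices

Floating-point determinism comes from fixed reduction orders (pandas/
numpy defaults, no parallelism) plus seeded RNG everywhere; a rerun with
the same config and seed reproduces every table byte-for-byte, which the
suite asserts. TSVs are written with `%.10g` floats. If a nucleus
center cannot be placed under the spacing constraint after 1000
rejections the constraint is waived for that nucleus so the Poisson
count stays exact (never observed at default density). Degenerate
inputs have defined behaviour rather than exceptions where a screen
could plausibly produce them (constant images, empty masks, zero-count
organoids); contract violations (duplicate ids, shape mismatches,
missing control) raise.

## Problem sizes

The test-suite and acceptance sizes are chosen as the smallest that
make each claim sharp: 50 organoids for segmentation recovery, a
200-organoid screen for count correlation, 200 replicate screens of
30 organoids/group for the null-rejection and power checks (run at
construction level through `render=False`), 150 organoids/group for the
2× effect-recovery measurement through the full imaging chain, and a
96-organoid end-to-end determinism rerun. Statistics-heavy sections use
a compact 160×160×6 field with proportionally scaled-down organoid
radius and element rates; noise parameters stay at the defaults.

## Known limitations

Counting carries a small negative bias at high nuclear density
(projection merging); the silhouette criterion prefers merging over
splitting when phenotype separations are very uneven, so `k="auto"`
should be read as "number of well-separated phenotypes"; Otsu-based
segmentation assumes a bimodal intensity structure and the half-max
refinement assumes plateau-like foreground; and the efficacy statistics
treat organoids as exchangeable within (treatment, day) — batch effects
beyond multiplicative gain (which normalization cancels) are not
modelled.
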