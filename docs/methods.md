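# Methods

This note documents the models and procedures implemented in `camometrics`,
the defaults and their rationale, the synthetic stimuli the tests run on,
and the numerical choices made where the design was genuinely open.

## Background standardization (`imnorm`)

Luminance is the mean of the linear red and green camera channels (human
luminance vision pools longwave and mediumwave; blue is ignored). Background
images are standardized so every stimulus has the same overall luminance and
similar contrast: pixels are log-transformed (natural log; the base only
rescales and the mapping absorbs it), histogrammed into 10,000 bins, and a
quadratic is fitted through the bins holding the 1st/50th/99th percentiles
against target anchors, then evaluated on every pixel's bin index. Anchors
default to (0.1, 0.5, 0.9) on a 0–1 scale — any symmetric choice works, and
the median target must sit halfway between the limits, which leaves equal
pixel mass beyond the low and high anchors.

Numerical choices: the quadratic maps *bin index* → target value (the
alternative, log-luminance → target, satisfies the same anchors; bin-index
mapping is what the histogram step implies). The mapped output is clipped at
a small positive floor (`p_low_target/1000`) so a normalized image remains in
the valid domain for a further log transform; only pixels in the extreme
lower tail can clip. Re-normalizing an already-normalized image moves the
anchor percentiles by at most a few histogram bins (~0.02 in anchor units);
the residual comes from histogram quantization of the stretched lower tail.
A flat image (coincident percentile bins) raises a degenerate-input error.

`monitor_gamma` is a calibration utility: the measured LCD gamma curve
`lux = 8.362e-4·(x+25.41)^2.127·exp(−(x+25.41)/3.840e11)` for 8-bit pixel
values, strictly increasing on [0, 255] (0 → 0.81 lux, 255 → 134.5 lux).

## Synthetic backgrounds (`synthbg`)

Real bark photographs are not redistributable, so the package generates
stand-ins: Gaussian noise shaped to an amplitude spectrum ∝ f^−β,
exponentiated (log-normal luminance), then passed through the same
normalization as a photograph. Defaults: 1920×1080 (the presentation
resolution), β = 1.2 (natural-image spectra fall off near 1/f; bark sits
slightly steeper), log-luminance SD 0.35 before normalization, and an
optional vertical-streak anisotropy (energy boosted along the horizontal
frequency axis) mimicking bark grain. The test battery uses 8 seeds × 2
betas (0.8, 1.2) with anisotropy 0.5 — 16 deterministic backgrounds standing
in for a library of photographs.

What the synthetic textures do **not** emulate: sharp occlusion boundaries,
lichen patches, depth/shading structure, and the higher-order phase
statistics of real bark. Tests passing on this battery show the pipeline
reproduces the documented stimulus-level effects under controlled texture
statistics; they do not certify effect sizes on real photographs.

## Prey generation (`stimgen`)

Prey are filled isoceles triangles, 126 px wide × 64 px high, apex up
(orientation configurable), rasterized symmetrically about the vertical
midline. A patch of the same size is sampled from a uniform-random location
of the prey's own background and thresholded into 60% background-tone / 40%
pattern. The threshold is the exact order statistic of the masked values;
if ties push the achieved fraction outside the 1-percentage-point tolerance
the patch is rejected and a new location is sampled (up to 100 retries).
Which tail becomes pattern follows polarity: dark-on-light prey take the
darker 40%, light-on-dark the lighter 40%.

*Disruptive* prey threshold the raw patch, so pattern blobs freely intersect
the outline. *Background-matching* prey first pull patch values toward the
patch median with weight exp(−d²/2σ²) of the distance d to the outline
(σ = 6 px by default; the functional form and width are our choice — only
the purpose, keeping pattern off the outline without salient parallel
lines, is fixed). Outline pixels are fully suppressed, so no pattern can
touch the outline; a generation that still leaks is re-sampled.

Tones come from background luminance percentiles: dark-on-light uses the
20th (pattern) and 70th (body); light-on-dark the 80th and 30th. With the
60/40 area split these pairs keep mean prey luminance near the background
median. Placement is uniform-random with a one-body-length (126 px) margin
from every image edge, so the local region is never clipped.

## Comparison regions (`regions`)

The prey *outline* is the thin inner boundary (pixels edge-adjacent to a
non-prey pixel), ordered by Moore contour following; diagonal steps count
one pixel, so the 126×64 triangle has 252 outline pixels against a Euclidean
perimeter of 305.6 px. The *local* region is every pixel within a Euclidean
126 px of the outline — including the prey interior, since every interior
pixel of a 64-px-tall prey is within range; this inclusive reading
reproduces the ~92,000-px local-zone figure (we compute 92,090). The
*global* region is the whole 1920×1080 image (2,073,600 px; 2,069,505
excluding the prey). For the Canny ratios an outline band spans 4 px inside
to 8 px outside the outline; the band is excluded from the local and global
background regions wherever it applies. All distances are Euclidean
transforms (the "radius" language implies Euclidean, not chessboard);
distance maps are computed on a padded bounding-box window and embedded,
which is exact and an order of magnitude faster than full-frame transforms.

## GabRat (`gabrat`)

Filters are even-symmetric (cosine-phase) Gabors: isotropic Gaussian
envelope (aspect ratio 1) truncated at radius ⌊3σ⌋, carrier perpendicular
to the filter orientation with 4 cycles across the kernel diameter, kernel
mean-subtracted to zero DC. The 4-cycles-per-diameter convention is
anchored by the 19-px σ = 3 kernel; "energy" is the absolute response of
the single even filter (not a quadrature pair) — both conventions are
underdetermined by the usual statement of the method and are flagged here
as our reading.

At each outline pixel the *parallel* angle is the argmax of absolute mask
responses over the four orientations {0°, 45°, 90°, 135°}; the orthogonal
angle is parallel + 90°, which stays in the set. Responses are quantized to
1e-8 before the argmax so ties on symmetric mask windows (45° staircases)
break deterministically. On the actual slide image the per-pixel ratio is
|E_o|/(|E_o|+|E_p|), defined as 0 when the denominator is below 1e-12 (no
perceived edge counts as non-disruptive); GabRat is the mean over outline
pixels. Convolutions are FFT-based with reflect padding; by the placement
contract the outline never approaches the image edge, so padding is inert
in normal use. GabRat is exactly invariant to affine luminance changes
a·I + b (a > 0) and to 90° rotations of image + mask (up to genuinely tied
pixels, whose ratio flips to its complement).

## Canny metrics (`edgemetrics`)

Edges come from scikit-image's Canny (Gaussian σ = 3, non-maximum
suppression, hysteresis). The published thresholds 0.2/0.5 originate in a
Java port whose normalization is not pinned down; we interpret them as
**quantiles of the gradient-magnitude distribution** (default). The
alternative, fractions of the maximum gradient, is available as
`threshold_mode="max_fraction"` but produces edge maps too sparse to
resolve the interior-vs-band density differences between prey treatments,
and yields DisRat far from the near-1 regime the ratios are described in;
the quantile reading reproduces both. Densities are edge pixels over region
pixels; VisRat = background density / band density (local or global),
DisRat = interior / band. Ratios are undefined when the band holds no edges
and are reported as missing, never 0; logs (natural) are provided since the
ratios need a log transform for roughly normal errors. The
edge-intersecting cluster count is the number of 8-connected pattern blobs
touching the outline; background-matching prey score 0 by construction
(zero inflation — analyse disruptive prey only).

## Bandpass and luminance metrics (`patternmetrics`)

Spectra use 13 scale bands from 2 px to 128 px in √2 steps. Each band is an
annular Fourier mask between the geometric midpoints to neighbouring
centres, applied to the region's bounding box with non-region pixels filled
by the region mean; band energy is the SD of the filtered pixels inside the
region (the granularity-analysis convention; the bare term "energy" does
not fix this choice, so it is flagged here). PatternDiff is the band-wise sum of absolute energy differences.
The five descriptives are max energy, dominant scale, proportion power,
mean energy, and energy SD (population SD over the 13 bands). The Euclidean
Pattern Distance z-scores each descriptive over the analysis batch (mean 0,
SD 1, population convention) before taking the Euclidean distance;
zero-variance statistics are dropped with a warning. Luminance metrics
histogram prey and region into 20 bins spanning their pooled range,
normalized to unit mass before differencing (regions differ in area;
identical distributions must give 0), so LuminanceDiff ∈ [0, 2]. Regions
smaller than the largest band (e.g. the prey itself) are computed with a
warning — the coarse bands are then poorly resolved, which is inherent to
measuring a 64-px object at 128-px scales.

## HMAX (`hmax`)

S1: absolute responses of the same even Gabor kernels at 4 orientations ×
10 scales (σ = 2…20 step 2). C1: max over a disc of radius σ + 4 (exact
chord-decomposed max filter) and over the two scales of each
neighbouring-scale band — consecutive disjoint pairs (2,4)…(18,20), giving
4 × 5 channels. The prey template is the channel-wise mean C1 within the
mask (an overall pattern match, not a template match). Similarity at a
region site is 1/(1 + d) with d the Euclidean distance over the 20
channels — bounded (0, 1]; the similarity function is our choice, since
"match" is otherwise undefined in this family of models. Sites are sampled every 2 px (stride configurable; results are
stable against stride 1 on fixtures). Rotation allowance takes the best of
the four circular shifts of the orientation axis at each site — the only
rotations the bank supports; with rotation the summaries dominate the
fixed-angle run elementwise by construction.

## SIFT (`siftmatch`)

Feature detection and description are delegated to scikit-image's SIFT with
the protocol settings: initial blur 1.0, 8 steps per octave, descriptor
size 4, 8 orientation bins. Prey and region are composited on white.
Matching is one-directional (prey → region) nearest neighbour with a
closest/next-closest ratio test at 0.96 — deliberately permissive so counts
are large and roughly normal. Exact keypoint counts differ between SIFT
implementations; the contract is the settings record plus the self-match
and ratio-monotonicity properties, not bit parity with any plugin.

## Batch pipeline (`harness`)

`run_batch` generates prey over a background list, scores every metric, and
emits one CSV row per prey plus a JSON manifest (seed, sizes, config).
Seeds derive from one `SeedSequence`, making runs bit-reproducible.
Per-metric failures are logged and recorded as missing values. Euclidean
Pattern Distances are computed in a second pass with the batch itself as
the z-scoring population. Statistical modelling of detection times is out
of scope — the CSV is the hand-off point to any stats environment.

## Problem sizes used in the tests

The unit suite runs on 640×420 and smaller backgrounds. The acceptance
suite builds the full 16-background battery at 1920×1080 and scores 352
prey per treatment (about a fifth of the 3,840 presentations of the
original detection experiment) for the treatment-separation checks:
disruptive prey score higher GabRat_σ3 and lower DisRat (tested on the log
scale) than background-matching prey, each at p < 0.01 by a two-sample
t-test. The acceptance script reports the local-zone pixel count and the
mean pattern percentage over 120 generated prey.

## Known limitations

* Achromatic only; no chromatic channels or colour-discrimination models.
* Triangular prey geometry; px-native (no mm/degree scaling).
* The synthetic battery controls second-order texture statistics only; real
  bark differs in phase structure, so effect sizes (not directions) should
  be re-estimated on photographs.
* Canny thresholds and the HMAX match function follow documented but
  unverifiable conventions of third-party implementations; both are
  exposed in config.
* One target per scene; no multi-prey bookkeeping.
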