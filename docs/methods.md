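# Methods

This note records the models, parameter choices and numerical conventions
behind `ihcquant`, and what the synthetic validation does and does not
demonstrate.

## Stain detection

Detection runs entirely on the second Ohta feature I2 = (R − B)/2: DAB's
brown is red-dominant (I2 > 0 and growing with stain density) while
hematoxylin's blue gives I2 < 0, so the two populations separate on a
single axis. A two-component 1-D Gaussian mixture is fitted to the I2
values inside the ROI (subsampled to 200 000 pixels with a seeded
generator when larger — EM cost is linear in n and the threshold estimate
is long since saturated at that size), and the decision threshold is the
crossing of the two weighted component curves between their means, the
point where the posterior odds flip. The third feature I3 is computed but
unused; the channel choice is exposed for other chromogens.

Calibration against reader marks adjusts a single scalar shift added to
the threshold rather than refitting the mixture: a one-parameter search is
reproducible, monotone (raising the shift can only remove stained pixels)
and sufficient for the stereology loop to align the detector with expert
consensus. Joint 2-D histograms (I2 with I1 or I3) were deliberately left
out: one axis suffices for a single chromogen and keeps the calibration
search one-dimensional.

## Epithelium segmentation

The intensity image I1 is low-pass filtered by sliding-window Fourier
analysis: tiles of `tile` pixels advance by half a tile; each is
multiplied by a Gaussian window (`window_sigma`), transformed, multiplied
by a radial raised-cosine response (unity below `cutoff/2` cycles per
window, cosine rolloff to zero at `cutoff`), inverse transformed and
re-accumulated under the same window. The output is normalized by the
accumulated window times the *filtered* window (normalized convolution):
with a truncated Gaussian window the naive squared-window normalization
leaks truncation sidelobes through the stop band, while this form
reproduces constants to machine precision by construction. Images are
reflect-padded by one tile so border pixels get full window coverage;
residual boundary artifacts are confined to roughly half a cutoff
wavelength at the frame edge.

The smoothed image is binarized with Tsai's moment-preserving threshold
(the cut whose two-level image preserves the first three sample moments),
the darker side is kept — epithelium is nuclei-dense under hematoxylin,
hence darker at blob scale; the polarity is a flag for other tissue types
— and a binary opening with a disk removes objects smaller than the
structuring element. A constant-intensity ROI has no bilevel structure and
yields an empty mask rather than an error.

Defaults: `tile` 256, `window_sigma` 64, `cutoff` 16 cycles/window
(passing structures coarser than ~16 px ≈ 8 µm at 0.5 µm/px),
`opening_radius` 10 px (~5 µm). The low-pass scale must sit between the
nuclei texture (a few pixels) and the epithelial blob scale (tens of
pixels); these four parameters are exactly the calibration search space of
the stereology stage, and the defaults were validated on phantoms, not on
study tissue.

## Stereology and quality control

Grid nodes sit at a uniformly random offset (seeded) modulo the spacing;
systematic uniform random sampling makes the labeled fraction an unbiased
estimator of area fraction, which the tests verify over 500 offsets. The
95% CI is the Wald binomial interval clipped to [0, 1] — the simplest
defensible choice, stated explicitly so a Gundersen-style CE can be
swapped in later. Each cross samples the single pixel under the node; no
neighborhood vote.

Two readers' marks are merged by consensus: disagreements become
"excluded" (kept in the bookkeeping, dropped from every ratio) rather than
silently deleted. Agreement percentages use the union base: positions
*both* call labeled over positions *either* calls labeled. Quality factors
are (i) overlap length of two 95% CIs over the length of their union and
(ii) the mean of sensitivity and specificity with the expert consensus
always the reference. Calibration is an exhaustive search over a finite
parameter grid maximizing factor (ii), ties broken by grid order so reruns
are identical.

## Hexagonal transmittance

A pointy-top hexagon lattice partitions the ROI; each pixel goes to the
nearest center via cube-coordinate rounding (exact for a hexagonal Voronoi
partition) using floor(x + 1/2) rounding, which commutes with lattice
translations so boundary tie-breaks are translation-consistent. Per
hexagon, T = Σ(255 − brown)/(N_epi · 255), where brown is I1 at stained
pixels and 255 elsewhere; the sum runs over all epithelium pixels in the
hexagon, unstained ones contributing zero. T is 0 for no staining, 1 for
fully stained black epithelium, and monotone: darkening any stained pixel
can only raise it. Hexagons with fewer than `min_epi_pixels` (default 50)
epithelium pixels are undefined and excluded from pooling — their T would
be dominated by a handful of pixels. Default circumradius is 100 px
(~50 µm), a scale that holds a few hundred epithelial cells' worth of
tissue; heterogeneity statistics do depend on this scale and it is a
config knob, not a derived quantity.

## Mixture thresholds and case calls

The 1-D EM is deliberately deterministic: means initialized at the
(2k−1)/(2K) sample quantiles, equal weights, SDs at sample SD/K, iterated
until the log-likelihood gain falls below 1e-8 (at most 500 iterations),
SDs floored at 1e-4 of the data range with a collapse error if a component
stays pinned for more than 10 iterations. No random restarts means
marker-level thresholds are bit-identical run to run. Class thresholds are
the crossings of adjacent weighted component curves — a quadratic solved
in closed form, keeping the root between the two means; when unequal
weights push both quadratic roots outside that bracket, the equal-posterior
point found by bisection (the posterior odds are monotone between the
means) is used instead. Values exactly at a threshold go to the upper
class.

Case calls group three classes into two: for Bim and Mcl-1 the dominant
class decides ("low" only when the low class holds the most hexagons, ties
toward the lower class); for the strongly heterogeneous P-ERK the call is
"high" only when the high class holds at least 50% of hexagons (a tie at
exactly 50% is "high"). Both rules reproduce every printed per-case label
of the study's class-count table, including its discordance counts of 4, 8
and 7 against the pathologist. The study's wording also admits reading the
Bim/Mcl-1 rule as "high iff n1 + n2 > n0"; every printed row is consistent
with both readings, the dominant-class reading is implemented.

## Composite PCA score

Per case, the mean, the population SD and the population skewness
g1 = m3/m2^{3/2} of the defined hexagon transmittances are computed (a
zero-variance case gets skewness 0 with a warning). Across cases the three
columns are standardized by their mean and *sample* SD (ddof = 1) and the
score is the projection onto the leading eigenvector of the correlation
matrix — the convention that reproduces the study's printed per-case
scores (e.g. Bim P19 = 2.22) to within the rounding of its printed inputs;
population-SD standardization misses by the factor √(n/(n−1)) ≈ 2%. The
component is sign-oriented so the coefficient on the mean is non-negative,
because the printed scores follow that orientation for all three markers
(the printed Mcl-1 loading row carries the opposite sign to its own score
column — the scores, not the loadings, are taken as the behavioral
contract). Scores are min-max mapped to [0, 100]; with the study's printed
thresholds (45 for Bim, 85 for P-ERK) this reproduces its second-approach
discordance counts of 5 and 3. For Mcl-1 the printed 25% threshold yields
8 discordant cases, not the printed 6, under every affine normalization
tried; the study describes its thresholds as manually adjusted near the
mixture intersection without giving the adjustment, so the Mcl-1 count is
documented as not reproducible from the printed inputs. The automatic
threshold (higher intersection of a 3-component mixture on the percent
scores) is the default; a manual override reproduces study-fixed values.

Reproduction accuracy is bounded by input rounding: the printed moment
columns carry 3 decimals while the Bim/Mcl-1 SD columns have a spread of
only ~0.009, so propagated rounding alone perturbs scores by up to ~0.03.
The acceptance tests assert 0.02 where the inputs support it (all 25
P-ERK cells, the example cells, the loading vector to 0.005) and 0.04
overall.

## Synthetic phantoms

Phantoms emulate the geometry the raster pipeline must cope with:
epithelium as thresholded Gaussian-smoothed noise (threshold at the
quantile matching the target area fraction, default 0.4), a fine
equal-channel nuclei texture darkening the epithelium (amplitude 30, scale
1.5 px) that the low-pass must reject without touching I2, stroma
near-white, and stain rendered by mixing epithelial pixels toward a brown
endpoint (RGB 140/60/0) by an amount s = (255 − m)/255 set per hexagon
level — I2 rises linearly in s, so detection is well-posed by
construction. Stain level is assigned independently per hexagon of the
analysis lattice (default proportions 0.2/0.5/0.3, brown means 200/130/55,
noise SD 8), giving exact per-hexagon class ground truth; pixels whose
noiseless stain amount reaches 0.1 define the true stain mask. All
randomness flows through one seeded generator per call.

What phantom validation shows: the geometry and statistics of every stage
compose correctly (epithelium Dice ≥ 0.90, stained-fraction error ≤ 0.05,
recovered hexagon class shares within 0.1 of the generating proportions on
a 1024² phantom — sizes chosen so the full suite stays cheap while each
phantom holds ~150 analyzable hexagons). What it does not show: robustness
to real-tissue nuisance — stain gradients, folds, necrosis, out-of-focus
regions, scanner color variation — none of which the rendering model
contains. The phantom is a correctness instrument, not a realism claim.

## Known limitations

- Single-chromogen model; no color deconvolution or multi-stain unmixing.
- Epithelium polarity assumes hematoxylin-dense epithelium; tissues with
  dense stroma need the polarity flag.
- Wald CIs undercover at extreme fractions and small n; grids should carry
  at least a few dozen crosses.
- The hexagon scale is a free parameter; marker-level thresholds and
  heterogeneity moments change with it.
- Only the first principal component is used; heterogeneity beyond the
  three moments (spatial arrangement of hexagon classes) is not scored.
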