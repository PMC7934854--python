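# Methods

This note documents the models and procedures implemented in `retmosaic`,
the tunable parameters and their defaults, what the synthetic data do and
do not emulate, and the numerical choices made where the design was open.

## Synthetic flat mounts

`generate_flatmount` renders an en-face confocal image of a GFP-labelled
retina as:

* a disc-shaped tissue mask (radius `retina_radius_px`, default 480 px in
  a 1024×1024 frame at a nominal 1 µm/px);
* `n_cones` (default 2000) cone nuclei as isotropic 2-D Gaussian spots of
  scale `nucleus_sigma_px` (default 2.5 px).  The nucleus profile is a
  modelling choice — the spot is the diffraction- and sampling-blurred
  image of a ~3–5 µm nucleus, and an isotropic Gaussian is the standard
  idealization;
* a bright/dim amplitude mixture (`dim_fraction` = 0.2 at
  `dim_amplitude`/`bright_amplitude` = 600/2000 ≈ 30%), emulating
  variation in reporter expression;
* `cluster_fraction` (default 0.1) of nuclei placed touching a partner at
  distance U(1, 2)·σ, producing the merged components that fragmentation
  must resolve;
* optional circumscribed cone-free craters (non-overlapping discs placed
  by rejection sampling, `sample_craters`); nucleus positions are rejected
  from crater discs with a half-pixel margin so rounded coordinates never
  land on the crater mask;
* signal-dependent Poisson shot noise plus additive Gaussian read noise
  (`noise_sd` = 10) over a background of 100 counts.  `shot_noise=False`
  with `noise_sd=0` gives an exactly noiseless render for oracle tests.

Sub-streams of the seed are used per concern (positions, classes, noise),
so changing one aspect of a spec does not perturb the others.
`generate_cluster_mosaic` plants isolated k-mers (chains with successive
spacings U(1.4, 2)·σ, clusters kept ≥ 28 px clear of everything else) so
per-cluster fragmentation can be scored unambiguously.

What the generator does **not** emulate: the petal relief cuts of real
flat mounts (the retina is a single disc), 3-D confocal stacks,
eccentricity-dependent cone density, vignetting or illumination gradients,
and autofluorescence texture.  Passing the recovery tests therefore shows
the algorithm is correct under the stated imaging model, not that it is
robust to every artifact of real microscopy.

## Cone detection

`count_cones` proceeds in three stages.

**Bright pass.**  Otsu's threshold is computed on a 256-bin histogram over
the masked intensity range (classical formulation; ties broken toward the
lowest candidate; a constant region raises a degenerate-histogram error).
Foreground is `image > t`; 8-connected components with area ≥
`min_component_area_px` (default 4) become bright components with
intensity-weighted centroids.  The single-nucleus area `a1` is the median
of component areas within [0.5, 1.5]× the overall median — merged
components fall outside the window, so the estimate is singleton-dominated
(≥ 5 components required).  Each component is fragmented into
`max(1, round(area / a1))` cones, rounding half-to-even.

**Bright modelling.**  The nucleus scale σ is recovered from the
thresholded-spot geometry: a Gaussian spot of amplitude A binarized at
threshold t over background b covers π·2σ²·ln(A/(t−b)) pixels, so σ
follows from `a1`, the median singleton peak amplitude, and the Otsu
threshold (fallbacks: half-maximum geometry, then 2.5 px).  Singleton
positions are refined to sub-pixel precision by a quadratic fit to the LoG
response; merged components get their k sub-centroids from distinct LoG
maxima or, when unresolvable, k-means partitioning of the pixel
coordinates, followed by a joint least-squares fit of k Gaussians on the
local patch (components up to `max_joint_fit` = 6 spots).  When
`area / a1` lands just below a rounding boundary (fractional part in
[0.15, 0.5)), the count is adjudicated by refitting with k+1 spots and
accepting the promotion only if the BIC improves by more than 20, every
fitted amplitude clears 15% of the reference bright amplitude, and all
spots are ≥ 1.5 px apart; duplicate fits closer than 0.9 px are merged
back.  Adjudication and a fixed-point amplitude relaxation (two rounds of
matched-filter corrections against the smoothed residual) are iterated
twice.  This stage exists because a pure area quotient misses nuclei whose
area contribution is partial — dim nuclei absorbed into a bright
component, touching pairs just below the rounding boundary.

**Dim pass.**  The fitted bright model is subtracted and the
scale-normalized negative LoG response (−σ²∇²G) of the residual is peak-
detected.  The response threshold defaults to mean + 5 SD of the response
in the background region (inside the mask, clear of every bright call),
with a floor at the response of a spot `dim_floor_fraction` (default 0.15)
as bright as the reference amplitude — blobs fainter than ~15% of a
typical nucleus are model residue or background structure, not cones
(planted dim nuclei run at 30%).  Candidate peaks must lie outside the
binarized bright footprint (supra-threshold pixels are already accounted
for by fragmentation — counting them again would double-count), farther
than `dedupe_radius_px` (default σ) from every bright call, and their
implied amplitude (2× response) must stand clear of 0.3× the local model
intensity.  `n_cones` is the sum of per-component counts plus the
surviving dim calls.

All automatic thresholds scale linearly with the image, so the count is
invariant to a positive gain; because the joint fits iterate in floating
point, the invariance is exact only to within ±1 call in practice, and the
tests assert it at 0.5%.

On the reference mosaic (2000 nuclei, defaults above) the detector reaches
~96% recall and ~98% precision at a 3-px match radius with a count error
of ~3%; on noiseless, non-overlapping mosaics the count is exact.

## Crater metrics

Craters are computed from cone positions only (intensity never enters).
The mosaic is covered by discs of radius r around every call; the default
r makes a *complete* spatially random mosaic of the observed density
saturate its own coverage (uncovered fraction exp(−λπr²) ≈ 10⁻⁵, i.e.
r = √(ln 10⁵ / (π λ)) with λ = calls per retina pixel) so that craters,
not sampling gaps, dominate the complement.  Uncovered 8-connected
components larger than a quarter coverage-disc are crater cores; each core
is dilated back by r minus the mean boundary-to-nearest-cone slack
(0.5/√λ), which removes the boundary erosion of the coverage discs and
leaves an unbiased area estimate.  Final components below
`min_crater_area_px` (default 50× the single-cone area) are discarded.  A
cone-free retina is one crater at 100%; a saturated mosaic has none.
Detectability is resolution-limited: craters with radius ≲ 1.5 r (≈ 45 px
at default density) cannot be separated from sampling gaps.

The central-third ratio takes the retina-mask pixels' distances from the
optic nerve head and uses their ⅓-quantile as the central radius
(`area_third`, default — "central one-third" read as a tissue-area
fraction), or one third of the maximum radius (`radius_third`).  Under
uniform placement the area-third ratio converges to ⅓ (checked at
n = 10⁴).

## EM surface-area fractionation

Debris-mask pixels are dead area regardless of intensity (mirroring manual
tracing); the remaining pixels are binarized — above threshold =
microvilli, at/below = no apical processes.  The threshold defaults to
Otsu on the non-debris pixels and is always recorded; percentages are
fractions of *all* pixels, so the three classes always sum to 100, and
areas scale by the field area (default 110 × 102 µm², a 1000× field).
Brightness/contrast preprocessing is deliberately omitted: affine
adjustments do not change an Otsu binarization, and manual adjustment is
irreproducible.  Group aggregation across fields is a simple per-image
mean; whether real analyses include debris pixels in per-image
denominators is an assumption made explicit here (they are included).

The synthetic EM generator tiles the frame into three regions by
thresholding two smoothed Gaussian random fields at the quantiles matching
the requested fractions (realized fractions track requests to pixel
resolution), with bright filament texture for microvilli (≈190 ± 35),
smooth dark for process-free area (≈40), and mid-grey speckle for dead
regions (≈105) — chosen so the classes are separable the way secondary-
electron contrast separates them in real micrographs.

## DE concordance

Significance is `padj < alpha` (default 0.05, configurable — the
threshold of any published comparison should be matched explicitly).
`discordant_genes` inner-joins the two tables on gene, keeps genes
significant in both, and partitions by fold-change sign; zero fold changes
are reported separately since their direction is undefined.  Term
over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n), computed via the survival function
and BH-corrected across all terms with K ≥ 1 (a `min_term_size` option
excludes small terms; the default keeps everything, matching the
exhaustive-enumeration oracle).  `shared_terms` computes UpSet semantics:
each item of the union is assigned to exactly the combination of lists
containing it, so the exclusive regions partition the union.

The planted DE tables draw |log₂FC| from N(1.5, 0.5) clipped at 0.25 and
log-uniform adjusted p-values below α/2 for planted genes; the remaining
genes are significant in at most one table.  One term is constructed
around the discordant set, so its enrichment is guaranteed by design.

## Statistics

Paired t: t = mean(d)/(sd(d)/√n) with the n−1 standard deviation,
df = n−1; one-way ANOVA: the standard between/within decomposition.  Tail
probabilities use the regularized incomplete beta function,
P(|T| ≥ t) = I_{df/(df+t²)}(df/2, ½) and
P(F ≥ f) = I_{d₂/(d₂+d₁f)}(d₂/2, d₁/2), which the tests verify against
quadrature of the raw densities to 1e-8.  Degenerate inputs are flagged
rather than erroring: all-zero differences give t = 0, p = 1; zero
variance about a nonzero mean gives p = 0 with `degenerate=True`.
Significance thresholds never gate pipeline outputs; p-values are
reported, not filtered on.

## Pipeline and problem sizes

`run_pipeline` simulates (or loads) n contralateral-eye pairs, runs
detection, crater and central-ratio quantification per eye, and paired t
tests across pairs, writing every output with a SHA-256 hash into a
manifest so a run is reproducible from (config, seed).  The default demo
configuration uses 512-px eyes with 700 cones and planted cratering of
~10% (control) vs ~1% (treated); the test suite and the acceptance script
use 384-px eyes with 450 cones and 2–3 pairs, and full-size (1024-px,
2000-cone) mosaics for the detection and crater recovery checks — sizes
chosen so the planted effects sit well above the delineation resolution
while a full run stays in the tens of seconds.

## Known limitations

* The detector assumes roughly isotropic, single-scale nuclei; strongly
  elongated or out-of-focus nuclei would need a multi-scale LoG.
* Fragmentation inherits the biases of the area quotient: clusters larger
  than `max_joint_fit` fall back to pure area division, and additive
  intensity in dense clusters inflates component areas.
* Crater delineation is algorithmic (coverage-complement); studies that
  trace craters manually will differ near boundaries, and craters below
  ~1.5 coverage radii are undetectable by construction.
* The EM classifier is a two-class threshold plus a mask; it does not
  segment individual microvilli and has no stereological correction.
* Published DE gene counts cannot be reproduced from this package alone —
  upstream alignment/quantification/DE fitting are consumed as tables,
  never re-implemented.
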