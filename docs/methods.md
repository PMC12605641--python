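# Methods

This note documents the models and procedures implemented in `segdecon`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish.

## Image preprocessing

H&E images are converted to HSV with the standard hexcone formulas
(scikit-image); hue is held internally as an angle in [0, 2π) and all hue
statistics are circular (weighted circular mean via `atan2` of S-weighted
sine/cosine sums; deviations wrapped to (−π, π]).

**Tissue mask.** Otsu threshold on the saturation channel (or on the
hematoxylin component of the RGB→H/E/DAB color deconvolution when
requested). Components smaller than 400 µm² are removed and equally small
holes filled — all pixel cutoffs are their µm² values divided by
`um_per_px²`, rounded to the nearest integer — followed by a disk closing
whose radius is the expected nucleus radius in pixels. A zero-variance
channel yields an empty mask with a warning rather than an exception.

**Artifact mask.** Hue within tissue is clipped to its 5th–95th percentiles
(linear-interpolation percentiles) and min–max normalized to [0, 1]. Yen,
Triangle and Otsu thresholds are screened in that fixed order, high-hue tail
before low, and the first candidate whose artifact-area fraction lands in
the target window (0.5–30 % of tissue) is selected; the fraction is
evaluated *after* tiny-component removal and hole filling, so the recorded
fraction always honors the window. The tiny-component cutoff is
0.35·π·(d/2)² for nucleus diameter d (≈ 27.5 µm², 110 px at defaults). When
no candidate qualifies, 2 % extreme-quantile thresholds are applied to both
tails and the tail with the smaller area is kept; the 2 % value is this
package's choice — only "extreme quantiles" is prescribed — and the
comparisons are strict so an all-equal hue field yields an empty mask, not a
full one.

**Background homogenization.** The S-weighted circular mean hue of
non-nuclear tissue defines the eosin "pink core". The pink band keeps the
pixels whose absolute circular hue deviation lies below the band-width
quantile (q = 0.30) and, unless ablated, whose S and V fall within
median ± 2.0 × MAD (MAD scaled by 1.4826, the normal-consistent version).
All other non-nuclear tissue pixels are replaced by the per-channel median
of the pink band (hue median computed circularly) and then smoothed with a
bilateral filter (σ_spatial = nucleus radius in px, σ_range = 0.1) applied
only at replaced pixels. Nuclear pixels are returned bit-identical. The
preliminary nuclei estimate for this step is a hematoxylin-channel Otsu
inside tissue, minus the artifact mask.

**Composition and ablations.** `preprocess` chains the three stages and
finally paints the artifact regions with the pink-band median HSV (the same
color as the replacement rule) so that stain speckles cannot seed false
detections. Ablation variants toggle exactly one component: AB01 removes
the S/V MAD constraints, AB02 forces the quantile fallback, AB03 disables
tiny-component removal and hole filling, AB04 dilates the nuclei mask by
2 px before replacement. The whole stack is deterministic given the image
and configuration.

## Segmentation

Two backends share one contract. The optional StarDist 2D backend (pretrained
"Versatile HE") is used when the `stardist` package and weights are present;
it is never required. The self-contained fallback is hematoxylin-channel
Otsu followed by a Euclidean distance transform and marker-based watershed,
with markers from distance peaks separated by at least 0.45 × nucleus
diameter. Inputs are (5, 95) percentile-normalized with an affine (unclipped)
transform before inference.

Label maps become polygons by outer-boundary tracing of each instance
(holes ignored); coordinates are physical, `x = col·um_per_px`,
`y = row·um_per_px`, pixels 0-based (row, col). The centroid is the polygon
area centroid. Block-tiled inference segments each block with surrounding
context and keeps an instance iff its centroid falls in the block's
exclusive half-open core, so tiles partition instances without duplicates;
the area filter applies after merging. The area filter is a strict open
interval, default (50, 2000) µm².

## Spot geometry

Capture spots are discs with an effective 45 µm radius on a 100 µm pitch
(non-overlapping). A nucleus is counted in a spot iff its polygon intersects
the disc with positive area; among candidates the larger overlap *fraction*
(intersection / polygon area) wins, exact ties resolved toward the nearer
spot center and then the lower spot index. Count moments use the unbiased
variance (divisor |S|−1); VMR = σ²/n̄ requires n̄ > 0.

Pseudo-spots aggregate HD bins whose centers lie within 27.5 µm of a
hexagonal-grid center (offset rows, row spacing pitch·√3/2, origin at the
bin cloud's bounding-box corner). The boundary is inclusive (≤), fixed so
tests can be bit-exact; the kd-tree search is verified against brute force.
Bin→nucleus reconstruction assigns a bin to the nucleus strictly containing
its centroid; boundary or contested centroids go to the mask with the larger
overlap against the bin's 2 µm square footprint. QC then applies two strict
filters sequentially: 50 < area < 2000 µm², then total UMI > 50.

## Deconvolution

The observation model is NB2: `y_gs ~ NB(mu_gs, alpha_g)` with
`Var = mu + mu²/alpha` and `mu_gs = m_s · Σ_k w_ks r_gk`. The Gamma prior on
`m_s` is moment-matched to the nucleus-count moments: κ = n̄²/σ², θ = n̄/σ²,
giving prior mean n̄ and variance σ² exactly. Per-region calibration applies
the same closed form per ROI with a global fallback for degenerate regions.
Constant counts (σ² = 0) raise an error by default; an optional variance
floor is left to the caller.

Inference is MAP: `w` is parameterized by a per-spot softmax of free reals
and `m` by the exponential of a free real, optimized jointly by L-BFGS-B
with analytic gradients. Box bounds |log m| ≤ 18 guard against a numerical
pathology of shape-κ < 1 priors, whose density spike at m = 0 would
otherwise pull zero-count spots into underflow territory where the floored
mean decouples the likelihood from m. α_g defaults to a fixed value of 10
per gene; optionally it is re-estimated between optimizer runs by a
method-of-moments update shrunk on the log scale toward 10 (a weak
log-normal-style pull), since no prior for α_g is prescribed anywhere. A
reparameterized-Gaussian mean-field VI (one-sample gradients, Adam,
seed-deterministic) is available as an alternative inference mode; MAP is
the default and is exactly deterministic. Gene sets of counts and reference
are intersected with the order taken from the reference, duplicate
identifiers collapsed by sum.

Absolute counts are the post-hoc product `C_ks = w_ks · n_s`, real-valued
and summing to `n_s` per spot exactly. An optional scalar detection
efficiency multiplies the reference (default 1), leaving the prior on `m_s`
itself.

## Benchmarking

The benchmark ROI (3000×3000 px by default) is tiled 6×6 into 500 px tiles;
points map to tiles by half-open intervals. The five HASS terms are defined
concretely here (only their names are fixed externally): artifact/tissue
pixel fraction; 95th-percentile artifact component area over tile area;
fraction of artifact-boundary pixels on (1 px-dilated) V-channel Canny
edges; fraction of artifact pixels within two nucleus diameters of the
nuclei mask; and one minus the ratio of V-channel variance inside the
artifact to that in the remaining tissue, clipped to [0, 1]. Terms are
min–max normalized within the slide and averaged without weights. Quintile
levels use the 20/40/60/80 linear-interpolation percentiles with ties (and
boundary scores) assigned to the lower level, so an all-equal slide is
entirely level 1.

Counting accuracy uses ME/MAE/RMSE and Bland–Altman bias ± 1.96·sd (unbiased
sd of paired differences). Paired Wilcoxon tests use the exact signed-rank
distribution for ≤ 25 non-zero pairs and the continuity-corrected normal
approximation otherwise, zeros dropped, all-zero differences returning p = 1
by convention; families are Holm-adjusted. The noise significance threshold
L* is the smallest level L in 2..5 whose Mann–Whitney U comparison of error
shifts (≥ L vs < L) falls below the significance level (default 0.05).

## Synthetic fixtures

`synth_hne` renders an H&E-like tile in HSV: eosin-pink background
(hue 0.89–0.95, S 0.30–0.45), blue-purple elliptical nuclei (hue 0.75–0.86,
eccentricity ≤ 2:1, radius 5.5 ± 0.5 µm ≈ 95 µm² — comfortably inside the
(50, 2000) µm² filter), optional brown speckle artifacts (hue 0.04–0.10,
radius 4–8 µm, i.e. nucleus-sized, which is what makes them segmentation
false positives), a 20 px unstained white border so tissue masking has a
background mode, a linear illumination ramp, and Gaussian pixel noise.
Nuclei are packed without overlap by rejection sampling; ground truth
records every centroid, area and speckle pixel. `synth_st` samples the
deconvolution model's own generative process: n_s negative-binomial with
requested mean 8 and VMR 2 (VMR < 1 is rejected; VMR = 1 switches to
Poisson), m_s = n_s (efficiency 1), Dirichlet(1) proportions, per-gene
marker structure (one enriched type per gene, 10× boost) and α_g uniform on
(2, 20). The reference scale is set so spots carry ~300 UMIs — a shallow,
FFPE-like depth at which the prior's contribution is visible; at deep
coverage the likelihood dominates and informed and diffuse priors coincide.
`synth_hd_bins` lays Poisson-count bins on a 2 µm lattice with exact
membership lists per pseudo-spot. All generators draw from independent
counter-based substreams (Philox spawn keys) of one root seed and are
bit-reproducible.

What the fixtures do not emulate: stain physics and scanner PSF, hue
continua between stain classes (the synthetic hue distribution is
multi-modal with gaps, which makes thresholding *easier* than on real
slides), chromatin texture inside nuclei, overlapping nuclei in 3-D, and
ambient RNA or batch effects in the counts. Passing tests therefore
establish internal correctness — geometry, calibration identities, model
self-consistency and the direction of the preprocessing benefit — not
performance on real tissue.

## Problem sizes and determinism

The test and acceptance workloads use 256 px (128 µm) benchmark tiles with
34 nuclei and 6 % speckle burden (36 tiles for the paired comparison),
S = 100 / G = 200 / K = 4 for recovery, 100 random nuclei for the geometry
oracle, and 50 tile pairs for score monotonicity — sizes chosen to exercise
every code path at desk scale. MAP fits, the image stack, and all
generators are deterministic given their seeds; the only stochastic mode is
VI, which is reproducible for a fixed seed.

## Known limitations

- The fallback watershed under-splits heavily overlapping nuclei and is not
  a substitute for a learned instance model on real H&E.
- A single global prior can be miscalibrated in strongly mosaic tissue;
  per-ROI calibration helps but hyperparameters are still shared within a
  region.
- MAP returns the posterior mode; for κ slightly above 1 the mode sits
  (κ−1)/θ, a factor (κ−1)/κ below the prior mean, so prior-dominated spots
  are mildly shrunk relative to the mean. VI gives a posterior-mean-like
  estimate at higher cost.
- The hue-based artifact screen assumes artifacts occupy a hue tail distinct
  from both stains; artifacts sharing nuclear hue would require the target
  fraction window to reject the contaminated candidates, as it does in the
  dense-tissue fixtures.
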