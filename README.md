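# segdecon

Histology-informed spatial deconvolution for spot-based spatial
transcriptomics.

Spot-based platforms (10x Visium and kin) measure expression in ~55 µm
capture spots that each cover several cells, so per-spot cell-type
composition must be inferred by deconvolution against a single-cell
reference. Most deconvolution models place a fixed or heuristic prior on the
number of cells per spot, ignoring genuine spatial variation in cellularity.
`segdecon` closes that gap with the paired H&E image: it denoises the
histology in HSV color space, segments nuclei, counts nuclei per capture
spot, and uses those counts to calibrate the prior of a negative-binomial
deconvolution model — without ever modifying the transcript counts.

## The model

Observed counts for gene *g* at spot *s* follow a negative binomial in
mean/inverse-dispersion (NB2) form,

    y_gs ~ NB(mu_gs, alpha_g),        Var(y_gs) = mu_gs + mu_gs^2 / alpha_g,

with the mean factorized into a spot total abundance and a reference-weighted
cell-type mixture,

    mu_gs = m_s * sum_k w_ks r_gk,    w_ks >= 0,  sum_k w_ks = 1,

where `r_gk` is the reference expression of gene *g* in cell type *k*. The
image enters through a shape–rate Gamma prior on the total abundance,

    m_s ~ Gamma(kappa, theta),
    kappa = n_bar^2 / sigma^2 = n_bar / VMR,    theta = n_bar / sigma^2 = 1 / VMR,

moment-matched to the mean `n_bar` and unbiased variance `sigma^2` of the
image-derived per-spot nucleus counts `n_s` (VMR is the variance-to-mean
ratio). Uniform cellularity (small VMR) gives a tight prior; heterogeneous
tissue (large VMR) lets the expression data dominate. After inference,
absolute per-type counts follow as `C_ks = w_ks * n_s`.

Upstream of the model, the H&E image is processed in HSV space: an Otsu
tissue mask from the saturation channel, a hue-threshold artifact mask
screened against a target artifact-area fraction (Yen/Triangle/Otsu
candidates on both hue tails, extreme-quantile fallback), and a background
homogenization that replaces off-pink non-nuclear tissue with the eosin-core
median color. Nuclei are segmented into polygons (optional pretrained
StarDist backend, or a self-contained watershed fallback), filtered to areas
strictly inside (50, 2000) µm², and assigned to 45 µm capture discs by
largest overlap. A five-term artifact severity score (HASS) with quintile
noise levels supports tile-wise benchmarking against manual counts
(ME/MAE/RMSE, Bland–Altman limits of agreement, paired Wilcoxon with Holm
correction).

## Worked example

```python
import numpy as np
from scipy.stats import pearsonr
from segdecon import NucleiSegmenter, count_moments, moment_match_prior, preprocess
from segdecon.deconv import ReferenceProfile, SpotDeconvolver
from segdecon.spot_mapping import SpotCounts
from segdecon.synthetic import SynthImageSpec, SynthStSpec, synth_hne, synth_st

# histology side: denoise an artifact-laden tile, then count nuclei
tile = synth_hne(SynthImageSpec(size_px=256, n_nuclei=34, speckle_fraction=0.06), seed=0)
pp = preprocess(tile.rgb)
nuclei = NucleiSegmenter().predict(pp.rgb)
print(f"nuclei detected: {len(nuclei)} (ground truth {len(tile.ground_truth)})")
print(f"artifact mask: method={pp.provenance['artifact_method']}, "
      f"area fraction={pp.provenance['artifact_area_fraction']:.3f}")

# expression side: calibrate the prior from counts and deconvolve
st = synth_st(SynthStSpec(), seed=0)           # S=100 spots, G=200 genes, K=4 types
mom = count_moments(st.n_s)
prior = moment_match_prior(mom)
print(f"n_bar={mom.n_bar:.2f} sigma2={mom.sigma2:.2f} VMR={mom.vmr:.2f}")
print(f"Gamma prior: kappa={prior.kappa:.3f} theta={prior.theta:.3f}")

ref = ReferenceProfile(st.genes, st.cell_types, st.r_gk)
ns = SpotCounts(list(range(100)), st.n_s)
model = SpotDeconvolver(reference=ref, seed=0).fit(st.y, nucleus_counts=ns)
r = pearsonr((st.w * st.m[:, None]).ravel(),
             (model.w_ks_ * model.m_s_[:, None]).ravel())[0]
print(f"abundance recovery: Pearson r={r:.3f}")
```

Output:

```
nuclei detected: 34 (ground truth 34)
artifact mask: method=otsu, area fraction=0.085
n_bar=8.46 sigma2=15.04 VMR=1.78
Gamma prior: kappa=4.759 theta=0.563
abundance recovery: Pearson r=0.984
```

The denoised tile is counted exactly (the brown stain speckles that inflate
the raw count are masked out), the prior reproduces the count moments by
construction, and the fitted per-spot per-type abundances `w_ks * m_s`
correlate with the generative truth at r ≈ 0.98. `model.C_ks_` holds the
absolute per-type counts, which sum to `n_s` in every spot.

A thin CLI wraps the same functions for shell use: `segdecon preprocess`,
`segment`, `map`, `deconv`, `bench`, `simulate` (see `segdecon --help`).

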