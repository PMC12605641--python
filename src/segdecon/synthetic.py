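"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`synth_hne` — an H&E-like RGB tile: pink eosin background, blue-purple
  elliptical nuclei, optional brown speckle artifacts, illumination drift and
  pixel noise.  Ground truth lists every nucleus centroid/area and every
  speckle pixel.
* :func:`synth_st` — spot-by-gene UMI counts drawn from the deconvolution
  model's own generative process (negative-binomial counts around
  ``mu_gs = m_s * sum_k w_ks r_gk``), with the true abundances returned.
* :func:`synth_hd_bins` — a 2 µm bin lattice with Poisson counts and the exact
  pseudo-spot membership of every bin.

All generators are bit-reproducible given (spec, seed): each one draws from an
independent counter-based substream of the root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw
from skimage.color import hsv2rgb

from ._utils import STREAM_HD, STREAM_HNE, STREAM_ST, rng_stream

__all__ = [
    "SynthImageSpec",
    "SynthHneResult",
    "SynthStSpec",
    "SynthStResult",
    "SynthHdSpec",
    "SynthHdResult",
    "synth_hne",
    "synth_st",
    "synth_hd_bins",
]


# ---------------------------------------------------------------------------
# H&E-like image
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthImageSpec:
    """Parameters of the synthetic stained-tissue tile.

    Hue bands are fractions of the full hue circle (skimage convention):
    eosin pink sits near 0.92, hematoxylin blue-purple near 0.70, and the
    brown speckle artifacts near 0.07.
    """

    size_px: int = 512
    um_per_px: float = 0.5
    n_nuclei: int = 50
    nucleus_radius_um_mean: float = 5.5
    nucleus_radius_um_sd: float = 0.5
    nucleus_hue: tuple[float, float] = (0.75, 0.86)
    nucleus_sat: tuple[float, float] = (0.45, 0.65)
    nucleus_val: tuple[float, float] = (0.30, 0.50)
    background_hue: tuple[float, float] = (0.89, 0.95)
    background_sat: tuple[float, float] = (0.30, 0.45)
    background_val: tuple[float, float] = (0.88, 0.96)
    speckle_fraction: float = 0.0
    speckle_hue: tuple[float, float] = (0.04, 0.10)
    speckle_sat: tuple[float, float] = (0.50, 0.70)
    speckle_val: tuple[float, float] = (0.25, 0.45)
    speckle_radius_um: tuple[float, float] = (4.0, 8.0)
    illumination_gradient: float = 0.04
    noise_sd: float = 0.01
    slide_margin_px: int = 20          # unstained white border around the tissue
    allow_overlap: bool = False
    seed: int = 0


@dataclass
class SynthHneResult:
    rgb: np.ndarray                  # (H, W, 3) uint8
    ground_truth: pd.DataFrame       # id, x_um, y_um, area_um2
    nuclei_mask: np.ndarray          # bool raster
    speckle_mask: np.ndarray         # bool raster
    spec: SynthImageSpec


def _uniform(rng: np.random.Generator, band: tuple[float, float], size=None):
    return rng.uniform(band[0], band[1], size=size)


def synth_hne(spec: SynthImageSpec, seed: int | None = None) -> SynthHneResult:
    """Render the tile and return it with full ground truth.

    Raises
    ------
    RuntimeError
        If the requested number of non-overlapping nuclei cannot be packed
        into the tile.
    """
    seed = spec.seed if seed is None else seed
    rng = rng_stream(seed, STREAM_HNE)
    n_px = spec.size_px
    px = spec.um_per_px

    h = np.empty((n_px, n_px), dtype=float)
    s = np.empty_like(h)
    v = np.empty_like(h)
    h[:] = _uniform(rng, spec.background_hue, (n_px, n_px))
    s[:] = _uniform(rng, spec.background_sat, (n_px, n_px))
    v[:] = _uniform(rng, spec.background_val, (n_px, n_px))

    # unstained slide border: nearly white, so tissue masking has a
    # background mode to separate from
    mg = spec.slide_margin_px
    if mg > 0:
        border = np.ones((n_px, n_px), dtype=bool)
        border[mg:-mg, mg:-mg] = False
        s[border] = rng.uniform(0.0, 0.03, border.sum())
        v[border] = rng.uniform(0.96, 1.0, border.sum())

    # --- nuclei: ellipses with eccentricity <= 2:1, optionally non-overlapping
    nuclei_mask = np.zeros((n_px, n_px), dtype=bool)
    centers: list[tuple[float, float, float]] = []  # (row, col, clearance radius px)
    records = []
    max_tries = 200 * max(spec.n_nuclei, 1)
    tries = 0
    nid = 0
    while nid < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei "
                f"in a {n_px}x{n_px} px tile"
            )
        r_um = max(rng.normal(spec.nucleus_radius_um_mean, spec.nucleus_radius_um_sd), 1.0)
        ecc = rng.uniform(1.0, 2.0)
        a_px = r_um * np.sqrt(ecc) / px   # semi-major
        b_px = r_um / np.sqrt(ecc) / px   # semi-minor
        margin = a_px + 2 + mg
        row = rng.uniform(margin, n_px - margin)
        col = rng.uniform(margin, n_px - margin)
        if not spec.allow_overlap:
            clash = any(
                np.hypot(row - r0, col - c0) < (a_px + rad0 + 2) for r0, c0, rad0 in centers
            )
            if clash:
                continue
        rot = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(row, col, a_px, b_px, shape=(n_px, n_px), rotation=rot)
        if rr.size == 0:
            continue
        nid += 1
        centers.append((row, col, a_px))
        nuclei_mask[rr, cc] = True
        h[rr, cc] = _uniform(rng, spec.nucleus_hue, rr.size)
        s[rr, cc] = _uniform(rng, spec.nucleus_sat, rr.size)
        v[rr, cc] = _uniform(rng, spec.nucleus_val, rr.size)
        records.append(
            {
                "id": nid,
                "x_um": col * px,
                "y_um": row * px,
                "area_um2": rr.size * px * px,
            }
        )

    # --- speckle artifacts: brown blobs outside nuclei, up to the target
    #     pixel fraction of the whole tile
    speckle_mask = np.zeros((n_px, n_px), dtype=bool)
    if spec.speckle_fraction > 0:
        target_px = spec.speckle_fraction * n_px * n_px
        guard = 0
        while speckle_mask.sum() < target_px:
            guard += 1
            if guard > 20000:
                break
            rad = rng.uniform(*spec.speckle_radius_um) / px
            row = rng.uniform(rad + 1 + mg, n_px - rad - 1 - mg)
            col = rng.uniform(rad + 1 + mg, n_px - rad - 1 - mg)
            rr, cc = draw.disk((row, col), rad, shape=(n_px, n_px))
            if rr.size == 0 or nuclei_mask[rr, cc].any():
                continue
            speckle_mask[rr, cc] = True
            h[rr, cc] = _uniform(rng, spec.speckle_hue, rr.size)
            s[rr, cc] = _uniform(rng, spec.speckle_sat, rr.size)
            v[rr, cc] = _uniform(rng, spec.speckle_val, rr.size)

    # --- illumination drift + pixel noise on V
    if spec.illumination_gradient:
        ramp = np.linspace(-0.5, 0.5, n_px)[None, :] * spec.illumination_gradient
        v = v + ramp
    if spec.noise_sd:
        v = v + rng.normal(0.0, spec.noise_sd, v.shape)
        s = s + rng.normal(0.0, spec.noise_sd, s.shape)
    s = np.clip(s, 0.0, 1.0)
    v = np.clip(v, 0.0, 1.0)
    h = h % 1.0

    rgb = hsv2rgb(np.stack([h, s, v], axis=-1))
    rgb8 = np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)

    gt = pd.DataFrame(records, columns=["id", "x_um", "y_um", "area_um2"])
    return SynthHneResult(rgb8, gt, nuclei_mask, speckle_mask, spec)


# ---------------------------------------------------------------------------
# Spot-by-gene counts from the deconvolution model's generative process
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthStSpec:
    """Generative settings for spot-level counts.

    ``n_mean``/``n_vmr`` control the negative-binomial law of per-spot nucleus
    counts; per-type marker structure makes the reference identifiable.
    """

    S: int = 100
    G: int = 200
    K: int = 4
    r_base_shape: float = 0.3
    r_marker_boost: float = 10.0
    r_scale: float = 0.2               # overall depth: ~300 UMIs/spot at defaults
    dirichlet_alpha: float = 1.0
    n_mean: float = 8.0
    n_vmr: float = 2.0
    alpha_range: tuple[float, float] = (2.0, 20.0)
    seed: int = 0


@dataclass
class SynthStResult:
    y: np.ndarray          # (S, G) integer counts
    r_gk: np.ndarray       # (G, K) reference expression
    w: np.ndarray          # (S, K) true proportions (rows on the simplex)
    m: np.ndarray          # (S,) true total abundance
    n_s: np.ndarray        # (S,) true nucleus counts (== m at efficiency 1)
    alpha_g: np.ndarray    # (G,) true inverse-dispersions
    genes: list[str] = field(default_factory=list)
    cell_types: list[str] = field(default_factory=list)


def sample_nb_counts(
    mu: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw NB2 counts with mean ``mu`` and variance ``mu + mu^2/alpha``."""
    mu = np.asarray(mu, dtype=float)
    alpha_b = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = alpha_b[pos] / (alpha_b[pos] + mu[pos])
    out[pos] = rng.negative_binomial(alpha_b[pos], p)
    return out


def _sample_counts_mean_vmr(
    mean: float, vmr: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer counts with the requested mean and variance-to-mean ratio."""
    if vmr < 1.0:
        raise ValueError(
            "a negative-binomial count law cannot be underdispersed (vmr < 1); "
            "use vmr = 1 for Poisson"
        )
    if vmr == 1.0:
        return rng.poisson(mean, size)
    size_param = mean / (vmr - 1.0)   # NB size r: var = m + m^2/r = m*vmr
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size)


def synth_st(spec: SynthStSpec, seed: int | None = None) -> SynthStResult:
    """Sample (y, r_gk, w, m, n_s) from the model's own generative process."""
    seed = spec.seed if seed is None else seed
    rng = rng_stream(seed, STREAM_ST)
    S, G, K = spec.S, spec.G, spec.K
    if min(S, G, K) < 1:
        raise ValueError("S, G, K must all be >= 1")

    r = rng.gamma(spec.r_base_shape, 1.0, size=(G, K))
    home = rng.integers(0, K, size=G)
    r[np.arange(G), home] *= spec.r_marker_boost
    r = np.maximum(r * spec.r_scale, 1e-8)

    n_s = _sample_counts_mean_vmr(spec.n_mean, spec.n_vmr, S, rng)
    m = n_s.astype(float)            # detection efficiency 1: m_s = n_s
    w = rng.dirichlet(np.full(K, spec.dirichlet_alpha), size=S)
    alpha_g = rng.uniform(*spec.alpha_range, size=G)

    mu = m[:, None] * (w @ r.T)      # (S, G)
    y = sample_nb_counts(mu, alpha_g[None, :], rng)

    genes = [f"gene_{i:04d}" for i in range(G)]
    cell_types = [f"type_{k}" for k in range(K)]
    return SynthStResult(y, r, w, m, n_s, alpha_g, genes, cell_types)


# ---------------------------------------------------------------------------
# HD bin lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthHdSpec:
    extent_um: tuple[float, float] = (300.0, 260.0)
    spot_pitch_um: float = 100.0
    capture_radius_um: float = 27.5
    bin_pitch_um: float = 2.0
    G: int = 20
    lam: float = 0.5
    seed: int = 0


@dataclass
class SynthHdResult:
    bin_centers: np.ndarray            # (B, 2) um
    bin_counts: np.ndarray             # (B, G) integer UMI
    spot_centers: np.ndarray           # (P, 2) um, hexagonal grid
    membership: dict[int, np.ndarray]  # spot index -> member bin indices


def hex_grid(extent_um: tuple[float, float], pitch_um: float) -> np.ndarray:
    """Hexagonal centers over [0, w] x [0, h]: offset rows, spacing pitch*sqrt(3)/2."""
    w, hgt = extent_um
    dy = pitch_um * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = 0.0
    while y <= hgt + 1e-9:
        x0 = 0.0 if row % 2 == 0 else pitch_um / 2.0
        x = x0
        while x <= w + 1e-9:
            pts.append((x, y))
            x += pitch_um
        y += dy
        row += 1
    return np.asarray(pts, dtype=float)


def synth_hd_bins(spec: SynthHdSpec, seed: int | None = None) -> SynthHdResult:
    """Bins on a regular lattice, Poisson counts, exact spot memberships."""
    seed = spec.seed if seed is None else seed
    rng = rng_stream(seed, STREAM_HD)
    w, hgt = spec.extent_um
    xs = np.arange(spec.bin_pitch_um / 2.0, w, spec.bin_pitch_um)
    ys = np.arange(spec.bin_pitch_um / 2.0, hgt, spec.bin_pitch_um)
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    counts = rng.poisson(spec.lam, size=(centers.shape[0], spec.G)).astype(np.int64)

    spots = hex_grid(spec.extent_um, spec.spot_pitch_um)
    membership = {}
    for i, c in enumerate(spots):
        d = np.hypot(centers[:, 0] - c[0], centers[:, 1] - c[1])
        membership[i] = np.flatnonzero(d <= spec.capture_radius_um)
    return SynthHdResult(centers, counts, spots, membership)


def spec_with(spec, **kw):
    """Copy of a frozen spec dataclass with fields replaced."""
    return dataclasses.replace(spec, **kw)
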