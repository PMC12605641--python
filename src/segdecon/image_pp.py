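"""HSV-space preprocessing of H&E images.

The stack has four stages, each exposed as a function and composed by
:func:`preprocess` (or the sklearn-style :class:`HneImagePreprocessor`):

1. RGB -> HSV conversion, with hue treated as an angle.
2. Tissue masking from the saturation channel (or the hematoxylin component
   of an RGB -> H/E/DAB color deconvolution), Otsu-thresholded with
   resolution-aware area filtering and a disk closing.
3. Hue-based artifact masking inside tissue: hue is percentile-clipped and
   normalized, then Yen / Triangle / Otsu thresholds on both hue tails are
   screened against a target artifact-area fraction, with an extreme-quantile
   fallback when none qualifies.
4. Background homogenization: an S-weighted circular mean hue defines the
   eosin "pink core"; non-nuclear tissue pixels outside a circular-hue
   quantile band (and outside robust S/V MAD ranges) are replaced by the core
   median HSV and lightly bilateral-smoothed.

Ablation variants toggle single stages for controlled comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage.restoration import denoise_bilateral

from ._utils import (
    TWO_PI,
    circular_diff,
    circular_mean,
    normal_consistent_mad,
    um2_to_px,
)

__all__ = [
    "ImageScale",
    "HsvImage",
    "TissueMask",
    "ArtifactMask",
    "PinkCore",
    "AblationVariant",
    "AblationConfig",
    "PreprocessResult",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "tissue_mask",
    "artifact_mask",
    "homogenize_background",
    "preprocess",
    "HneImagePreprocessor",
]

DEFAULT_MIN_TISSUE_AREA_UM2 = 400.0
DEFAULT_CLIP = (5.0, 95.0)
DEFAULT_TARGET = (0.005, 0.30)
SMALL_COMPONENT_FACTOR = 0.35
FALLBACK_QUANTILE = 0.02


@dataclass(frozen=True)
class ImageScale:
    """Physical acquisition scale.

    Parameters
    ----------
    um_per_px : float
        Microns per pixel (default 0.5).
    nucleus_diameter_um : float
        Expected nucleus diameter in microns (default 10).
    """

    um_per_px: float = 0.5
    nucleus_diameter_um: float = 10.0

    def __post_init__(self):
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.nucleus_diameter_um <= 0:
            raise ValueError("nucleus_diameter_um must be > 0")

    @property
    def nucleus_radius_px(self) -> int:
        return max(1, int(round(self.nucleus_diameter_um / 2.0 / self.um_per_px)))

    def area_px(self, area_um2: float) -> int:
        return um2_to_px(area_um2, self.um_per_px)

    @property
    def nucleus_area_um2(self) -> float:
        return float(np.pi * (self.nucleus_diameter_um / 2.0) ** 2)


@dataclass
class HsvImage:
    """HSV raster with angular hue (radians in [0, 2*pi)) and unit S/V."""

    h: np.ndarray
    s: np.ndarray
    v: np.ndarray
    scale: ImageScale
    rgb: np.ndarray | None = None   # original 8-bit RGB, kept for stain separation

    def __post_init__(self):
        if not (self.h.shape == self.s.shape == self.v.shape):
            raise ValueError("H, S, V channels must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.h.shape

    def copy(self) -> "HsvImage":
        return HsvImage(
            self.h.copy(), self.s.copy(), self.v.copy(), self.scale,
            None if self.rgb is None else self.rgb.copy(),
        )


@dataclass
class TissueMask:
    mask: np.ndarray
    source: str = "saturation"
    min_object_area_um2: float = DEFAULT_MIN_TISSUE_AREA_UM2


@dataclass
class ArtifactMask:
    mask: np.ndarray
    chosen_threshold: float
    chosen_method: str          # yen | triangle | otsu | quantile_fallback
    chosen_tail: str            # high_hue | low_hue
    area_fraction: float


@dataclass
class PinkCore:
    core_hue: float
    q_width: float = 0.30
    k_s: float = 2.0
    k_v: float = 2.0
    median_hsv: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not (0 < self.q_width <= 1):
            raise ValueError("q_width must lie in (0, 1]")
        if self.k_s <= 0 or self.k_v <= 0:
            raise ValueError("MAD multipliers must be > 0")


class AblationVariant(str, Enum):
    PP01_base = "PP01_base"
    AB01_disable_MAD = "AB01_disable_MAD"
    AB02_force_quantile = "AB02_force_quantile"
    AB03_no_smallfilter = "AB03_no_smallfilter"
    AB04_dilate2 = "AB04_dilate2"


@dataclass(frozen=True)
class AblationConfig:
    variant: AblationVariant = AblationVariant.PP01_base
    dilation_px: int = 0

    def __post_init__(self):
        if self.variant is AblationVariant.AB04_dilate2 and self.dilation_px == 0:
            object.__setattr__(self, "dilation_px", 2)


@dataclass
class PreprocessResult:
    rgb: np.ndarray
    hsv: HsvImage
    tissue: TissueMask
    artifact: ArtifactMask
    nuclei_mask: np.ndarray
    pink: PinkCore
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Color-space conversion
# ---------------------------------------------------------------------------

def rgb_to_hsv(image: np.ndarray, scale: ImageScale = ImageScale()) -> HsvImage:
    """Standard hexcone RGB -> HSV; hue stored as an angle in [0, 2*pi)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("expected a 3-channel RGB raster")
    if image.dtype != np.uint8:
        image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    hsv = skcolor.rgb2hsv(image)
    return HsvImage(
        h=hsv[..., 0] * TWO_PI,
        s=hsv[..., 1],
        v=hsv[..., 2],
        scale=scale,
        rgb=image,
    )


def hsv_to_rgb(hsv: HsvImage) -> np.ndarray:
    """Inverse conversion back to 8-bit RGB."""
    stack = np.stack([(hsv.h % TWO_PI) / TWO_PI, hsv.s, hsv.v], axis=-1)
    rgb = skcolor.hsv2rgb(stack)
    return np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)


def hematoxylin_channel(rgb: np.ndarray) -> np.ndarray:
    """Hematoxylin component of the RGB -> H/E/DAB color deconvolution."""
    return skcolor.rgb2hed(rgb)[..., 0]


# ---------------------------------------------------------------------------
# Tissue mask
# ---------------------------------------------------------------------------

def tissue_mask(
    hsv: HsvImage,
    source: str = "saturation",
    min_object_area_um2: float = DEFAULT_MIN_TISSUE_AREA_UM2,
) -> TissueMask:
    """Otsu tissue mask from the S channel (or hematoxylin), with
    resolution-aware area filtering and a disk closing.

    A blank channel yields an empty mask with a warning rather than an error.
    """
    scale = hsv.scale
    if source == "saturation":
        channel = hsv.s
    elif source == "hematoxylin":
        if hsv.rgb is None:
            raise ValueError("hematoxylin source requires the original RGB image")
        channel = hematoxylin_channel(hsv.rgb)
    else:
        raise ValueError(f"unknown tissue mask source: {source!r}")

    if np.ptp(channel) == 0:
        warnings.warn("tissue channel has zero variance; returning an empty mask")
        return TissueMask(np.zeros(channel.shape, bool), source, min_object_area_um2)

    thr = skfilters.threshold_otsu(channel)
    mask = channel > thr
    min_px = scale.area_px(min_object_area_um2)
    mask = skmorph.remove_small_objects(mask, max_size=min_px - 1)
    mask = skmorph.remove_small_holes(mask, max_size=min_px - 1)
    mask = skmorph.closing(mask, skmorph.disk(scale.nucleus_radius_px))
    return TissueMask(mask, source, min_object_area_um2)


# ---------------------------------------------------------------------------
# Artifact mask
# ---------------------------------------------------------------------------

def _clip_normalize_hue(hue_frac: np.ndarray, inside: np.ndarray, clip) -> np.ndarray:
    """Percentile-clip hue (as a unit fraction) within tissue, min-max to [0,1]."""
    lo, hi = np.percentile(hue_frac[inside], clip)
    if hi <= lo:
        return np.zeros_like(hue_frac)
    return np.clip((hue_frac - lo) / (hi - lo), 0.0, 1.0)


def _clean_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    mask = skmorph.remove_small_objects(mask, max_size=min_px - 1)
    return skmorph.remove_small_holes(mask, area_threshold=min_px)


def artifact_mask(
    hsv: HsvImage,
    tissue: TissueMask,
    clip: tuple[float, float] = DEFAULT_CLIP,
    target: tuple[float, float] = DEFAULT_TARGET,
    force_fallback: bool = False,
    clean_small: bool = True,
    small_factor: float = SMALL_COMPONENT_FACTOR,
) -> ArtifactMask:
    """Hue-threshold artifact mask inside tissue.

    Candidate thresholds are screened in a fixed order (Yen, Triangle, Otsu;
    high-hue tail before low) and the first whose artifact-area fraction lands
    inside ``target`` wins; otherwise extreme 2 % quantiles are used and the
    tail with the smaller area is kept.  Components smaller than
    ``small_factor * pi * (d/2)^2`` are removed and equally small holes filled
    (skipped when ``clean_small`` is False).
    """
    tmask = tissue.mask
    if not tmask.any():
        raise ValueError("artifact masking requires a non-empty tissue mask")
    scale = hsv.scale
    hue_frac = (hsv.h % TWO_PI) / TWO_PI
    norm = _clip_normalize_hue(hue_frac, tmask, clip)
    vals = norm[tmask]
    n_tissue = int(tmask.sum())
    min_px = max(1, scale.area_px(small_factor * scale.nucleus_area_um2))

    def build(mask_raw: np.ndarray) -> tuple[np.ndarray, float]:
        m = mask_raw & tmask
        if clean_small:
            m = _clean_small(m, min_px) & tmask
        return m, m.sum() / n_tissue

    candidates: list[tuple[str, str, float]] = []
    if not force_fallback and np.ptp(vals) > 0:
        methods = (
            ("yen", skfilters.threshold_yen),
            ("triangle", skfilters.threshold_triangle),
            ("otsu", skfilters.threshold_otsu),
        )
        for name, fn in methods:
            try:
                thr = float(fn(vals))
            except Exception:
                continue
            candidates.append((name, "high_hue", thr))
            candidates.append((name, "low_hue", thr))

    for name, tail, thr in candidates:
        raw = (norm > thr) if tail == "high_hue" else (norm < thr)
        m, frac = build(raw)
        if target[0] <= frac <= target[1]:
            return ArtifactMask(m, thr, name, tail, frac)

    # extreme-quantile fallback: keep the tail with the smaller area
    q = FALLBACK_QUANTILE
    thr_hi = float(np.quantile(vals, 1 - q))
    thr_lo = float(np.quantile(vals, q))
    # strict comparisons: an all-equal hue field yields an empty mask
    # instead of flagging the whole tissue
    m_hi, f_hi = build(norm > thr_hi)
    m_lo, f_lo = build(norm < thr_lo)
    if f_hi <= f_lo:
        return ArtifactMask(m_hi, thr_hi, "quantile_fallback", "high_hue", f_hi)
    return ArtifactMask(m_lo, thr_lo, "quantile_fallback", "low_hue", f_lo)


# ---------------------------------------------------------------------------
# Background homogenization
# ---------------------------------------------------------------------------

def homogenize_background(
    hsv: HsvImage,
    tissue: TissueMask,
    nuclei_mask: np.ndarray,
    pink: PinkCore | None = None,
    ablation: AblationConfig = AblationConfig(),
) -> tuple[HsvImage, PinkCore]:
    """Replace off-pink, non-nuclear tissue by the pink-core median HSV.

    The pink core is the S-weighted circular mean hue of non-nuclear tissue;
    the pink band keeps pixels within the circular-hue quantile band of width
    ``q_width`` around it and, unless the MAD constraints are ablated, within
    median +/- k * MAD (normal-consistent) on S and on V.  Replaced pixels are
    lightly bilateral-filtered; nuclear pixels are returned bit-identical.
    """
    if pink is None:
        pink = PinkCore(core_hue=np.nan)
    nuclei_mask = nuclei_mask.astype(bool)
    if ablation.dilation_px > 0:
        nuclei_mask = skmorph.dilation(
            nuclei_mask, skmorph.disk(ablation.dilation_px)
        )
    non_nuclear = tissue.mask & ~nuclei_mask
    if not non_nuclear.any():
        warnings.warn("no non-nuclear tissue pixels; returning input unchanged")
        return hsv.copy(), pink

    h, s, v = hsv.h, hsv.s, hsv.v
    core = circular_mean(h[non_nuclear], weights=s[non_nuclear])
    dev = np.abs(circular_diff(h, core))
    half_width = float(np.quantile(dev[non_nuclear], pink.q_width))
    in_band = dev <= half_width

    keep = in_band.copy()
    if ablation.variant is not AblationVariant.AB01_disable_MAD:
        for chan in (s, v):
            med = float(np.median(chan[non_nuclear]))
            mad = normal_consistent_mad(chan[non_nuclear])
            k = pink.k_s if chan is s else pink.k_v
            lo, hi = med - k * mad, med + k * mad
            keep &= (chan >= lo) & (chan <= hi)

    pink_px = non_nuclear & keep
    if not pink_px.any():
        pink_px = non_nuclear & in_band   # MAD constraints removed everything

    med_h = float((core + np.median(circular_diff(h[pink_px], core))) % TWO_PI)
    med_s = float(np.median(s[pink_px]))
    med_v = float(np.median(v[pink_px]))
    pink = replace(pink, core_hue=core, median_hsv=(med_h, med_s, med_v))

    replaced = non_nuclear & ~pink_px
    out = hsv.copy()
    out.h[replaced] = med_h
    out.s[replaced] = med_s
    out.v[replaced] = med_v

    if replaced.any():
        # light edge-preserving smoothing, restricted to the replaced pixels
        rgb = skcolor.hsv2rgb(
            np.stack([(out.h % TWO_PI) / TWO_PI, out.s, out.v], axis=-1)
        )
        smoothed = denoise_bilateral(
            rgb,
            sigma_color=0.1,
            sigma_spatial=hsv.scale.nucleus_radius_px,
            channel_axis=-1,
        )
        mixed = rgb.copy()
        mixed[replaced] = smoothed[replaced]
        back = skcolor.rgb2hsv(np.clip(mixed, 0, 1))
        out.h[replaced] = back[..., 0][replaced] * TWO_PI
        out.s[replaced] = back[..., 1][replaced]
        out.v[replaced] = back[..., 2][replaced]

    return out, pink


# ---------------------------------------------------------------------------
# Full stack
# ---------------------------------------------------------------------------

def preliminary_nuclei_mask(hsv: HsvImage, tissue: TissueMask) -> np.ndarray:
    """Hematoxylin-channel Otsu inside tissue — the nuclei estimate that the
    homogenization step must preserve."""
    if hsv.rgb is None:
        raise ValueError("preliminary nuclei mask requires the original RGB image")
    hema = hematoxylin_channel(hsv.rgb)
    inside = tissue.mask
    if not inside.any() or np.ptp(hema[inside]) == 0:
        return np.zeros(hsv.shape, bool)
    thr = skfilters.threshold_otsu(hema[inside])
    return (hema > thr) & inside


def preprocess(
    image: np.ndarray,
    scale: ImageScale = ImageScale(),
    ablation: AblationConfig = AblationConfig(),
    pink: PinkCore | None = None,
) -> PreprocessResult:
    """Tissue mask -> artifact mask -> background homogenization -> uniform
    background fill of artifact regions.  Deterministic given (image, config)."""
    variant = ablation.variant
    hsv = rgb_to_hsv(image, scale)
    tis = tissue_mask(hsv)
    art = artifact_mask(
        hsv,
        tis,
        force_fallback=(variant is AblationVariant.AB02_force_quantile),
        clean_small=(variant is not AblationVariant.AB03_no_smallfilter),
    )
    nuc = preliminary_nuclei_mask(hsv, tis) & ~art.mask
    hom, pink_out = homogenize_background(hsv, tis, nuc, pink, ablation)

    # artifact regions are flattened to a uniform background before inference;
    # the fill color is the tissue-median HSV, matching the replacement rule
    fill = (
        float(
            (circular_mean(hsv.h[tis.mask], weights=hsv.s[tis.mask]))
            % TWO_PI
        ),
        float(np.median(hsv.s[tis.mask])),
        float(np.median(hsv.v[tis.mask])),
    )
    bg = pink_out.median_hsv if pink_out.median_hsv != (0.0, 0.0, 0.0) else fill
    hom.h[art.mask], hom.s[art.mask], hom.v[art.mask] = bg

    out_rgb = hsv_to_rgb(hom)
    prov = {
        "variant": variant.value,
        "dilation_px": ablation.dilation_px,
        "artifact_method": art.chosen_method,
        "artifact_tail": art.chosen_tail,
        "artifact_threshold": art.chosen_threshold,
        "artifact_area_fraction": art.area_fraction,
        "pink_q_width": pink_out.q_width,
        "pink_k_s": pink_out.k_s,
        "pink_k_v": pink_out.k_v,
        "um_per_px": scale.um_per_px,
        "nucleus_diameter_um": scale.nucleus_diameter_um,
        "min_tissue_area_um2": tis.min_object_area_um2,
    }
    return PreprocessResult(out_rgb, hom, tis, art, nuc, pink_out, prov)


class HneImagePreprocessor:
    """sklearn-style transformer over :func:`preprocess`.

    ``transform`` maps an 8-bit RGB raster to its preprocessed counterpart;
    the full :class:`PreprocessResult` of the last transform is kept on
    ``result_``.  The transformer is stateless across images (``fit`` is a
    no-op kept for pipeline compatibility).
    """

    def __init__(
        self,
        um_per_px: float = 0.5,
        nucleus_diameter_um: float = 10.0,
        variant: str | AblationVariant = AblationVariant.PP01_base,
        dilation_px: int = 0,
    ):
        self.um_per_px = um_per_px
        self.nucleus_diameter_um = nucleus_diameter_um
        self.variant = variant
        self.dilation_px = dilation_px

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "um_per_px": self.um_per_px,
            "nucleus_diameter_um": self.nucleus_diameter_um,
            "variant": self.variant,
            "dilation_px": self.dilation_px,
        }

    def set_params(self, **params) -> "HneImagePreprocessor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> tuple[ImageScale, AblationConfig]:
        scale = ImageScale(self.um_per_px, self.nucleus_diameter_um)
        variant = AblationVariant(self.variant)
        return scale, AblationConfig(variant, self.dilation_px)

    def fit(self, X=None, y=None) -> "HneImagePreprocessor":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        scale, ablation = self._config()
        self.result_ = preprocess(X, scale, ablation)
        return self.result_.rgb

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
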