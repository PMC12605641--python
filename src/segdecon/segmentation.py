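"""Instance segmentation of nuclei into polygons.

Two backends share one contract: an optional pretrained StarDist 2D model
(star-convex polygons; requires the ``stardist`` package and its weights at
runtime), and a self-contained deterministic fallback — hematoxylin-channel
Otsu followed by a distance-transform watershed.  All downstream code and all
tests run on the fallback, so no model download is ever required.

Instances are reported in physical microns: a simple outer-boundary polygon,
its area centroid, and its area.  A strict open-interval area filter
(default (50, 2000) µm²) removes debris and merged objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage import measure as skmeasure
from skimage import filters as skfilters
from skimage import morphology as skmorph
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .image_pp import ImageScale, hematoxylin_channel

__all__ = [
    "NucleusInstance",
    "SegmentationParams",
    "segment_nuclei",
    "filter_nuclei_by_area",
    "fallback_segment",
    "NucleiSegmenter",
    "percentile_normalize",
]

DEFAULT_AREA_RANGE = (50.0, 2000.0)


@dataclass
class NucleusInstance:
    """One segmented nucleus in physical coordinates (µm)."""

    id: int
    polygon: Polygon
    centroid: tuple[float, float]
    area_um2: float


@dataclass(frozen=True)
class SegmentationParams:
    backend: str = "fallback"                    # stardist_2d | fallback
    prob_thresh: float = 0.2
    block_size: int = 4096
    min_overlap: int = 128
    context: int = 128
    n_tiles: tuple[int, int] | None = None
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE

    def __post_init__(self):
        if not (0 < self.prob_thresh < 1):
            raise ValueError("prob_thresh must lie in (0, 1)")
        if self.area_range_um2[0] >= self.area_range_um2[1]:
            raise ValueError("area range min must be < max")


def percentile_normalize(
    image: np.ndarray, pmin: float = 5.0, pmax: float = 95.0
) -> np.ndarray:
    """(5, 95) percentile normalization, the pre-inference contract.

    Affine, not clipped: values outside the percentile window keep their
    contrast, matching how deep-learning backends normalize before inference.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = np.percentile(img, (pmin, pmax))
    if hi <= lo:
        return img - lo
    return (img - lo) / (hi - lo)


def _label_map_to_instances(labels: np.ndarray, scale: ImageScale) -> list[NucleusInstance]:
    """Outer-boundary tracing of each labelled component; ids dense from 1.

    Holes inside an instance are ignored; the centroid is the polygon's area
    centroid.
    """
    px = scale.um_per_px
    instances: list[NucleusInstance] = []
    next_id = 1
    for region in skmeasure.regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        # pad so the contour closes around border-touching instances
        m = np.zeros((maxr - minr + 2, maxc - minc + 2), dtype=float)
        m[1:-1, 1:-1] = region.image
        contours = skmeasure.find_contours(m, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        rows = contour[:, 0] + minr - 1
        cols = contour[:, 1] + minc - 1
        poly = Polygon(np.column_stack([cols * px, rows * px]))
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.area <= 0:
            continue
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        c = poly.centroid
        instances.append(NucleusInstance(next_id, poly, (c.x, c.y), poly.area))
        next_id += 1
    return instances


def fallback_segment(
    image: np.ndarray, scale: ImageScale = ImageScale(), seed: int = 0
) -> list[NucleusInstance]:
    """Deterministic watershed backend.

    Hematoxylin-channel Otsu isolates nuclear chroma; the Euclidean distance
    transform seeds a watershed that splits touching nuclei.  ``seed`` is part
    of the contract for backend interchangeability; the procedure itself has
    no random component.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        hema = hematoxylin_channel(image)
    else:
        hema = image.astype(float)
    hema = percentile_normalize(hema)
    if np.ptp(hema) == 0:
        return []
    thr = skfilters.threshold_otsu(hema)
    fg = hema > thr
    fg = skmorph.remove_small_objects(fg, max_size=3)
    if not fg.any():
        return []
    distance = ndi.distance_transform_edt(fg)
    min_dist = max(2, int(round(0.45 * scale.nucleus_diameter_um / scale.um_per_px)))
    coords = peak_local_max(
        distance, min_distance=min_dist, labels=fg, exclude_border=False
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers, _ = ndi.label(fg)
    labels = watershed(-distance, markers, mask=fg)
    return _label_map_to_instances(labels, scale)


def _segment_block(image, scale, params, seed):
    if params.backend == "fallback":
        return fallback_segment(image, scale, seed)
    if params.backend == "stardist_2d":
        try:
            from stardist.models import StarDist2D  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "backend 'stardist_2d' requires the optional stardist package "
                "and its pretrained weights; use backend='fallback' for a "
                "self-contained run"
            ) from exc
        return _stardist_segment(image, scale, params)
    raise ValueError(f"unknown backend {params.backend!r}")


def _stardist_segment(image, scale, params):  # pragma: no cover - optional backend
    from csbdeep.utils import normalize
    from stardist.models import StarDist2D

    model = StarDist2D.from_pretrained("2D_versatile_he")
    labels, _ = model.predict_instances(
        normalize(image, 5, 95), prob_thresh=params.prob_thresh
    )
    return _label_map_to_instances(labels, scale)


def segment_nuclei(
    image: np.ndarray,
    scale: ImageScale = ImageScale(),
    params: SegmentationParams = SegmentationParams(),
    seed: int = 0,
) -> list[NucleusInstance]:
    """Segment an image into nucleus instances, optionally block-tiled.

    With tiling, each block is segmented with surrounding context and an
    instance is kept iff its centroid falls in the block's exclusive core, so
    the tiles partition the instances without duplicates.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if params.n_tiles is None or params.n_tiles == (1, 1):
        return _renumber(_segment_block(image, scale, params, seed))

    ty, tx = params.n_tiles[:2]
    ctx = params.context
    core_h, core_w = int(np.ceil(h / ty)), int(np.ceil(w / tx))
    out: list[NucleusInstance] = []
    for iy in range(ty):
        for ix in range(tx):
            y0, x0 = iy * core_h, ix * core_w
            y1, x1 = min(h, y0 + core_h), min(w, x0 + core_w)
            ys, xs = max(0, y0 - ctx), max(0, x0 - ctx)
            ye, xe = min(h, y1 + ctx), min(w, x1 + ctx)
            block = image[ys:ye, xs:xe]
            for inst in _segment_block(block, scale, params, seed):
                cx = inst.centroid[0] + xs * scale.um_per_px
                cy = inst.centroid[1] + ys * scale.um_per_px
                # keep iff centroid in this tile's half-open core
                if (
                    x0 * scale.um_per_px <= cx < x1 * scale.um_per_px
                    and y0 * scale.um_per_px <= cy < y1 * scale.um_per_px
                ):
                    from shapely.affinity import translate

                    poly = translate(
                        inst.polygon,
                        xoff=xs * scale.um_per_px,
                        yoff=ys * scale.um_per_px,
                    )
                    out.append(NucleusInstance(0, poly, (cx, cy), poly.area))
    return _renumber(out)


def _renumber(instances: list[NucleusInstance]) -> list[NucleusInstance]:
    for i, inst in enumerate(instances, start=1):
        inst.id = i
    return instances


def filter_nuclei_by_area(
    nuclei: list[NucleusInstance],
    area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE,
) -> list[NucleusInstance]:
    """Strict open-interval retention: keep min < area < max; order and ids
    preserved.  Applying the filter twice equals applying it once."""
    lo, hi = area_range_um2
    return [n for n in nuclei if lo < n.area_um2 < hi]


class NucleiSegmenter:
    """sklearn-style wrapper: ``predict(image)`` returns area-filtered
    nucleus instances; the unfiltered set is kept on ``raw_instances_``.

    The area filter applies after merging tiled-inference blocks.
    """

    def __init__(
        self,
        backend: str = "fallback",
        um_per_px: float = 0.5,
        nucleus_diameter_um: float = 10.0,
        prob_thresh: float = 0.2,
        n_tiles: tuple[int, int] | None = None,
        context: int = 128,
        area_range_um2: tuple[float, float] = DEFAULT_AREA_RANGE,
        seed: int = 0,
    ):
        self.backend = backend
        self.um_per_px = um_per_px
        self.nucleus_diameter_um = nucleus_diameter_um
        self.prob_thresh = prob_thresh
        self.n_tiles = n_tiles
        self.context = context
        self.area_range_um2 = area_range_um2
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "backend",
                "um_per_px",
                "nucleus_diameter_um",
                "prob_thresh",
                "n_tiles",
                "context",
                "area_range_um2",
                "seed",
            )
        }

    def set_params(self, **params) -> "NucleiSegmenter":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "NucleiSegmenter":
        return self

    def predict(self, image: np.ndarray) -> list[NucleusInstance]:
        scale = ImageScale(self.um_per_px, self.nucleus_diameter_um)
        params = SegmentationParams(
            backend=self.backend,
            prob_thresh=self.prob_thresh,
            n_tiles=self.n_tiles,
            context=self.context,
            area_range_um2=self.area_range_um2,
        )
        self.raw_instances_ = segment_nuclei(image, scale, params, self.seed)
        return filter_nuclei_by_area(self.raw_instances_, self.area_range_um2)
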