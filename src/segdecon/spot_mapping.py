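"""Geometry layer: spot layouts, nuclei-to-spot assignment, count moments,
HD-bin pseudo-spot aggregation, and HD bin-to-nucleus cell reconstruction.

All geometry is done in physical microns.  Capture spots are modelled as
discs with an effective radius of 45 µm on a 100 µm pitch (non-overlapping);
a nucleus polygon is counted in the disc it overlaps most.  Visium HD bins
(~2 µm) are aggregated into pseudo-spots by an inclusive 27.5 µm radius
search, and reconstructed into per-nucleus expression profiles by
centroid-in-mask assignment with an area-overlap tiebreak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box
from shapely.strtree import STRtree

from .segmentation import NucleusInstance

__all__ = [
    "SpotLayout",
    "SpotCounts",
    "CountMoments",
    "HdBin",
    "NucleusProfile",
    "assign_nuclei_to_spots",
    "count_moments",
    "make_pseudospots",
    "assign_bins_to_nuclei",
    "qc_nuclei_profiles",
]

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_UM = 45.0
DEFAULT_PITCH_UM = 100.0
PSEUDOSPOT_RADIUS_UM = 27.5
QC_AREA_RANGE_UM2 = (50.0, 2000.0)
QC_MIN_TOTAL_UMI = 50


@dataclass
class SpotLayout:
    """Capture-disc geometry: ids, centers (µm), radius and pitch."""

    spot_ids: list
    centers: np.ndarray                    # (n, 2) µm
    effective_radius_um: float = DEFAULT_RADIUS_UM
    pitch_um: float = DEFAULT_PITCH_UM

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if len(self.spot_ids) != len(self.centers):
            raise ValueError("spot_ids and centers must align")

    def discs(self) -> list[Polygon]:
        r = self.effective_radius_um
        return [Point(c).buffer(r, quad_segs=64) for c in self.centers]


@dataclass
class SpotCounts:
    spot_ids: list
    n_s: np.ndarray                        # integer nuclei/spot
    unassigned: int = 0
    assignment: dict[int, object] = field(default_factory=dict)

    def __post_init__(self):
        self.n_s = np.asarray(self.n_s)
        if len(self.spot_ids) != len(self.n_s):
            raise ValueError("spot_ids and n_s must align")


@dataclass(frozen=True)
class CountMoments:
    n_bar: float
    sigma2: float
    vmr: float
    n_spots: int


@dataclass
class HdBin:
    center: tuple[float, float]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")


@dataclass
class NucleusProfile:
    nucleus_id: int
    counts: np.ndarray
    total_counts: float
    centroid: tuple[float, float]
    area_um2: float


# ---------------------------------------------------------------------------
# Nuclei -> spots
# ---------------------------------------------------------------------------

def assign_nuclei_to_spots(
    nuclei: list[NucleusInstance], layout: SpotLayout
) -> SpotCounts:
    """Count each nucleus in the spot disc it overlaps.

    A nucleus is counted in a spot iff its polygon intersects the disc with
    positive area; among several candidate discs the one with the larger
    overlap fraction (intersection area / polygon area) wins, so each nucleus
    contributes to at most one spot.  Nuclei overlapping no disc are logged
    and left unassigned.
    """
    discs = layout.discs()
    tree = STRtree(discs)
    counts = np.zeros(len(discs), dtype=np.int64)
    assignment: dict[int, object] = {}
    unassigned = 0
    for nucleus in nuclei:
        poly = nucleus.polygon
        best, best_frac = None, 0.0
        for idx in sorted(tree.query(poly)):
            inter = poly.intersection(discs[idx]).area
            if inter <= 0:
                continue
            frac = inter / poly.area
            # ties broken toward the nearer spot center, then the lower index
            if frac > best_frac + 1e-12 or (
                abs(frac - best_frac) <= 1e-12
                and best is not None
                and Point(nucleus.centroid).distance(Point(layout.centers[idx]))
                < Point(nucleus.centroid).distance(Point(layout.centers[best]))
            ):
                best, best_frac = idx, frac
        if best is None:
            unassigned += 1
            logger.debug("nucleus %d overlaps no capture disc", nucleus.id)
            continue
        counts[best] += 1
        assignment[nucleus.id] = layout.spot_ids[best]
    if unassigned:
        logger.info("%d nuclei fell outside all capture discs", unassigned)
    return SpotCounts(list(layout.spot_ids), counts, unassigned, assignment)


def count_moments(counts: SpotCounts | np.ndarray) -> CountMoments:
    """Mean, unbiased variance (divisor |S|-1) and VMR of per-spot counts."""
    n = counts.n_s if isinstance(counts, SpotCounts) else np.asarray(counts)
    n = n.astype(float)
    if n.size < 2:
        raise ValueError("count moments require at least 2 spots")
    n_bar = float(n.mean())
    sigma2 = float(n.var(ddof=1))
    if n_bar == 0:
        raise ValueError("mean count is zero; VMR is undefined")
    return CountMoments(n_bar, sigma2, sigma2 / n_bar, int(n.size))


# ---------------------------------------------------------------------------
# HD bins -> pseudo-spots
# ---------------------------------------------------------------------------

def make_pseudospots(
    bin_centers: np.ndarray,
    bin_counts: np.ndarray,
    spot_centers: np.ndarray,
    radius_um: float = PSEUDOSPOT_RADIUS_UM,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sum raw bin counts into pseudo-spots by an inclusive radius search.

    Returns the spot-by-gene matrix and, per spot, the member bin indices.
    The kd-tree search equals the brute-force distance test (boundary
    inclusive, <=).
    """
    bin_centers = np.asarray(bin_centers, dtype=float)
    bin_counts = np.asarray(bin_counts)
    spot_centers = np.asarray(spot_centers, dtype=float)
    tree = cKDTree(bin_centers)
    members = [
        np.asarray(sorted(idx), dtype=int)
        for idx in tree.query_ball_point(spot_centers, r=radius_um)
    ]
    out = np.zeros((len(spot_centers), bin_counts.shape[1]), dtype=bin_counts.dtype)
    for i, idx in enumerate(members):
        if idx.size:
            out[i] = bin_counts[idx].sum(axis=0)
    return out, members


# ---------------------------------------------------------------------------
# HD bins -> nuclei
# ---------------------------------------------------------------------------

def assign_bins_to_nuclei(
    bins: list[HdBin],
    nuclei: list[NucleusInstance],
    bin_size_um: float = 2.0,
) -> list[NucleusProfile]:
    """Reconstruct per-nucleus expression by summing assigned bins.

    A bin goes to the nucleus whose mask strictly contains its centroid;
    boundary or multiply-claimed centroids are resolved by the larger area
    overlap between the bin's square footprint and the candidate masks.
    Unassigned bins are dropped.
    """
    if not nuclei:
        return []
    polys = [n.polygon for n in nuclei]
    tree = STRtree(polys)
    half = bin_size_um / 2.0
    sums: dict[int, np.ndarray] = {}
    for b in bins:
        pt = Point(b.center)
        cand = sorted(tree.query(pt, predicate="intersects"))
        strict = [i for i in cand if polys[i].contains(pt)]
        if len(strict) == 1:
            winner = strict[0]
        else:
            pool = strict if strict else cand
            if not pool:
                continue
            foot = box(
                b.center[0] - half, b.center[1] - half,
                b.center[0] + half, b.center[1] + half,
            )
            overlaps = [(polys[i].intersection(foot).area, -i) for i in pool]
            area, neg = max(overlaps)
            if area <= 0:
                continue
            winner = -neg
        if winner in sums:
            sums[winner] = sums[winner] + np.asarray(b.counts)
        else:
            sums[winner] = np.asarray(b.counts).copy()
    profiles = []
    for i, n in enumerate(nuclei):
        if i in sums:
            c = sums[i]
            profiles.append(
                NucleusProfile(n.id, c, float(c.sum()), n.centroid, n.area_um2)
            )
    return profiles


def qc_nuclei_profiles(
    profiles: list[NucleusProfile],
    area_range_um2: tuple[float, float] = QC_AREA_RANGE_UM2,
    min_total_umi: float = QC_MIN_TOTAL_UMI,
) -> list[NucleusProfile]:
    """Sequential QC: strict area window first, then total UMI > threshold.

    Both bounds are strict: area must satisfy lo < area < hi, and totals must
    exceed ``min_total_umi`` (a total equal to the threshold is removed).
    """
    lo, hi = area_range_um2
    kept = [p for p in profiles if lo < p.area_um2 < hi]
    return [p for p in kept if p.total_counts > min_total_umi]
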