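"""Artifact-severity scoring and the counting-accuracy evaluation suite.

A benchmarking ROI (default 3000x3000 px) is partitioned into a 6x6 grid of
500x500 px tiles.  Each tile receives an H&E Artifact Severity Score (HASS)
combining five interpretable terms derived from the hue-based artifact mask:

* ``speckle_area_fraction`` — artifact pixels / tissue pixels;
* ``p95_component_size_norm`` — 95th percentile of artifact connected-component
  areas, normalized by the tile area;
* ``edge_overlap_index`` — fraction of artifact-boundary pixels overlapping
  (dilated) V-channel Canny edges;
* ``blue_nuclei_proximity`` — fraction of artifact pixels within two nucleus
  diameters of the nuclei mask;
* ``texture_drop`` — relative loss of local V-channel variance inside the
  artifact versus the surrounding tissue.

Raw terms are min-max normalized within the slide, averaged without weights
into a composite in [0, 1], and binned into five noise levels by within-slide
quintiles (1-5; higher = worse; equal scores share the lower level).

Counting accuracy against manual ground truth uses ME/MAE/RMSE, Bland-Altman
bias with 95 % limits of agreement, paired Wilcoxon tests with Holm
adjustment, and a noise-level significance threshold L* from Mann-Whitney U
comparisons of error shifts above/below each level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage import feature as skfeature
from skimage import morphology as skmorph
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TileGrid",
    "HassTile",
    "CountEval",
    "tile_roi",
    "hass_terms",
    "score_slide",
    "stratify_hass",
    "counting_errors",
    "bland_altman",
    "paired_wilcoxon_holm",
    "significance_threshold",
]

logger = logging.getLogger(__name__)

HASS_TERM_NAMES = (
    "speckle_area_fraction",
    "p95_component_size_norm",
    "edge_overlap_index",
    "blue_nuclei_proximity",
    "texture_drop",
)


@dataclass(frozen=True)
class TileGrid:
    """Disjoint, exhaustive tiling of a square ROI."""

    roi_origin: tuple[float, float] = (0.0, 0.0)
    roi_size: int = 3000
    grid: int = 6
    tile_size: int = 500

    def __post_init__(self):
        if self.grid * self.tile_size != self.roi_size:
            raise ValueError("grid * tile_size must equal roi_size")

    @property
    def n_tiles(self) -> int:
        return self.grid * self.grid

    def tile_ids(self) -> list[tuple[int, int]]:
        return [(r, c) for r in range(self.grid) for c in range(self.grid)]


@dataclass
class HassTile:
    tile_id: tuple[int, int]
    terms: dict[str, float]
    score: float = np.nan
    level: int = 0


@dataclass
class CountEval:
    pred: np.ndarray
    gt: np.ndarray
    me: float
    mae: float
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    p_raw: np.ndarray | None = None
    p_holm: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------

def tile_roi(grid: TileGrid, points: np.ndarray) -> dict[tuple[int, int], int]:
    """Per-tile point counts under half-open intervals [x0, x0 + tile).

    Points outside the ROI are dropped with a log message.
    """
    counts = {tid: 0 for tid in grid.tile_ids()}
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ox, oy = grid.roi_origin
    dropped = 0
    for x, y in pts:
        col = int(np.floor((x - ox) / grid.tile_size))
        row = int(np.floor((y - oy) / grid.tile_size))
        if 0 <= row < grid.grid and 0 <= col < grid.grid:
            counts[(row, col)] += 1
        else:
            dropped += 1
    if dropped:
        logger.info("%d points fell outside the ROI", dropped)
    return counts


# ---------------------------------------------------------------------------
# HASS
# ---------------------------------------------------------------------------

def hass_terms(
    v_channel: np.ndarray,
    artifact: np.ndarray,
    nuclei_mask: np.ndarray,
    tissue: np.ndarray | None = None,
    nucleus_diameter_px: float = 20.0,
) -> dict[str, float]:
    """Raw (unnormalized) five-term artifact severity of one tile.

    All terms are bounded in [0, 1]; an empty-tissue tile scores 0 on every
    term.
    """
    artifact = artifact.astype(bool)
    nuclei_mask = nuclei_mask.astype(bool)
    tissue = np.ones_like(artifact) if tissue is None else tissue.astype(bool)
    tile_area = artifact.size
    n_tissue = int(tissue.sum())
    zero = {name: 0.0 for name in HASS_TERM_NAMES}
    if n_tissue == 0:
        return zero

    speckle_frac = artifact.sum() / n_tissue

    labels, n_comp = ndi.label(artifact)
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]
        p95 = float(np.percentile(sizes, 95)) / tile_area
    else:
        p95 = 0.0

    if artifact.any():
        boundary = artifact & ~skmorph.erosion(artifact)
        edges = skfeature.canny(v_channel.astype(float))
        edges = skmorph.dilation(edges, skmorph.disk(1))
        edge_overlap = (boundary & edges).sum() / max(boundary.sum(), 1)
    else:
        edge_overlap = 0.0

    if artifact.any() and nuclei_mask.any():
        dist = ndi.distance_transform_edt(~nuclei_mask)
        near = dist <= 2.0 * nucleus_diameter_px
        proximity = (artifact & near).sum() / artifact.sum()
    else:
        proximity = 0.0

    ref = tissue & ~artifact
    if artifact.any() and ref.any():
        var_art = float(np.var(v_channel[artifact]))
        var_tis = float(np.var(v_channel[ref]))
        texture_drop = float(np.clip(1.0 - var_art / max(var_tis, 1e-12), 0.0, 1.0))
    else:
        texture_drop = 0.0

    return {
        "speckle_area_fraction": float(min(speckle_frac, 1.0)),
        "p95_component_size_norm": float(min(p95, 1.0)),
        "edge_overlap_index": float(edge_overlap),
        "blue_nuclei_proximity": float(proximity),
        "texture_drop": texture_drop,
    }


def score_slide(tiles: list[HassTile]) -> list[HassTile]:
    """Within-slide min-max normalization of each term, unweighted composite,
    then quintile stratification into levels 1-5."""
    raw = np.array([[t.terms[n] for n in HASS_TERM_NAMES] for t in tiles], float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    rng = hi - lo
    norm = np.where(rng > 0, (raw - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    scores = norm.mean(axis=1)
    # quintile levels need at least 5 tiles; smaller slides keep level 0
    levels = stratify_hass(scores) if len(tiles) >= 5 else np.zeros(len(tiles), int)
    for t, sc, lv in zip(tiles, scores, levels):
        t.score = float(sc)
        t.level = int(lv)
    return tiles


def stratify_hass(scores: np.ndarray) -> np.ndarray:
    """Quintile levels 1-5 from the empirical score distribution.

    Boundaries are the 20/40/60/80 linear-interpolation percentiles; a score
    on a boundary (and any tie of equal scores) takes the lower level, so an
    all-equal slide is entirely level 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 5:
        raise ValueError("quintile stratification requires at least 5 tiles")
    qs = np.percentile(scores, [20, 40, 60, 80])
    levels = 1 + (scores[:, None] > qs[None, :]).sum(axis=1)
    return levels.astype(int)


# ---------------------------------------------------------------------------
# Counting metrics
# ---------------------------------------------------------------------------

def counting_errors(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """ME, MAE and RMSE of per-tile counts (nuclei/tile)."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must align")
    d = pred - gt
    return float(d.mean()), float(np.abs(d).mean()), float(np.sqrt((d**2).mean()))


def bland_altman(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """Mean bias and 95 % limits of agreement: bias +/- 1.96 * sd(d), with the
    unbiased (ddof=1) standard deviation of the paired differences."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt must align")
    if pred.size < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    d = pred - gt
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.all(d == 0):
        logger.info("all paired differences are zero; p = 1 by convention")
        return 1.0
    n_nonzero = int((d != 0).sum())
    method = "exact" if n_nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue)


def paired_wilcoxon_holm(
    errors_a: np.ndarray,
    errors_b: np.ndarray,
    strata: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Two-sided paired Wilcoxon per comparison (one per stratum when given),
    Holm step-down across the family.

    Returns (raw p, Holm-adjusted p, stratum labels).  Uses the exact signed-
    rank distribution for n <= 25 non-zero pairs, the continuity-corrected
    normal approximation otherwise; all-zero differences give p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    if strata is None:
        labels = ["all"]
        raws = [_wilcoxon_p(a, b)]
    else:
        strata = np.asarray(strata)
        labels = sorted(set(strata.tolist()))
        raws = [_wilcoxon_p(a[strata == s], b[strata == s]) for s in labels]
    _, p_holm, _, _ = multipletests(raws, method="holm")
    return np.asarray(raws), np.asarray(p_holm), labels


def significance_threshold(
    delta_err: np.ndarray,
    levels: np.ndarray,
    alpha: float = 0.05,
) -> int | None:
    """Smallest noise level L* at which the error shift splits significantly.

    For each L in 2..5 with both sides nonempty, a two-sided Mann-Whitney U
    compares delta-|err| in tiles with level >= L versus < L; L* is the
    smallest L with p < alpha, or None.
    """
    delta_err = np.asarray(delta_err, dtype=float)
    levels = np.asarray(levels)
    for L in (2, 3, 4, 5):
        hi = delta_err[levels >= L]
        lo = delta_err[levels < L]
        if hi.size == 0 or lo.size == 0:
            continue
        if np.ptp(np.concatenate([hi, lo])) == 0:
            continue
        p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
        if p < alpha:
            return L
    return None


def evaluate_counts(
    pred: np.ndarray, gt: np.ndarray, strata: np.ndarray | None = None
) -> CountEval:
    """Bundle ME/MAE/RMSE and Bland-Altman agreement into one record."""
    me, mae, rmse = counting_errors(pred, gt)
    bias, lo, hi = bland_altman(pred, gt)
    ev = CountEval(np.asarray(pred), np.asarray(gt), me, mae, rmse, bias, lo, hi)
    if strata is not None:
        ev.p_raw, ev.p_holm, _ = paired_wilcoxon_holm(pred, gt, strata)
    return ev
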