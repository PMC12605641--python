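"""Shared numeric helpers: circular hue statistics, seed streams, unit conversion."""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi

# Stable stream ids so each generator draws from an independent,
# counter-addressable substream of one root seed.
STREAM_HNE = 1
STREAM_ST = 2
STREAM_HD = 3
STREAM_SEG = 4
STREAM_VI = 5


def rng_stream(seed: int, stream: int) -> np.random.Generator:
    """Counter-based child stream: same root seed, independent per stream id."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),))
    return np.random.Generator(np.random.Philox(ss))


def circular_mean(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of angles in radians, result in [0, 2*pi)."""
    a = np.asarray(angles, dtype=float)
    if weights is None:
        s, c = np.sin(a).sum(), np.cos(a).sum()
    else:
        w = np.asarray(weights, dtype=float)
        s, c = (w * np.sin(a)).sum(), (w * np.cos(a)).sum()
    return float(np.arctan2(s, c) % TWO_PI)


def circular_diff(angles: np.ndarray, center: float) -> np.ndarray:
    """Signed circular deviation in (-pi, pi]."""
    return (np.asarray(angles, dtype=float) - center + np.pi) % TWO_PI - np.pi


def normal_consistent_mad(x: np.ndarray) -> float:
    """Median absolute deviation scaled by 1.4826 (consistent for a normal)."""
    x = np.asarray(x, dtype=float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def um2_to_px(area_um2: float, um_per_px: float) -> int:
    """Physical area cutoff converted to a pixel count (nearest integer)."""
    return int(round(area_um2 / (um_per_px**2)))


def odd_kernel_px(length_um: float, um_per_px: float) -> int:
    """Resolution-aware odd kernel size (>=1) for a physical length."""
    k = int(round(length_um / um_per_px))
    if k % 2 == 0:
        k += 1
    return max(k, 1)
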