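"""Shape histograms of isodose surfaces and their Bray-Curtis comparison.

A shape histogram ``his_x`` bins the distances of the level-``x`` isodose
surface points from the parametrization point; it is the "signature" of the
surface.  The bin count comes from Doane's formula (appropriate for the
skewed distance distributions these surfaces produce)::

    k = ceil(1 + log2(n) + log2(1 + |g1| / sigma_g1)),
    sigma_g1 = sqrt(6 (n - 2) / ((n + 1)(n + 3)))

with ``g1`` the adjusted Fisher-Pearson sample skewness, and a floor of 4
bins.  Two surfaces are compared by binning both distance samples on shared
edges (bin count anchored on the reference sample, span covering the union
of both samples) and evaluating the Bray-Curtis dissimilarity

    BC = sum_i |e_i - r_i| / sum_i (e_i + r_i)   in [0, 1],

0 meaning identical binned shapes and 1 disjoint ones.  By default counts
are first scaled to relative frequencies so unequal sample sizes do not
masquerade as shape difference.  The median of the *raw* (unbinned)
distances travels with each histogram; comparing medians decides whether
the evaluated surface lies farther from ("hotter") or closer to ("cooler")
the isocenter than the reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import DistanceSample

__all__ = [
    "ShapeHistogram",
    "HistogramPair",
    "doane_bin_count",
    "build_histogram",
    "pair_histograms",
    "bray_curtis",
]


@dataclass
class ShapeHistogram:
    """Binned distance distribution of one isodose surface."""

    level: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_points: int
    median_distance: float  # median of the raw, unbinned distances

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry fewer than bin_edges")
        if int(self.counts.sum()) != self.n_points:
            raise ValueError("histogram counts do not sum to the sample size")

    @property
    def frequencies(self) -> np.ndarray:
        """Counts scaled to unit sum."""
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


@dataclass
class HistogramPair:
    """Reference and evaluated histograms binned on identical edges."""

    reference: ShapeHistogram
    evaluated: ShapeHistogram

    def __post_init__(self) -> None:
        if not np.array_equal(self.reference.bin_edges, self.evaluated.bin_edges):
            raise ValueError("paired histograms must share bin edges")

    @property
    def shared_edges(self) -> np.ndarray:
        return self.reference.bin_edges


def _distances_array(distances) -> np.ndarray:
    if isinstance(distances, DistanceSample):
        return np.asarray(distances.distances, dtype=float)
    return np.asarray(distances, dtype=float).ravel()


def doane_bin_count(distances) -> int:
    """Number of histogram bins for a distance sample, by Doane's formula.

    Returns 1 for a zero-variance (degenerate) sample, with a warning;
    otherwise at least 4 bins.  Requires n >= 4.
    """
    d = _distances_array(distances)
    n = d.size
    if n < 4:
        raise ValueError(f"Doane's formula needs at least 4 samples, got {n}")
    if np.ptp(d) == 0 or np.std(d) == 0:
        warnings.warn("zero-variance distance sample: single-bin histogram")
        return 1
    g1 = stats.skew(d, bias=False)
    sigma_g1 = math.sqrt(6.0 * (n - 2) / ((n + 1.0) * (n + 3.0)))
    k = math.ceil(1.0 + math.log2(n) + math.log2(1.0 + abs(g1) / sigma_g1))
    return max(k, 4)


def build_histogram(distances, edges=None) -> ShapeHistogram:
    """Bin a distance sample into a shape histogram.

    With ``edges=None`` the bins are equal-width over the sample range with
    a Doane-derived count; otherwise the provided ascending shared edges
    are used.  The stored median always comes from the raw distances.
    """
    d = _distances_array(distances)
    if d.size == 0:
        raise ValueError("cannot build a histogram from an empty sample")
    level = distances.level if isinstance(distances, DistanceSample) else float("nan")
    if edges is None:
        k = doane_bin_count(d)
        edges = _equal_width_edges(d.min(), d.max(), k)
    else:
        edges = np.asarray(edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be ascending with at least 2 entries")
    counts, _ = np.histogram(d, bins=edges)
    return ShapeHistogram(
        level=level,
        bin_edges=edges,
        counts=counts,
        n_points=int(counts.sum()),
        median_distance=float(np.median(d)),
    )


def _equal_width_edges(lo: float, hi: float, k: int) -> np.ndarray:
    if hi <= lo:  # degenerate sample: one bin of unit width around the value
        return np.array([lo - 0.5, lo + 0.5])
    return np.linspace(lo, hi, k + 1)


def pair_histograms(
    ref_distances: DistanceSample, eval_distances: DistanceSample
) -> HistogramPair:
    """Bin both samples on shared edges anchored to the reference sample.

    The bin count comes from Doane's formula on the reference sample; the
    edge span covers the union range of both samples so every point of
    either sample falls inside a bin.
    """
    ref = _distances_array(ref_distances)
    ev = _distances_array(eval_distances)
    if ref.size == 0 or ev.size == 0:
        raise ValueError("both distance samples must be non-empty")
    k = doane_bin_count(ref)
    lo = min(ref.min(), ev.min())
    hi = max(ref.max(), ev.max())
    edges = _equal_width_edges(lo, hi, k)
    return HistogramPair(
        reference=build_histogram(ref_distances, edges=edges),
        evaluated=build_histogram(eval_distances, edges=edges),
    )


def bray_curtis(pair: HistogramPair, normalize: bool = True) -> float:
    """Bray-Curtis dissimilarity of a histogram pair, in [0, 1].

    With ``normalize=True`` (default) both histograms are first scaled to
    relative frequencies, making the value invariant to sample size; the
    raw-count mode reproduces the count-based comparison directly.
    """
    if normalize:
        r = pair.reference.frequencies
        e = pair.evaluated.frequencies
    else:
        r = pair.reference.counts.astype(float)
        e = pair.evaluated.counts.astype(float)
    denom = float((e + r).sum())
    if denom == 0:
        raise ValueError("cannot compare two all-zero histograms")
    return float(np.abs(e - r).sum() / denom)
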