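"""Doane binning, shape histograms, Bray-Curtis dissimilarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import skew

from isdqa import (
    HistogramPair,
    ShapeHistogram,
    bray_curtis,
    build_histogram,
    doane_bin_count,
    pair_histograms,
)
from isdqa.geometry import DistanceSample


def sample(values, level=50.0):
    values = np.asarray(values, dtype=float)
    return DistanceSample(level=level, distances=values,
                          parametrization_point=np.zeros(3))


class TestDoane:
    def test_symmetric_power_of_two_sample(self):
        # exactly symmetric integer sample: skewness is exactly zero, so
        # k = ceil(1 + log2(1024)) = 11
        x = np.arange(1, 513, dtype=float)
        d = np.concatenate([1000.0 - x, 1000.0 + x])
        assert doane_bin_count(sample(d)) == 11

    def test_degenerate_sample_single_bin(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert doane_bin_count(sample([3.0] * 10)) == 1

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            doane_bin_count(sample([1.0, 2.0, 3.0]))

    def test_skewed_sample_matches_direct_formula(self, rng):
        d = rng.gamma(2.0, 3.0, size=500)  # right-skewed
        n = d.size
        g1 = skew(d, bias=False)
        sigma = math.sqrt(6 * (n - 2) / ((n + 1) * (n + 3)))
        expected = max(
            4, math.ceil(1 + math.log2(n) + math.log2(1 + abs(g1) / sigma))
        )
        assert doane_bin_count(sample(d)) == expected

    def test_floor_of_four_bins(self):
        # n = 4 nearly-symmetric: raw formula gives 3, floor lifts it to 4
        assert doane_bin_count(sample([1.0, 2.0, 3.0, 4.0])) == 4


class TestBuildHistogram:
    def test_fixed_edges_example(self):
        h = build_histogram(sample([1, 1, 3, 3]), edges=[0, 2, 4])
        np.testing.assert_array_equal(h.counts, [2, 2])
        assert h.median_distance == 2.0

    def test_sphere_sample_single_occupied_bin(self):
        with pytest.warns(UserWarning):
            h = build_histogram(sample([7.0] * 64))
        assert h.counts.sum() == 64
        assert (h.counts > 0).sum() == 1
        assert h.median_distance == 7.0
        assert h.bin_edges[0] <= 7.0 <= h.bin_edges[-1]

    def test_counts_conserve_sample_size(self, rng):
        d = rng.uniform(5, 25, size=777)
        h = build_histogram(sample(d))
        assert h.counts.sum() == 777
        assert h.n_points == 777

    def test_non_ascending_edges_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            build_histogram(sample([1, 2, 3, 4]), edges=[0, 2, 1])


class TestPairHistograms:
    def test_identical_samples_identical_histograms(self, rng):
        d = rng.uniform(0, 10, size=300)
        pair = pair_histograms(sample(d), sample(d.copy()))
        np.testing.assert_array_equal(pair.reference.counts,
                                      pair.evaluated.counts)

    def test_shift_preserves_mass_on_shared_edges(self, rng):
        d = rng.uniform(5, 15, size=400)
        pair = pair_histograms(sample(d), sample(d + 1.0))
        assert pair.reference.counts.sum() == 400
        assert pair.evaluated.counts.sum() == 400
        # mass moved right: evaluated mean bin index exceeds reference's
        idx = np.arange(pair.reference.counts.size)
        assert (idx * pair.evaluated.counts).sum() > (
            idx * pair.reference.counts
        ).sum()

    def test_disjoint_ranges_covered_by_shared_edges(self, rng):
        a, b = rng.uniform(0, 5, 200), rng.uniform(20, 30, 200)
        pair = pair_histograms(sample(a), sample(b))
        assert pair.shared_edges[0] <= a.min()
        assert pair.shared_edges[-1] >= b.max()
        assert pair.evaluated.counts.sum() == 200

    def test_mismatched_edges_rejected(self):
        h1 = build_histogram(sample([1, 2, 3, 4]), edges=[0, 2, 4])
        h2 = build_histogram(sample([1, 2, 3, 4]), edges=[0, 3, 5])
        with pytest.raises(ValueError, match="share"):
            HistogramPair(reference=h1, evaluated=h2)


def pair_from_counts(ref_counts, eval_counts):
    edges = np.arange(len(ref_counts) + 1, dtype=float)

    def hist(counts):
        counts = np.asarray(counts)
        d = np.repeat(edges[:-1] + 0.5, counts)
        med = float(np.median(d)) if d.size else 0.0
        return ShapeHistogram(level=50, bin_edges=edges, counts=counts,
                              n_points=int(counts.sum()), median_distance=med)

    return HistogramPair(reference=hist(ref_counts), evaluated=hist(eval_counts))


class TestBrayCurtis:
    def test_identical_histograms_score_zero(self):
        pair = pair_from_counts([4, 2, 6], [4, 2, 6])
        assert bray_curtis(pair) == 0.0
        assert bray_curtis(pair, normalize=False) == 0.0

    def test_disjoint_histograms_score_one(self):
        pair = pair_from_counts([5, 0, 3, 0], [0, 2, 0, 4])
        assert bray_curtis(pair) == 1.0
        assert bray_curtis(pair, normalize=False) == 1.0

    def test_raw_count_example(self):
        pair = pair_from_counts([2, 1, 0], [0, 1, 2])
        assert bray_curtis(pair, normalize=False) == pytest.approx(2.0 / 3.0)

    def test_matches_scipy_on_random_counts(self, rng):
        for _ in range(20):
            a = rng.integers(0, 50, size=8)
            b = rng.integers(0, 50, size=8)
            if a.sum() == 0 or b.sum() == 0:
                continue
            pair = pair_from_counts(a, b)
            assert bray_curtis(pair, normalize=False) == pytest.approx(
                scipy_braycurtis(b.astype(float), a.astype(float))
            )

    def test_symmetry(self, rng):
        a = rng.integers(0, 20, size=6) + 1
        b = rng.integers(0, 20, size=6) + 1
        assert bray_curtis(pair_from_counts(a, b)) == pytest.approx(
            bray_curtis(pair_from_counts(b, a))
        )

    def test_sample_size_invariance_when_normalized(self):
        pair = pair_from_counts([4, 2, 6], [8, 4, 12])  # doubled sample
        assert bray_curtis(pair, normalize=True) == pytest.approx(0.0)
        assert bray_curtis(pair, normalize=False) > 0.0

    def test_all_zero_rejected(self):
        pair = pair_from_counts([0, 0], [0, 0])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(pair)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.lists(st.integers(0, 100), min_size=3, max_size=10),
        b=st.lists(st.integers(0, 100), min_size=3, max_size=10),
    )
    def test_bounded_on_unit_interval(self, a, b):
        n = min(len(a), len(b))
        a, b = np.array(a[:n]), np.array(b[:n])
        if a.sum() == 0 or b.sum() == 0:
            return
        bc = bray_curtis(pair_from_counts(a, b))
        assert 0.0 <= bc <= 1.0
        # zero iff the relative frequencies coincide
        if bc == 0.0:
            np.testing.assert_allclose(a / a.sum(), b / b.sum())

    def test_median_increases_under_radial_shift(self, rng):
        d = rng.uniform(10, 30, size=500)
        assert sample(d + 2.0).median > sample(d).median
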