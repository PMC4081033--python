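"""Anchor-centered extraction, normalization, averaging and sorting."""

import numpy as np
import pandas as pd
import pytest

from nuclattice.aggregate import (
    AnchorSet,
    ProfileMatrix,
    extract_and_average,
    sort_matrix_by_mean,
)
from nuclattice.fixtures import gen_periodic_anchor_track
from nuclattice.seqaff import detrend_fourier_period


def anchors_of(positions, chrom="chr1", strand=None):
    df = pd.DataFrame({"chrom": chrom, "pos": positions})
    if strand is not None:
        df["strand"] = strand
    return AnchorSet(df)


class TestExtractAndAverage:
    def test_constant_track_normalizes_to_one(self):
        track = {"chr1": np.full(20000, 7.0)}
        matrix, avg, dropped = extract_and_average(
            track, anchors_of([3000, 8000, 15000])
        )
        np.testing.assert_allclose(matrix.matrix, 1.0)
        np.testing.assert_allclose(avg, 1.0)
        assert sum(dropped.values()) == 0

    def test_average_leftmost_value_is_exactly_one(self):
        rng = np.random.default_rng(0)
        track = {"chr1": 1 + rng.random(30000)}
        _, avg, _ = extract_and_average(track, anchors_of([5000, 12000, 20000]))
        assert avg[0] == pytest.approx(1.0)

    def test_out_of_bounds_and_zero_leftmost_are_counted(self):
        track = {"chr1": np.ones(10000), "chr2": np.zeros(10000)}
        anchors = AnchorSet(pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr2", "chrX"],
            "pos": [5000, 50, 5000, 5000],  # 50: window exceeds track start
        }))
        matrix, _, dropped = extract_and_average(
            track, anchors, missing_as_zero=False
        )
        # one usable row; the others split across the drop reasons
        assert matrix.matrix.shape[0] == 1
        assert matrix.matrix.shape[0] + sum(dropped.values()) == 4
        assert dropped["zero_leftmost"] == 1
        assert dropped["missing_chrom"] == 1
        assert dropped["out_of_bounds"] == 1

    def test_minus_strand_row_is_reversed(self):
        arr = np.ones(10000)
        arr[5000:] = 2.0  # step up right of the anchor
        track = {"chr1": arr}
        m_plus, _, _ = extract_and_average(track, anchors_of([5000], strand=["+"]),
                                           window=(-100, 100))
        m_minus, _, _ = extract_and_average(track, anchors_of([5000], strand=["-"]),
                                            window=(-100, 100))
        np.testing.assert_allclose(
            m_minus.matrix[0],
            m_plus.matrix[0][::-1] / m_plus.matrix[0][::-1][0],
        )

    def test_strand_naive_mode_ignores_strand(self):
        rng = np.random.default_rng(5)
        track = {"chr1": 1 + rng.random(10000)}
        m1, _, _ = extract_and_average(track, anchors_of([5000], strand=["-"]),
                                       window=(-50, 50), reverse_minus=False)
        m2, _, _ = extract_and_average(track, anchors_of([5000], strand=["+"]),
                                       window=(-50, 50))
        np.testing.assert_allclose(m1.matrix, m2.matrix)

    def test_averaging_commutes_with_anchor_permutation(self):
        rng = np.random.default_rng(9)
        track = {"chr1": 1 + rng.random(50000)}
        pos = [4000, 9000, 17000, 30000, 41000]
        _, avg1, _ = extract_and_average(track, anchors_of(pos))
        _, avg2, _ = extract_and_average(track, anchors_of(pos[::-1]))
        np.testing.assert_allclose(avg1, avg2)

    def test_empty_survivors_raise(self):
        with pytest.raises(ValueError):
            extract_and_average({"chr1": np.zeros(10000)}, anchors_of([5000]))

    def test_recovers_implanted_period_from_jittered_anchors(self):
        track, anchors = gen_periodic_anchor_track(
            n_anchors=30, period=200.0, jitter=5.0, seed=42
        )
        _, avg, _ = extract_and_average(track, AnchorSet(anchors))
        # low polynomial degree: the 3 kb window holds only ~15 cycles
        res = detrend_fourier_period(avg, poly_degree=5)
        assert res.period == pytest.approx(200.0, abs=200**2 / len(avg))


class TestSortMatrixByMean:
    def test_direct_ordering(self):
        pm = ProfileMatrix(
            np.array([[0.2] * 11, [0.9] * 11, [0.5] * 11]), window=(-5, 5)
        )
        out = sort_matrix_by_mean(pm, region=(-5, 5))
        np.testing.assert_array_equal(out.anchor_index, [1, 2, 0])

    def test_idempotent_on_sorted_matrix(self):
        pm = ProfileMatrix(np.array([[3.0] * 5, [2.0] * 5, [1.0] * 5]),
                           window=(-2, 2))
        out = sort_matrix_by_mean(pm, region=(-2, 2))
        np.testing.assert_array_equal(out.matrix, pm.matrix)

    def test_region_clipped_and_means_nonincreasing(self):
        rng = np.random.default_rng(1)
        pm = ProfileMatrix(rng.random((20, 101)), window=(-50, 50))
        out = sort_matrix_by_mean(pm, region=(-2000, 2000))
        means = out.matrix.mean(axis=1)
        assert np.all(np.diff(means) <= 1e-12)
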