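"""Anchor-centered extraction, normalization and averaging of occupancy
tracks (aggregate plots around TSSs, bound-factor peaks, etc.).

Occupancy is read in a fixed window around each anchor (ChIP-seq peak
summit or similar), each row is normalized to 1 at the leftmost window
position, and rows are averaged column-wise.  Anchors without full window
coverage, and rows whose leftmost value is zero, are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (-1500, 1500)


@dataclass(frozen=True)
class AnchorSet:
    """Genomic anchor positions (peak summits), optionally stranded."""

    table: pd.DataFrame  # columns: chrom, pos[, strand]

    def __post_init__(self):
        t = self.table
        if not {"chrom", "pos"}.issubset(t.columns):
            raise ValueError("anchor table needs columns 'chrom' and 'pos'")
        if (t["pos"] < 0).any():
            raise ValueError("anchor positions must be >= 0")
        if "strand" not in t.columns:
            t = t.assign(strand="+")
            object.__setattr__(self, "table", t)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ProfileMatrix:
    """Rows = anchors, columns = window offsets, values = occupancy."""

    matrix: np.ndarray
    window: tuple[int, int]
    anchor_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        lo, hi = self.window
        if self.matrix.shape[1] != hi - lo + 1:
            raise ValueError("matrix width does not match window bounds")
        if self.anchor_index is None:
            self.anchor_index = np.arange(self.matrix.shape[0])

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)


def extract_and_average(
    track: Mapping[str, np.ndarray],
    anchors: AnchorSet,
    window: tuple[int, int] = DEFAULT_WINDOW,
    reverse_minus: bool = True,
    missing_as_zero: bool = True,
):
    """Anchor-centered profile matrix and its column-mean average.

    ``track`` maps chromosome name to a per-bp occupancy array.  Windows on
    minus-strand anchors are reversed before normalization when
    ``reverse_minus`` (so "leftmost" is upstream-most in gene orientation).
    Each surviving row is normalized to 1 at its leftmost position; rows
    whose leftmost value is 0 are dropped.  Returns
    ``(ProfileMatrix, average, dropped)`` where ``dropped`` counts anchors
    removed for missing coverage or zero normalizer.
    """
    lo, hi = int(window[0]), int(window[1])
    if hi <= lo:
        raise ValueError("window must satisfy hi > lo")
    rows, kept_idx = [], []
    dropped = {"out_of_bounds": 0, "zero_leftmost": 0, "missing_chrom": 0}
    for i, rec in enumerate(anchors.table.itertuples(index=False)):
        arr = track.get(rec.chrom)
        if arr is None:
            dropped["missing_chrom"] += 1
            continue
        a, b = rec.pos + lo, rec.pos + hi + 1
        if a < 0 or b > len(arr):
            if missing_as_zero and not (b <= 0 or a >= len(arr)):
                row = np.zeros(hi - lo + 1)
                sl = arr[max(a, 0) : min(b, len(arr))]
                row[max(a, 0) - a : max(a, 0) - a + len(sl)] = sl
                log.warning("window for anchor %d partially outside track; "
                            "missing values treated as 0", i)
            else:
                dropped["out_of_bounds"] += 1
                continue
        else:
            row = np.asarray(arr[a:b], dtype=float)
        if reverse_minus and getattr(rec, "strand", "+") == "-":
            row = row[::-1]
        if row[0] == 0.0:
            dropped["zero_leftmost"] += 1
            continue
        rows.append(row / row[0])
        kept_idx.append(i)
    if not rows:
        raise ValueError("no anchors with usable window coverage")
    matrix = ProfileMatrix(np.vstack(rows), (lo, hi), np.asarray(kept_idx))
    average = matrix.matrix.mean(axis=0)
    return matrix, average, dropped


def sort_matrix_by_mean(
    matrix: ProfileMatrix, region: tuple[int, int] = (-2000, 2000)
) -> ProfileMatrix:
    """Rows reordered by descending mean occupancy over ``region``.

    The region is clipped to the matrix window; the sort is stable, so an
    already-sorted matrix is returned unchanged.
    """
    lo, hi = matrix.window
    a = max(region[0], lo) - lo
    b = min(region[1], hi) - lo + 1
    if b <= a:
        raise ValueError("sort region does not overlap the matrix window")
    means = matrix.matrix[:, a:b].mean(axis=1)
    order = np.argsort(-means, kind="stable")
    return ProfileMatrix(matrix.matrix[order], matrix.window, matrix.anchor_index[order])
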