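"""Comparing haplotypes to an ancestral haplotype.

Every row of the matrix is compared to a reference (ancestral)
haplotype: the maximal contiguous run of matching markers through the
start marker is that row's *shared segment*, whose breakpoints feed the
MRCA estimator.  Per sample, the haplotype sharing the longer segment is
taken to be the carrier haplotype; long matching runs re-appearing
*beyond* a breakpoint are reported as suspected switch or genotyping
errors (never auto-corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import Haplotype, HaplotypeMatrix

__all__ = [
    "SharedSegment",
    "ComparisonMatrix",
    "SwitchErrorFlag",
    "match_vector",
    "shared_segment",
    "comparison_matrix",
    "select_carrier_haplotypes",
    "flag_switch_errors",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_RUN = 20


@dataclass
class SharedSegment:
    """One row's contiguous sharing with the ancestral haplotype.

    ``left_break``/``right_break`` are the bp positions of the nearest
    mismatching marker on each side of the start marker, or the
    ancestral range end when the run reaches it (then the side is
    *censored*: the true segment extends beyond the data).  ``n_markers``
    counts the contiguous matching markers through the start marker and
    is 0 iff the row mismatches at the start marker itself.
    """

    row_idx: int
    left_break: int
    right_break: int
    n_markers: int
    censored_left: bool = False
    censored_right: bool = False
    cM_left: float | None = None
    cM_right: float | None = None

    @property
    def bp_len(self) -> int:
        return self.right_break - self.left_break


@dataclass
class ComparisonMatrix:
    """Per-row match/mismatch vectors vs the ancestral haplotype.

    Rows are sorted by downstream (left-side) contiguous sharing,
    descending; ties break on right-side sharing, then row index.
    ``longer_per_sample`` marks, for diploid input, the row of each
    sample with the larger shared segment.
    """

    matches: np.ndarray  # (n_rows, n_ancestral_markers) bool, in sorted order
    row_order: np.ndarray  # original row indices, sorted
    segments: list[SharedSegment]  # in original row order
    longer_per_sample: np.ndarray  # bool per original row
    start_col: int  # column of the start marker within the ancestral range


def _ancestral_columns(
    matrix: HaplotypeMatrix, ancestral: Haplotype, start_idx: int
) -> tuple[np.ndarray, int]:
    """Marker columns of the ancestral within the matrix + start offset."""
    if len(ancestral) == 0:
        raise ValueError("ancestral haplotype is empty")
    if ancestral.marker_indices is not None:
        cols = ancestral.marker_indices
    else:
        pos_to_col = {v.pos: j for j, v in enumerate(matrix.variants)}
        try:
            cols = np.array([pos_to_col[v.pos] for v in ancestral.variants])
        except KeyError as e:
            raise ValueError(f"ancestral marker at position {e} absent from matrix")
    offset = np.flatnonzero(cols == start_idx)
    if not offset.size:
        raise ValueError(
            f"start marker index {start_idx} outside the ancestral haplotype range"
        )
    return cols.astype(np.int64), int(offset[0])


def match_vector(
    matrix: HaplotypeMatrix, row_idx: int, ancestral: Haplotype
) -> np.ndarray:
    """Boolean match/mismatch of one row against the ancestral markers."""
    if ancestral.marker_indices is not None:
        cols = ancestral.marker_indices
    else:
        pos_to_col = {v.pos: j for j, v in enumerate(matrix.variants)}
        cols = np.array([pos_to_col[v.pos] for v in ancestral.variants])
    return matrix.data[row_idx, cols] == ancestral.alleles


def _run_bounds(m: np.ndarray, start_col: int) -> tuple[int, int]:
    """Half-open [lo, hi) bounds of the contiguous True run through start_col;
    (start_col, start_col) when m[start_col] is False."""
    if not m[start_col]:
        return start_col, start_col
    lo = start_col
    while lo > 0 and m[lo - 1]:
        lo -= 1
    hi = start_col + 1
    while hi < m.size and m[hi]:
        hi += 1
    return lo, hi


def shared_segment(
    matrix: HaplotypeMatrix,
    row_idx: int,
    ancestral: Haplotype,
    start_idx: int,
) -> SharedSegment:
    """Maximal contiguous ancestral-matching run through the start marker."""
    cols, start_col = _ancestral_columns(matrix, ancestral, start_idx)
    m = matrix.data[row_idx, cols] == ancestral.alleles
    positions = ancestral.positions
    start_pos = int(positions[start_col])
    lo, hi = _run_bounds(m, start_col)
    if lo == hi:  # mismatch at the start marker itself
        return SharedSegment(
            row_idx=row_idx,
            left_break=start_pos,
            right_break=start_pos,
            n_markers=0,
        )
    censored_left = lo == 0
    censored_right = hi == m.size
    left_break = int(positions[0] if censored_left else positions[lo - 1])
    right_break = int(positions[-1] if censored_right else positions[hi])
    return SharedSegment(
        row_idx=row_idx,
        left_break=left_break,
        right_break=right_break,
        n_markers=int(hi - lo),
        censored_left=censored_left,
        censored_right=censored_right,
    )


def _side_sharing(m: np.ndarray, start_col: int) -> tuple[int, int]:
    """(left, right) contiguous matching marker counts, start marker included
    on both sides."""
    lo, hi = _run_bounds(m, start_col)
    if lo == hi:
        return 0, 0
    return start_col - lo + 1, hi - start_col


def comparison_matrix(
    matrix: HaplotypeMatrix, ancestral: Haplotype, start_idx: int
) -> ComparisonMatrix:
    """Compare every row to the ancestral haplotype and sort for display."""
    cols, start_col = _ancestral_columns(matrix, ancestral, start_idx)
    matches = matrix.data[:, cols] == ancestral.alleles[None, :]
    segments = [
        shared_segment(matrix, r, ancestral, start_idx)
        for r in range(matrix.n_haplotypes)
    ]
    keys = []
    for r in range(matrix.n_haplotypes):
        left, right = _side_sharing(matches[r], start_col)
        keys.append((-left, -right, r))
    order = np.array([r for _, _, r in sorted(keys)], dtype=np.int64)

    longer = np.zeros(matrix.n_haplotypes, dtype=bool)
    if matrix.ploidy == 2:
        for s in range(matrix.n_samples):
            r1, r2 = 2 * s, 2 * s + 1
            longer[_pick_longer(segments[r1], segments[r2])] = True
    else:
        longer[:] = True
    return ComparisonMatrix(
        matches=matches[order],
        row_order=order,
        segments=segments,
        longer_per_sample=longer,
        start_col=start_col,
    )


def _pick_longer(seg1: SharedSegment, seg2: SharedSegment) -> int:
    """Row index of the longer-sharing segment; ties fall to the lower row."""
    if seg1.n_markers != seg2.n_markers:
        return seg1.row_idx if seg1.n_markers > seg2.n_markers else seg2.row_idx
    if seg1.bp_len != seg2.bp_len:
        return seg1.row_idx if seg1.bp_len > seg2.bp_len else seg2.row_idx
    logger.warning(
        "rows %d and %d share equally long segments; keeping row %d",
        seg1.row_idx, seg2.row_idx, seg1.row_idx,
    )
    return seg1.row_idx


def select_carrier_haplotypes(
    matrix: HaplotypeMatrix, ancestral: Haplotype, start_idx: int
) -> HaplotypeMatrix:
    """Keep, per sample, the haplotype sharing the longer ancestral segment.

    Output has one row per sample (ploidy 1) in the input sample order;
    equal sharing keeps the first haplotype with a logged warning.
    """
    if matrix.ploidy != 2:
        raise ValueError("carrier selection requires diploid input (ploidy 2)")
    kept_rows = []
    for s in range(matrix.n_samples):
        seg1 = shared_segment(matrix, 2 * s, ancestral, start_idx)
        seg2 = shared_segment(matrix, 2 * s + 1, ancestral, start_idx)
        kept_rows.append(_pick_longer(seg1, seg2))
    return matrix.subset_rows(kept_rows, matrix.sample_ids, ploidy=1)


@dataclass
class SwitchErrorFlag:
    """A suspiciously long ancestral-matching run beyond a breakpoint."""

    row_idx: int
    side: str  # "left" | "right"
    start_pos: int
    end_pos: int
    n_markers: int


def flag_switch_errors(
    matrix: HaplotypeMatrix,
    ancestral: Haplotype,
    start_idx: int,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[SwitchErrorFlag]:
    """Report maximal matching runs of >= min_run markers beyond breakpoints.

    After a haplotype has separated from the ancestral haplotype, long
    runs of renewed agreement are most likely switch or genotyping
    errors; they are reported with side and coordinates, never corrected.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    cols, start_col = _ancestral_columns(matrix, ancestral, start_idx)
    positions = ancestral.positions
    flags: list[SwitchErrorFlag] = []
    for r in range(matrix.n_haplotypes):
        m = matrix.data[r, cols] == ancestral.alleles
        lo, hi = _run_bounds(m, start_col)
        if lo == hi:  # mismatch at start: everything else is "beyond"
            regions = (("left", 0, start_col), ("right", start_col + 1, m.size))
        else:
            # lo-1 and hi are the mismatching breakpoint markers themselves
            regions = (("left", 0, max(lo - 1, 0)), ("right", min(hi + 1, m.size), m.size))
        for side, a, b in regions:
            i = a
            while i < b:
                if m[i]:
                    j = i
                    while j < b and m[j]:
                        j += 1
                    if j - i >= min_run:
                        flags.append(
                            SwitchErrorFlag(
                                row_idx=r,
                                side=side,
                                start_pos=int(positions[i]),
                                end_pos=int(positions[j - 1]),
                                n_markers=int(j - i),
                            )
                        )
                    i = j
                else:
                    i += 1
    return flags
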