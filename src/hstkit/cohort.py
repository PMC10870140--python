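"""Cross-cohort analyses: sharing with a foreign ancestral haplotype,
concordance with a published tree, and repeat-class grouping.

Cohorts genotyped on different arrays share only part of their markers,
so every comparison starts from a marker intersection on (contig, pos,
ref, alt).  Records whose ref/alt are swapped between datasets are
rescued by inverting allele codes (and strand flips by complementing);
strand-ambiguous A/T and C/G markers cannot be harmonized and are
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .compare import SharedSegment, shared_segment
from .datatypes import Haplotype, HaplotypeMatrix, VariantInfo
from .hst import Hst
from .mrca import MrcaEstimate, estimate_mrca, segment_genetic_lengths

__all__ = [
    "DEFAULT_REPEAT_BINS",
    "RepeatAnnotation",
    "NodeConcordance",
    "CohortComparison",
    "intersect_markers",
    "cohort_to_haplotype",
    "cohort_to_hst",
    "group_sharing",
    "read_repeat_annotation",
]

logger = logging.getLogger(__name__)

#: repeat-class bins (inclusive): non-expanded alleles start at 2 repeats
DEFAULT_REPEAT_BINS = ((2, 6), (7, 9), (10, 14), (15, 19), (20, 45))

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def intersect_markers(
    variants_a: Sequence[VariantInfo],
    variants_b: Sequence[VariantInfo],
    drop_ambiguous: bool = True,
) -> list[tuple[int, int, bool]]:
    """Match two marker panels on (contig, pos) with allele harmonization.

    Returns (index_a, index_b, flip) triples; ``flip`` means dataset b's
    allele codes must be inverted to mean the same thing as dataset a's.
    Strand flips are rescued via reverse complement; A/T and C/G markers
    are dropped when ``drop_ambiguous`` (their strand cannot be decided).
    """
    by_locus = {(v.contig, v.pos): (i, v) for i, v in enumerate(variants_a)}
    out: list[tuple[int, int, bool]] = []
    for j, vb in enumerate(variants_b):
        hit = by_locus.get((vb.contig, vb.pos))
        if hit is None:
            continue
        i, va = hit
        if drop_ambiguous and (va.is_strand_ambiguous or vb.is_strand_ambiguous):
            continue
        if (va.ref, va.alt) == (vb.ref, vb.alt):
            out.append((i, j, False))
        elif (va.ref, va.alt) == (vb.alt, vb.ref):
            out.append((i, j, True))
        elif (va.ref, va.alt) == (_revcomp(vb.ref), _revcomp(vb.alt)):
            out.append((i, j, False))
        elif (va.ref, va.alt) == (_revcomp(vb.alt), _revcomp(vb.ref)):
            out.append((i, j, True))
        # otherwise alleles are irreconcilable; skip the marker
    return out


@dataclass
class CohortComparison:
    """Per-row sharing of a query cohort with a foreign ancestral haplotype."""

    segments: list[SharedSegment]
    n_common_markers: int
    start_col: int  # matrix column used as the focal marker
    summary: dict[str, float] = field(default_factory=dict)


def cohort_to_haplotype(
    matrix: HaplotypeMatrix,
    ancestral: Haplotype,
    start_idx: int,
    drop_ambiguous: bool = True,
) -> CohortComparison:
    """Shared segments of every query row with an ancestral haplotype from
    another dataset, computed on the marker intersection.

    ``start_idx`` is the focal marker column of the query matrix; if it
    is not part of the intersection the nearest intersected marker (ties
    upstream) is used and recorded in the result.
    """
    pairs = intersect_markers(
        ancestral.variants, matrix.variants, drop_ambiguous=drop_ambiguous
    )
    if not pairs:
        raise ValueError("no markers in common between ancestral haplotype and cohort")
    cols = np.array([j for _, j, _ in pairs], dtype=np.int64)
    alleles = np.array(
        [int(ancestral.alleles[i]) ^ int(flip) for i, _, flip in pairs],
        dtype=np.uint8,
    )
    order = np.argsort(cols)
    cols, alleles = cols[order], alleles[order]

    if start_idx not in cols:
        target_pos = matrix.variants[start_idx].pos
        dist = np.abs(matrix.positions[cols].astype(np.int64) - target_pos)
        start_col = int(cols[int(np.argmin(dist))])
        logger.warning(
            "focal marker %d not in the %d-marker intersection; using column %d",
            start_idx, cols.size, start_col,
        )
    else:
        start_col = int(start_idx)

    restricted = Haplotype(
        variants=[matrix.variants[c] for c in cols],
        alleles=alleles,
        marker_indices=cols,
    )
    segments = [
        shared_segment(matrix, r, restricted, start_col)
        for r in range(matrix.n_haplotypes)
    ]
    markers = np.array([s.n_markers for s in segments], dtype=np.float64)
    mb = np.array([s.bp_len for s in segments], dtype=np.float64) / 1e6
    summary = {
        "mean_markers": float(markers.mean()),
        "median_markers": float(np.median(markers)),
        "min_markers": float(markers.min()),
        "max_markers": float(markers.max()),
        "mean_mb": float(mb.mean()),
        "median_mb": float(np.median(mb)),
        "min_mb": float(mb.min()),
        "max_mb": float(mb.max()),
    }
    return CohortComparison(
        segments=segments,
        n_common_markers=int(cols.size),
        start_col=start_col,
        summary=summary,
    )


@dataclass
class NodeConcordance:
    """Per-node counts of query haplotypes consistent with the node haplotype."""

    node_id: int
    node_n: int
    count: int
    proportion: float
    applicable: bool = True  # False for the root (it has no haplotype)
    uninformative: bool = False  # restricted haplotype empty: vacuous match


def cohort_to_hst(
    hst: Hst,
    matrix: HaplotypeMatrix,
    drop_ambiguous: bool = True,
) -> list[NodeConcordance]:
    """For every tree node, how many query rows carry its haplotype.

    Node haplotypes are restricted to the markers the query shares with
    the tree; a query row counts toward a node when it matches every
    restricted allele.  Sibling nodes whose restricted haplotypes
    coincide (their differentiating markers are absent from the query)
    count the same rows.  The root has no haplotype and is reported as
    not applicable.
    """
    pairs = intersect_markers(hst.variants, matrix.variants, drop_ambiguous=drop_ambiguous)
    if not pairs:
        raise ValueError("no markers in common between HST and cohort")
    col_of: dict[int, tuple[int, bool]] = {i: (j, flip) for i, j, flip in pairs}
    n_query = matrix.n_haplotypes
    out: list[NodeConcordance] = []
    for node in hst.walk():
        if node.id == hst.root_id:
            out.append(
                NodeConcordance(node.id, node.n, n_query, 1.0, applicable=False)
            )
            continue
        cols, expected = [], []
        for marker, allele in node.haplotype:
            hit = col_of.get(marker)
            if hit is None:
                continue
            j, flip = hit
            cols.append(j)
            expected.append(allele ^ int(flip))
        if not cols:
            out.append(
                NodeConcordance(node.id, node.n, n_query, 1.0, uninformative=True)
            )
            continue
        sub = matrix.data[:, np.array(cols, dtype=np.int64)]
        count = int(
            np.all(sub == np.array(expected, dtype=np.uint8)[None, :], axis=1).sum()
        )
        out.append(NodeConcordance(node.id, node.n, count, count / n_query))
    return out


# ---------------------------------------------------------------------------
# repeat-class grouping
# ---------------------------------------------------------------------------

@dataclass
class RepeatAnnotation:
    """Per-sample repeat-allele counts; grouping uses the larger allele."""

    repeats: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for sid, (r1, r2) in self.repeats.items():
            if r1 < 2 or r2 < 2:
                raise ValueError(
                    f"sample {sid}: repeat counts must be >= 2, got ({r1}, {r2})"
                )

    def max_repeat(self, sample_id: str) -> int:
        r1, r2 = self.repeats[sample_id]
        return max(r1, r2)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.repeats


def read_repeat_annotation(path) -> RepeatAnnotation:
    """TSV with columns sample, rep1, rep2 (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (sample, rep1, rep2)")
    if not str(df.iloc[0, 1]).isdigit():  # header row present
        df = df.iloc[1:]
    return RepeatAnnotation(
        {str(r[0]): (int(r[1]), int(r[2])) for r in df.itertuples(index=False)}
    )


@dataclass
class GroupSharing:
    """Per-bin sharing summary and MRCA estimate."""

    bin: tuple[int, int]
    n_haplotypes: int
    mean_markers: float | None
    mean_mb: float | None
    mrca: MrcaEstimate | None


def _validate_bins(bins: Sequence[tuple[int, int]]) -> None:
    spans = sorted(bins)
    for (lo, hi) in spans:
        if lo > hi:
            raise ValueError(f"bin {lo}-{hi} is empty")
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ValueError(f"bins {lo1}-{hi1} and {lo2}-{hi2} overlap")


def group_sharing(
    segments: Sequence[SharedSegment],
    annotation: RepeatAnnotation,
    matrix: HaplotypeMatrix,
    bins: Sequence[tuple[int, int]] = DEFAULT_REPEAT_BINS,
    gmap=None,
    locus_pos: int | None = None,
    mrca_mode: str = "independent",
    alpha: float = 0.05,
) -> list[GroupSharing]:
    """Group samples by their largest repeat allele and summarize sharing.

    Each sample falls in the bin of its larger repeat count; its
    haplotypes' segments (whichever set the caller computed: all rows or
    carrier-selected ones) contribute to the bin's mean length.  When a
    genetic map and locus are given, a per-bin MRCA estimate is added.
    Samples without an annotation are excluded with a warning.
    """
    _validate_bins(bins)
    by_bin: dict[tuple[int, int], list[SharedSegment]] = {tuple(b): [] for b in bins}
    missing: set[str] = set()
    for seg in segments:
        sid = matrix.sample_of_row(seg.row_idx)
        if sid not in annotation:
            missing.add(sid)
            continue
        r = annotation.max_repeat(sid)
        for lo, hi in bins:
            if lo <= r <= hi:
                by_bin[(lo, hi)].append(seg)
                break
    if missing:
        logger.warning(
            "%d samples without repeat annotation excluded: %s",
            len(missing), ", ".join(sorted(missing)[:5]),
        )
    out: list[GroupSharing] = []
    for b in bins:
        segs = by_bin[tuple(b)]
        if not segs:
            out.append(GroupSharing(tuple(b), 0, None, None, None))
            continue
        mean_markers = float(np.mean([s.n_markers for s in segs]))
        mean_mb = float(np.mean([s.bp_len for s in segs]) / 1e6)
        est = None
        if gmap is not None and locus_pos is not None:
            lengths = segment_genetic_lengths(segs, gmap, locus_pos)
            if lengths.sum() > 0:
                est = estimate_mrca(lengths, mode=mrca_mode, alpha=alpha)
        out.append(GroupSharing(tuple(b), len(segs), mean_markers, mean_mb, est))
    return out
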