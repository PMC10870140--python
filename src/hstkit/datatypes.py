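"""Core in-memory containers shared by every analysis module.

The substrate of the whole toolkit is a matrix of phased haplotypes:
one row per phased chromosome, one column per biallelic SNP marker,
allele codes in {0, 1} (REF/ALT).  All coordinates are 1-based and
inclusive, following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VariantInfo",
    "HaplotypeMatrix",
    "Haplotype",
    "GeneticMap",
]

#: ref/alt pairs whose reverse complement is indistinguishable from an
#: allele swap; they cannot be strand-harmonized across arrays.
STRAND_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class VariantInfo:
    """One biallelic marker: contig, 1-based position, id, REF and single ALT."""

    contig: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(
                f"{self.contig}:{self.pos} ref and alt alleles are identical"
            )

    @property
    def is_strand_ambiguous(self) -> bool:
        return (self.ref, self.alt) in STRAND_AMBIGUOUS_PAIRS

    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class HaplotypeMatrix:
    """Phased haplotype rows x biallelic marker columns.

    ``data`` is an (n_haplotypes, n_markers) uint8 array with entries in
    {0, 1}.  Rows come in sample order: for diploid input, sample *i*
    occupies rows ``2*i`` (haplotype 1) and ``2*i + 1`` (haplotype 2).
    After carrier selection ``ploidy`` drops to 1 and each sample keeps
    a single row.
    """

    variants: list[VariantInfo]
    data: np.ndarray
    sample_ids: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("haplotype data must be 2-dimensional")
        n_rows, n_markers = self.data.shape
        if n_markers != len(self.variants):
            raise ValueError(
                f"{n_markers} data columns but {len(self.variants)} variants"
            )
        if n_rows != len(self.sample_ids) * self.ploidy:
            raise ValueError(
                f"{n_rows} rows != {len(self.sample_ids)} samples x ploidy {self.ploidy}"
            )
        if self.data.size and self.data.max() > 1:
            raise ValueError("allele codes must be 0 or 1")
        contigs = {v.contig for v in self.variants}
        if len(contigs) > 1:
            raise ValueError(f"matrix must hold a single contig, got {sorted(contigs)}")
        pos = self.positions
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def contig(self) -> str:
        return self.variants[0].contig

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def row_labels(self) -> list[str]:
        """``sample-1`` / ``sample-2`` style labels, one per haplotype row."""
        if self.ploidy == 1:
            return list(self.sample_ids)
        return [
            f"{sid}-{h + 1}" for sid in self.sample_ids for h in range(self.ploidy)
        ]

    def sample_of_row(self, row_idx: int) -> str:
        return self.sample_ids[row_idx // self.ploidy]

    def marker_at(self, pos: int, select: str = "exact") -> int:
        """Index of the marker at ``pos``.

        ``select`` controls behaviour when no marker sits exactly at
        ``pos``: "exact" raises, "upstream" takes the closest marker at
        or below ``pos``, "downstream" the closest at or above, and
        "nearest" whichever is closer in bp (ties go upstream).
        """
        positions = self.positions
        exact = np.flatnonzero(positions == pos)
        if exact.size:
            return int(exact[0])
        if select == "exact":
            raise KeyError(f"no marker at {self.contig}:{pos}")
        below = np.flatnonzero(positions < pos)
        above = np.flatnonzero(positions > pos)
        if select == "upstream":
            if not below.size:
                raise KeyError(f"no marker at or upstream of {self.contig}:{pos}")
            return int(below[-1])
        if select == "downstream":
            if not above.size:
                raise KeyError(f"no marker at or downstream of {self.contig}:{pos}")
            return int(above[0])
        if select == "nearest":
            if not below.size:
                return int(above[0])
            if not above.size:
                return int(below[-1])
            lo, hi = int(below[-1]), int(above[0])
            return lo if pos - positions[lo] <= positions[hi] - pos else hi
        raise ValueError(f"unknown marker selection policy {select!r}")

    def subset_rows(
        self, rows: Sequence[int], sample_ids: Sequence[str], ploidy: int = 1
    ) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            variants=list(self.variants),
            data=self.data[np.asarray(rows, dtype=np.intp)],
            sample_ids=list(sample_ids),
            ploidy=ploidy,
        )


@dataclass
class Haplotype:
    """An ordered run of (marker, allele) pairs over a contiguous range."""

    variants: list[VariantInfo]
    alleles: np.ndarray
    #: marker column indices into the source matrix, when known
    marker_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if len(self.variants) != self.alleles.size:
            raise ValueError("variants and alleles length mismatch")
        pos = np.array([v.pos for v in self.variants], dtype=np.int64)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("haplotype markers must be strictly increasing by position")
        if self.marker_indices is not None:
            self.marker_indices = np.asarray(self.marker_indices, dtype=np.int64)
            if self.marker_indices.size != self.alleles.size:
                raise ValueError("marker_indices length mismatch")

    def __len__(self) -> int:
        return self.alleles.size

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def allele_at_pos(self, pos: int) -> int:
        i = np.flatnonzero(self.positions == pos)
        if not i.size:
            raise KeyError(f"no marker at position {pos} in haplotype")
        return int(self.alleles[i[0]])


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> centimorgan map for one contig."""

    contig: str
    bp: np.ndarray
    cM: np.ndarray

    def __post_init__(self) -> None:
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cM = np.asarray(self.cM, dtype=np.float64)
        if self.bp.size != self.cM.size:
            raise ValueError("bp and cM arrays differ in length")
        if self.bp.size < 2:
            raise ValueError("genetic map needs at least 2 points")
        if np.any(np.diff(self.bp) <= 0):
            raise ValueError("genetic map bp positions must be strictly increasing")
        if np.any(np.diff(self.cM) < 0):
            raise ValueError("non-monotone genetic map: cM decreases with bp")

    def interpolate(self, pos) -> np.ndarray | float:
        """cM at bp position(s); clamps outside the mapped range."""
        out = np.interp(np.asarray(pos, dtype=np.float64), self.bp, self.cM)
        return float(out) if np.isscalar(pos) or np.ndim(pos) == 0 else out

    @classmethod
    def uniform(
        cls, contig: str, start_bp: int, end_bp: int, cM_per_Mb: float
    ) -> "GeneticMap":
        span_cM = (end_bp - start_bp) / 1e6 * cM_per_Mb
        return cls(contig, np.array([start_bp, end_bp]), np.array([0.0, span_cM]))
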