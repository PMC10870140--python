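"""Haplotype sharing trees (HSTs).

An HST summarizes continuous haplotype sharing around a focal marker.
Starting from a node holding every phased haplotype, the algorithm scans
marker by marker away from the start: columns where all of a node's rows
agree extend the node's shared haplotype, and the first contradictory
column splits the node.  Unidirectional trees scan a single direction
and split two ways; the bidirectional tree scans both directions at once
and splits on the (left allele, right allele) pair into two to four
children.  At every split the largest child comes first, so the leftmost
root-to-leaf path (the *majority branch*) walks recombination events
backwards toward the majority-based ancestral haplotype.

Recursion is implemented with an explicit work stack so cohort-sized
trees never hit the interpreter's recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .datatypes import Haplotype, HaplotypeMatrix, VariantInfo

__all__ = [
    "HstNode",
    "Hst",
    "build_uhst",
    "build_bhst",
    "majority_branch",
    "majority_divergence_markers",
    "ancestral_haplotype",
    "merge_ancestral",
    "core_haplotype",
    "prune_anonymize",
]


@dataclass
class HstNode:
    """One tree node: the rows sharing a haplotype and the haplotype itself.

    ``haplotype`` is an ordered list of (marker_idx, allele) pairs over a
    contiguous marker range; ``start_idx``/``stop_idx`` are the range ends
    (equal frontiers for unidirectional trees, per-side frontiers for the
    bidirectional tree).  ``indexes`` is None in anonymized trees, where
    only the count ``n`` survives.
    """

    id: int
    indexes: np.ndarray | None
    n: int
    haplotype: list[tuple[int, int]] = field(default_factory=list)
    start_idx: int | None = None
    stop_idx: int | None = None
    children: list[int] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def haplotype_range(self) -> tuple[int, int] | None:
        if not self.haplotype:
            return None
        markers = [m for m, _ in self.haplotype]
        return min(markers), max(markers)


@dataclass
class Hst:
    direction: str  # "left" | "right" | "bidirectional"
    start_marker_idx: int
    variants: list[VariantInfo]
    nodes: dict[int, HstNode]
    root_id: int = 0
    samples: list[str] | None = None
    min_node_size: int = 1
    anonymized: bool = False
    source: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def root(self) -> HstNode:
        return self.nodes[self.root_id]

    @property
    def n_haplotypes(self) -> int:
        return self.root.n

    @property
    def contig(self) -> str:
        return self.variants[0].contig

    @property
    def start_pos(self) -> int:
        return self.variants[self.start_marker_idx].pos

    def node_haplotype(self, node_id: int) -> Haplotype:
        node = self.nodes[node_id]
        pairs = sorted(node.haplotype)
        return Haplotype(
            variants=[self.variants[m] for m, _ in pairs],
            alleles=np.array([a for _, a in pairs], dtype=np.uint8),
            marker_indices=np.array([m for m, _ in pairs], dtype=np.int64),
        )

    def leaves(self) -> list[HstNode]:
        return [n for n in self.walk() if n.is_leaf]

    def walk(self) -> Iterable[HstNode]:
        """Depth-first pre-order traversal, children in stored order."""
        stack = [self.root_id]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def validate(self) -> None:
        seen: set[int] = set()
        for node in self.walk():
            if node.id in seen:
                raise ValueError(f"node {node.id} reachable twice (cycle?)")
            seen.add(node.id)
            kids = [self.nodes[c] for c in node.children]
            if kids:
                # pruned trees may have truncated subtrees, so children are
                # disjoint subsets of the parent but need not cover it
                if sum(k.n for k in kids) > node.n:
                    raise ValueError(f"children of node {node.id} exceed its size")
                if any(kids[0].n < k.n for k in kids[1:]):
                    raise ValueError(f"first child of node {node.id} is not largest")
                if node.indexes is not None and all(k.indexes is not None for k in kids):
                    union = np.concatenate([k.indexes for k in kids]).tolist()
                    if len(set(union)) != len(union) or not set(union) <= set(
                        node.indexes.tolist()
                    ):
                        raise ValueError(
                            f"children of node {node.id} are not disjoint subsets of it"
                        )
            if node.indexes is not None and len(node.indexes) != node.n:
                raise ValueError(f"node {node.id}: n does not match indexes")
        if seen != set(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise ValueError(f"nodes unreachable from root: {orphans}")
        if self.root.haplotype:
            raise ValueError("root node must carry an empty haplotype")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _scan(data: np.ndarray, rows: np.ndarray, ptr: int, step: int, n_markers: int):
    """Absorb uniform columns from ptr in direction step.

    Returns (ext, ptr) where ext is the absorbed (marker, allele) list and
    ptr is the first contradictory column, or out of range if exhausted.
    """
    ext: list[tuple[int, int]] = []
    while 0 <= ptr < n_markers:
        col = data[rows, ptr]
        first = col[0]
        if np.all(col == first):
            ext.append((ptr, int(first)))
            ptr += step
        else:
            break
    return ext, ptr


def _check_build_args(matrix: HaplotypeMatrix, start_idx: int, min_size: int) -> None:
    if matrix.n_haplotypes == 0:
        raise ValueError("cannot build an HST from an empty matrix")
    if not 0 <= start_idx < matrix.n_markers:
        raise ValueError(
            f"start marker index {start_idx} out of range 0..{matrix.n_markers - 1}"
        )
    if min_size < 1:
        raise ValueError("min_size must be >= 1")


def build_uhst(
    matrix: HaplotypeMatrix,
    start_idx: int,
    direction: str,
    min_size: int = 1,
) -> Hst:
    """Build a unidirectional HST scanning left or right from start_idx.

    Nodes stop branching once they hold a single row, fewer than
    ``min_size`` rows, or the end of the data is reached.  At every split
    the larger child comes first; equal sizes break toward the lower
    allele code so the tree is deterministic.
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    _check_build_args(matrix, start_idx, min_size)
    step = 1 if direction == "right" else -1
    data = matrix.data
    nm = matrix.n_markers
    all_rows = np.arange(matrix.n_haplotypes, dtype=np.int64)

    nodes: dict[int, HstNode] = {}
    root = HstNode(0, all_rows, len(all_rows))
    nodes[0] = root
    next_id = 1
    stack: list[tuple[int, int]] = [(0, start_idx)]  # (node id, next ptr)

    def new_node(rows: np.ndarray, hap: list[tuple[int, int]]) -> HstNode:
        nonlocal next_id
        hap = sorted(hap)
        node = HstNode(next_id, rows, len(rows), hap)
        if hap:
            node.start_idx, node.stop_idx = hap[0][0], hap[-1][0]
        nodes[next_id] = node
        next_id += 1
        return node

    while stack:
        nid, ptr = stack.pop()
        node = nodes[nid]
        rows = node.indexes
        is_root = nid == 0
        if not is_root and (node.n < 2 or node.n < min_size):
            continue
        ext, ptr2 = _scan(data, rows, ptr, step, nm)
        if is_root:
            # the root keeps an empty haplotype: any uniform run scanned from
            # it becomes a single chain child holding all rows
            if ext or node.n < 2:
                child = new_node(rows, ext)
                node.children.append(child.id)
                if node.n >= 2:
                    stack.append((child.id, ptr2))
                continue
        else:
            if ext:
                node.haplotype = sorted(node.haplotype + ext)
                node.start_idx = node.haplotype[0][0]
                node.stop_idx = node.haplotype[-1][0]
        if not (0 <= ptr2 < nm):
            continue  # data end reached
        col = data[rows, ptr2]
        groups = [(rows[col == a], a) for a in (0, 1)]
        groups = [(g, a) for g, a in groups if g.size]
        groups.sort(key=lambda ga: (-ga[0].size, ga[1]))
        for g_rows, allele in groups:
            child = new_node(g_rows, node.haplotype + [(ptr2, int(allele))])
            node.children.append(child.id)
            stack.append((child.id, ptr2 + step))

    hst = Hst(
        direction=direction,
        start_marker_idx=start_idx,
        variants=list(matrix.variants),
        nodes=nodes,
        samples=matrix.row_labels,
        min_node_size=min_size,
    )
    return hst


def build_bhst(matrix: HaplotypeMatrix, start_idx: int, min_size: int = 1) -> Hst:
    """Build a bidirectional HST scanning both directions at once.

    Each node absorbs uniform columns on both sides until a contradictory
    column is found on each; rows are then partitioned by their (left
    allele, right allele) pair into two to four children.  If one side is
    exhausted, a two-way split on the remaining side keeps the tree
    growing to the contig end.  The start marker belongs to the rightward
    scan.
    """
    _check_build_args(matrix, start_idx, min_size)
    data = matrix.data
    nm = matrix.n_markers
    all_rows = np.arange(matrix.n_haplotypes, dtype=np.int64)

    nodes: dict[int, HstNode] = {}
    root = HstNode(0, all_rows, len(all_rows))
    nodes[0] = root
    next_id = 1
    # (node id, next left ptr, next right ptr)
    stack: list[tuple[int, int, int]] = [(0, start_idx - 1, start_idx)]

    def new_node(rows: np.ndarray, hap: list[tuple[int, int]]) -> HstNode:
        nonlocal next_id
        hap = sorted(hap)
        node = HstNode(next_id, rows, len(rows), hap)
        if hap:
            node.start_idx, node.stop_idx = hap[0][0], hap[-1][0]
        nodes[next_id] = node
        next_id += 1
        return node

    while stack:
        nid, lp, rp = stack.pop()
        node = nodes[nid]
        rows = node.indexes
        is_root = nid == 0
        if not is_root and (node.n < 2 or node.n < min_size):
            continue
        ext_l, lp2 = _scan(data, rows, lp, -1, nm)
        ext_r, rp2 = _scan(data, rows, rp, +1, nm)
        ext = ext_l + ext_r
        if is_root:
            if ext or node.n < 2:
                child = new_node(rows, ext)
                node.children.append(child.id)
                if node.n >= 2:
                    stack.append((child.id, lp2, rp2))
                continue
        else:
            if ext:
                node.haplotype = sorted(node.haplotype + ext)
                node.start_idx = node.haplotype[0][0]
                node.stop_idx = node.haplotype[-1][0]
        left_hit = lp2 >= 0
        right_hit = rp2 < nm
        if not left_hit and not right_hit:
            continue  # both sides exhausted
        if left_hit and right_hit:
            la = data[rows, lp2]
            ra = data[rows, rp2]
            groups = []
            for al in (0, 1):
                for ar in (0, 1):
                    g = rows[(la == al) & (ra == ar)]
                    if g.size:
                        groups.append((g, (al, ar)))
            groups.sort(key=lambda gk: (-gk[0].size, gk[1]))
            for g_rows, (al, ar) in groups:
                child = new_node(
                    g_rows, node.haplotype + [(lp2, al), (rp2, ar)]
                )
                node.children.append(child.id)
                stack.append((child.id, lp2 - 1, rp2 + 1))
        else:
            # one side exhausted: fall back to a one-sided two-way split
            ptr = lp2 if left_hit else rp2
            col = data[rows, ptr]
            groups = [(rows[col == a], a) for a in (0, 1)]
            groups = [(g, a) for g, a in groups if g.size]
            groups.sort(key=lambda ga: (-ga[0].size, ga[1]))
            for g_rows, allele in groups:
                child = new_node(g_rows, node.haplotype + [(ptr, int(allele))])
                node.children.append(child.id)
                stack.append(
                    (child.id, lp2 - 1 if left_hit else lp2, rp2 + 1 if right_hit else rp2)
                )

    hst = Hst(
        direction="bidirectional",
        start_marker_idx=start_idx,
        variants=list(matrix.variants),
        nodes=nodes,
        samples=matrix.row_labels,
        min_node_size=min_size,
    )
    return hst


# ---------------------------------------------------------------------------
# derived haplotypes
# ---------------------------------------------------------------------------

def majority_branch(hst: Hst) -> list[int]:
    """Root-to-leaf path following the first (largest) child at every node."""
    path = [hst.root_id]
    node = hst.root
    while node.children:
        node = hst.nodes[node.children[0]]
        path.append(node.id)
    return path


def _split_marker(hst: Hst, parent: HstNode) -> int | None:
    """Scan-direction marker at which ``parent`` split into its children.

    For bidirectional trees a split adds two markers; the returned value
    is only meaningful for unidirectional trees.
    """
    if not parent.children:
        return None
    child = hst.nodes[parent.children[0]]
    parent_markers = {m for m, _ in parent.haplotype}
    new = [m for m, _ in child.haplotype if m not in parent_markers]
    if not new:
        return None
    # the child may have absorbed uniform columns past the split, so the
    # contradictory marker is the new marker nearest the parent's range
    return new[-1] if hst.direction == "left" else new[0]


def majority_divergence_markers(hst: Hst) -> dict[int, int | None]:
    """Per haplotype row, the marker index at which it leaves the majority
    branch (None for rows that never do before branching stops)."""
    if hst.anonymized or hst.root.indexes is None:
        raise ValueError("divergence markers require a non-anonymized tree")
    out: dict[int, int | None] = {int(r): None for r in hst.root.indexes}
    node = hst.root
    while node.children:
        first = hst.nodes[node.children[0]]
        marker = _split_marker(hst, node)
        stay = set(first.indexes.tolist())
        for r in node.indexes.tolist():
            if r not in stay:
                out[int(r)] = marker
        node = first
    return out


def ancestral_haplotype(hst: Hst) -> Haplotype:
    """Majority-based ancestral haplotype.

    The haplotype of the deepest majority-branch node still holding at
    least two rows, including uniform columns absorbed inside that node
    but excluding its children's contradictory markers.
    """
    if hst.n_haplotypes < 2:
        raise ValueError("ancestral haplotype requires at least 2 haplotypes")
    last = None
    for nid in majority_branch(hst):
        node = hst.nodes[nid]
        if node.n >= 2:
            last = node
    assert last is not None
    return hst.node_haplotype(last.id)


def merge_ancestral(
    left: Haplotype, right: Haplotype, start_idx: int | None = None
) -> Haplotype:
    """Merge down- and upstream ancestral haplotypes into one.

    Both sides include the start marker; it is counted once.  Any marker
    present on both sides must carry the same allele.
    """
    by_pos: dict[int, tuple[VariantInfo, int]] = {
        v.pos: (v, int(a)) for v, a in zip(left.variants, left.alleles)
    }
    overlap = False
    for v, a in zip(right.variants, right.alleles):
        if v.pos in by_pos:
            overlap = True
            if by_pos[v.pos][1] != int(a):
                raise ValueError(
                    f"conflicting allele at shared marker {v.contig}:{v.pos} "
                    "when merging ancestral haplotypes"
                )
        by_pos[v.pos] = (v, int(a))
    if not overlap:
        raise ValueError(
            "left and right ancestral haplotypes share no marker; both must "
            "include the start marker"
        )
    idx_by_pos: dict[int, int] = {}
    for hap in (left, right):
        if hap.marker_indices is not None:
            for v, m in zip(hap.variants, hap.marker_indices):
                idx_by_pos[v.pos] = int(m)
    positions = sorted(by_pos)
    variants = [by_pos[p][0] for p in positions]
    alleles = np.array([by_pos[p][1] for p in positions], dtype=np.uint8)
    indices = None
    if len(idx_by_pos) == len(positions):
        indices = np.array([idx_by_pos[p] for p in positions], dtype=np.int64)
    return Haplotype(variants=variants, alleles=alleles, marker_indices=indices)


def core_haplotype(matrix: HaplotypeMatrix, start_idx: int) -> Haplotype:
    """Maximal contiguous marker run around start_idx shared by ALL rows.

    Empty when the start column itself is not uniform.
    """
    if not 0 <= start_idx < matrix.n_markers:
        raise ValueError(f"start marker index {start_idx} out of range")
    data = matrix.data
    uniform = np.all(data == data[0], axis=0)
    if not uniform[start_idx]:
        return Haplotype(variants=[], alleles=np.array([], dtype=np.uint8),
                         marker_indices=np.array([], dtype=np.int64))
    lo = start_idx
    while lo > 0 and uniform[lo - 1]:
        lo -= 1
    hi = start_idx
    while hi < matrix.n_markers - 1 and uniform[hi + 1]:
        hi += 1
    idx = np.arange(lo, hi + 1, dtype=np.int64)
    return Haplotype(
        variants=[matrix.variants[i] for i in idx],
        alleles=data[0, lo : hi + 1].copy(),
        marker_indices=idx,
    )


def prune_anonymize(hst: Hst, min_size: int, anonymize: bool = False) -> Hst:
    """Drop nodes shared by fewer than ``min_size`` rows; optionally strip
    all sample identity, leaving per-node counts only."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if min_size > hst.n_haplotypes:
        raise ValueError(
            f"min_size {min_size} exceeds the {hst.n_haplotypes} haplotypes in the tree"
        )
    keep: dict[int, HstNode] = {}
    stack = [hst.root_id]
    while stack:
        nid = stack.pop()
        node = hst.nodes[nid]
        kept_children = [c for c in node.children if hst.nodes[c].n >= min_size]
        keep[nid] = HstNode(
            id=node.id,
            indexes=None if anonymize or node.indexes is None else node.indexes.copy(),
            n=node.n,
            haplotype=list(node.haplotype),
            start_idx=node.start_idx,
            stop_idx=node.stop_idx,
            children=kept_children,
            extra=dict(node.extra),
        )
        stack.extend(kept_children)
    return Hst(
        direction=hst.direction,
        start_marker_idx=hst.start_marker_idx,
        variants=list(hst.variants),
        nodes=keep,
        root_id=hst.root_id,
        samples=None if anonymize else (list(hst.samples) if hst.samples else None),
        min_node_size=max(min_size, hst.min_node_size),
        anonymized=anonymize or hst.anonymized,
        source=hst.source,
        extra=dict(hst.extra),
    )
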