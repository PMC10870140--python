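"""Tree and comparison-matrix rendering.

Figures are conveniences: every quantity drawn here is also available as
TSV from the CLI, so no scientific result depends on a plotting backend.
All renderings are deterministic functions of their inputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .compare import ComparisonMatrix
from .hst import Hst

__all__ = ["render_tree", "plot_segment_matrix"]

# mismatch pink; per-sample shorter-sharing match blue; longer-sharing white
_COLOR_MISMATCH = (0.96, 0.62, 0.72)
_COLOR_SHORTER = (0.55, 0.70, 0.92)
_COLOR_LONGER = (1.0, 1.0, 1.0)


def _node_tag_counts(hst: Hst, node_id: int, tags: dict[str, str]) -> dict[str, int]:
    node = hst.nodes[node_id]
    if node.indexes is None or not hst.samples:
        return {}
    counts: dict[str, int] = {}
    for r in node.indexes:
        label = tags.get(hst.samples[int(r)])
        if label:
            counts[label] = counts.get(label, 0) + 1
    return counts


def _text_tree(hst: Hst, tags: dict[str, str]) -> str:
    lines: list[str] = []
    stack: list[tuple[int, int]] = [(hst.root_id, 0)]
    while stack:
        node_id, depth = stack.pop()
        node = hst.nodes[node_id]
        rng = node.haplotype_range()
        span = ""
        if rng is not None:
            lo, hi = rng
            span = f" {hst.variants[lo].pos}-{hst.variants[hi].pos}"
        tag_counts = _node_tag_counts(hst, node_id, tags)
        tag_str = (
            " [" + ", ".join(f"{k}:{v}" for k, v in sorted(tag_counts.items())) + "]"
            if tag_counts
            else ""
        )
        lines.append(f"{'  ' * depth}node {node.id} n={node.n}{span}{tag_str}")
        for c in reversed(node.children):
            stack.append((c, depth + 1))
    return "\n".join(lines) + "\n"


def _dot_tree(hst: Hst, tags: dict[str, str]) -> str:
    lines = ["digraph hst {", "  node [shape=circle];"]
    for node in hst.walk():
        tag_counts = _node_tag_counts(hst, node.id, tags)
        label = str(node.n)
        attrs = [f'label="{label}"']
        if tag_counts:
            tag_str = ",".join(f"{k}:{v}" for k, v in sorted(tag_counts.items()))
            attrs.append(f'xlabel="{tag_str}"')
            attrs.append('color="darkgreen"')
        lines.append(f"  n{node.id} [{', '.join(attrs)}];")
    for node in hst.walk():
        for c in node.children:
            lines.append(f"  n{node.id} -> n{c};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _layout(hst: Hst) -> dict[int, tuple[float, float]]:
    """Leaf-ordered layered layout: x by leaf rank, y by depth."""
    pos: dict[int, tuple[float, float]] = {}
    next_x = 0.0
    # post-order with explicit stack: leaves left to right, parents centered
    stack: list[tuple[int, int, bool]] = [(hst.root_id, 0, False)]
    while stack:
        node_id, depth, expanded = stack.pop()
        node = hst.nodes[node_id]
        if not node.children:
            pos[node_id] = (next_x, -float(depth))
            next_x += 1.0
        elif not expanded:
            stack.append((node_id, depth, True))
            for c in reversed(node.children):
                stack.append((c, depth + 1, False))
        else:
            xs = [pos[c][0] for c in node.children]
            pos[node_id] = (float(np.mean(xs)), -float(depth))
    return pos


def _image_tree(hst: Hst, tags: dict[str, str], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = _layout(hst)
    n_leaves = max(1, sum(1 for n in hst.nodes.values() if n.is_leaf))
    depth = max(1, int(-min(y for _, y in pos.values())))
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * n_leaves), max(3, 0.8 * depth)))
    for node in hst.walk():
        x0, y0 = pos[node.id]
        for c in node.children:
            x1, y1 = pos[c]
            ax.plot([x0, x1], [y0, y1], "-", color="0.6", lw=1, zorder=1)
    for node in hst.walk():
        x, y = pos[node.id]
        tagged = bool(_node_tag_counts(hst, node.id, tags))
        ax.scatter(
            [x], [y], s=300, zorder=2,
            c="mediumseagreen" if tagged else "lightsteelblue",
            edgecolors="k", linewidths=0.5,
        )
        ax.annotate(
            str(node.n), (x, y), ha="center", va="center", fontsize=8, zorder=3
        )
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_tree(
    hst: Hst,
    style: str,
    path: str | Path | None = None,
    tags: dict[str, str] | None = None,
) -> str | None:
    """Render a tree as indented text, DOT, or an image file.

    Node labels carry the number of haplotypes sharing the node's
    haplotype; ``tags`` (sample label -> tag) colors/annotates nodes
    containing tagged samples.  Text and DOT are returned as strings and
    optionally written; the image style requires ``path``.
    """
    tags = tags or {}
    if style == "text":
        out = _text_tree(hst, tags)
    elif style == "dot":
        out = _dot_tree(hst, tags)
    elif style == "image":
        if path is None:
            raise ValueError("image rendering requires an output path")
        _image_tree(hst, tags, Path(path))
        return None
    else:
        raise ValueError(f"unknown tree rendering style {style!r}")
    if path is not None:
        Path(path).write_text(out)
    return out


def plot_segment_matrix(comparison: ComparisonMatrix, out: str | Path) -> None:
    """Heat-strip of every haplotype vs the ancestral haplotype.

    Three colors: mismatching alleles pink, matches on the per-sample
    shorter-sharing haplotype blue, matches on the longer one white.
    Rows follow the comparison sort (most downstream sharing on top).
    """
    if comparison.matches.size == 0:
        raise ValueError("empty comparison matrix")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_rows, n_cols = comparison.matches.shape
    rgb = np.empty((n_rows, n_cols, 3), dtype=np.float64)
    for disp_i, orig_row in enumerate(comparison.row_order):
        match_color = (
            _COLOR_LONGER
            if comparison.longer_per_sample[orig_row]
            else _COLOR_SHORTER
        )
        row = comparison.matches[disp_i]
        rgb[disp_i] = np.where(row[:, None], match_color, _COLOR_MISMATCH)
    fig, ax = plt.subplots(figsize=(8, max(2, 0.08 * n_rows)))
    ax.imshow(rgb, aspect="auto", interpolation="nearest")
    ax.axvline(comparison.start_col, color="k", lw=0.8)
    ax.set_xlabel("marker")
    ax.set_ylabel("haplotype (sorted by downstream sharing)")
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
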