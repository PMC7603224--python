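"""p-distances and neighbor-joining tree construction.

The distance between two aligned sequences is the proportion of mismatching
residues over columns where neither has a gap.  Trees are built with the
Saitou-Nei neighbor-joining agglomeration; the result is an unrooted binary
tree serializable as Newick.  Negative branch-length estimates (possible on
non-additive matrices) are clamped to zero with the deficit moved to the
sister branch, preserving the pair's summed length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence import Msa

__all__ = ["DistanceMatrix", "TreeNode", "p_distance", "neighbor_joining",
           "leaf_names", "sister_pairs"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry names, edges carry lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(f"{c._newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})" + (self.name or "")


def p_distance(msa: Msa) -> DistanceMatrix:
    """Pairwise mismatch proportion over mutually gap-free columns."""
    n = len(msa.ids)
    arr = np.array([list(s) for s in msa.sequences])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            if not ok.any():
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]!r} and {msa.ids[j]!r}")
            d[i, j] = d[j, i] = np.mean(arr[i, ok] != arr[j, ok])
    return DistanceMatrix(list(msa.ids), d)


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    # move any negative-length deficit to the sister branch
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi += bj
        bj = 0.0
    return bi, max(bj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; deterministic, ties broken by the
    lexicographically smallest active-index pair.

    Returns the unrooted tree as a trifurcating root node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)  # first == smallest pair
        ai, aj = sorted(best)
        i, j = active[ai], active[aj]
        dij = d[i, j]
        bi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        bj = dij - bi
        bi, bj = _clamp_pair(bi, bj)
        parent = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        # new distances to the remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    # three-point formulas for the final star
    ba = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    bb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    bc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return TreeNode(children=[(nodes[a], max(ba, 0.0)),
                              (nodes[b], max(bb, 0.0)),
                              (nodes[c], max(bc, 0.0))])


def leaf_names(tree: TreeNode) -> set[str]:
    if tree.is_leaf:
        return {tree.name}
    out: set[str] = set()
    for child, _ in tree.children:
        out |= leaf_names(child)
    return out


def sister_pairs(tree: TreeNode) -> set[frozenset[str]]:
    """All cherries: pairs of leaves joined by one internal node."""
    pairs: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> None:
        kids = [c for c, _ in node.children]
        leaves = [c for c in kids if c.is_leaf]
        if len(kids) == 2 and len(leaves) == 2:
            pairs.add(frozenset(c.name for c in leaves))
        for c in kids:
            walk(c)

    walk(tree)
    return pairs
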