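"""Distance-based phylogeny of confirmed hits.

The confirmed-methioninase tree is rebuilt with neighbor joining on
pairwise protein distances (p-distance, optionally Poisson-corrected
``d = -ln(1 - p)``) computed from a reference-anchored alignment. NJ is
exact on additive matrices; it replaces the approximate-ML step used
for the published figure, whose claims here are about clustering
structure rather than branch support. Trees are ``skbio.TreeNode``
objects and are read/written as Newick.
"""

from __future__ import annotations

import io as _io
import math

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import OverlapError, SaturationError, TreeError
from .io import Msa


def distance_matrix(msa: Msa, correction: str = "none") -> DistanceMatrix:
    """Pairwise distances over columns where both rows are ungapped.

    p-distance = mismatches / shared ungapped columns. ``correction``
    is ``"none"`` or ``"poisson"`` (``-ln(1-p)``; p >= 1 saturates).
    """
    if correction not in ("none", "poisson"):
        raise TreeError(f"unknown distance correction {correction!r}")
    n = len(msa.records)
    if n < 2:
        raise TreeError("need at least two rows for a distance matrix")
    ids = [rid for rid, _ in msa.records]
    rows = [row for _, row in msa.records]
    arr = np.array([[c for c in row] for row in rows])
    gap = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise OverlapError(
                    f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / n_shared
            if correction == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"p-distance saturated (p={p:.3f}) for pair "
                        f"({ids[i]!r}, {ids[j]!r})"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids)


def _clamp_pair(li: float, lj: float, total: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sibling."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; arbitrary trifurcating root.

    Q-matrix ties break on the smallest (i, j) index pair; negative
    branch lengths are clamped to 0 with the deficit added to the
    sibling edge. Two taxa yield a single edge split evenly.
    """
    ids = list(dm.ids)
    d = np.array(dm.data, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T) or np.any(d < 0):
        raise TreeError("distance matrix must be symmetric and non-negative")
    if np.any(np.diag(d) != 0):
        raise TreeError("distance matrix diagonal must be zero")
    n = len(ids)
    if n < 2:
        raise TreeError("need at least two taxa")
    nodes = [TreeNode(name=name) for name in ids]
    if n == 2:
        half = d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return TreeNode(children=nodes)

    active = list(range(n))
    while len(active) > 3:
        na = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for ai in range(na):
            for aj in range(ai + 1, na):
                q = (na - 2) * sub[ai, aj] - r[ai] - r[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (na - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj, dij)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every other active taxon
        new_row = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        new = d.shape[0] - 1
        for ak in range(na):
            k = active[ak]
            if k in (i, j):
                continue
            dk = max(0.0, (sub[ai, ak] + sub[aj, ak] - dij) / 2.0)
            d[new, k] = d[k, new] = dk
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    # trifurcating root from the last three nodes
    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = d[a, b] - la
    lc = d[a, c] - la
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(0.0, ln)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        tree.write(fh)


def parse_newick(text: str) -> TreeNode:
    """Parse Newick text; unbalanced or malformed input raises TreeError."""
    if text.count("(") != text.count(")"):
        raise TreeError(
            f"unbalanced parentheses ({text.count('(')} open, "
            f"{text.count(')')} close)"
        )
    try:
        return TreeNode.read(_io.StringIO(text))
    except Exception as exc:  # skbio raises several parser error types
        raise TreeError(f"malformed Newick: {exc}") from exc


def read_newick(path) -> TreeNode:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())
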