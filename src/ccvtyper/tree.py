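"""Neighbour-joining trees from distance matrices, Newick IO, patristic distances.

Canonical Saitou-Nei agglomeration with the Studier-Keppler selection
criterion Q(i,j) = (n-2) D(i,j) - sum_k D(i,k) - sum_k D(j,k).  On an
additive (tree-realizable) matrix, NJ recovers the generating topology and
branch lengths exactly, so the patristic distances of the output reproduce
the input matrix; this is the main correctness oracle.

The implementation is O(n^3) with cached row sums and in-place matrix
compaction (the removed row/column is overwritten by the last active one),
so a single triangular-equivalent workspace serves the whole run.  Trees are
dendropy objects: Newick serialization and leaf-to-leaf path sums reuse
dendropy's machinery, while the agglomeration itself lives here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "neighbour_joining",
    "write_newick",
    "read_newick",
    "patristic_distances",
]


def neighbour_joining(
    D: DistanceMatrix | np.ndarray,
    ids: Sequence[str] | None = None,
    clamp_negative: bool = False,
) -> dendropy.Tree:
    """Build an unrooted NJ tree (trifurcating root) from a distance matrix.

    Ties in the minimum of Q break toward the lexicographically smallest
    (i, j) index pair of the working matrix.  Negative branch lengths are
    preserved unless ``clamp_negative`` is set.
    """
    if isinstance(D, DistanceMatrix):
        ids = list(D.ids)
        M = D.values.astype(float).copy()
    else:
        M = np.asarray(D, dtype=float).copy()
        if ids is None:
            ids = [f"t{i}" for i in range(M.shape[0])]
        ids = list(ids)
        if M.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(M, M.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diagonal(M) != 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
    if np.any(M < 0.0):
        raise ValueError("distance matrix has negative entries")
    n = len(ids)
    if n < 2:
        raise ValueError("neighbour joining requires at least 2 leaves")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for sid in ids:
        taxon = tns.new_taxon(label=sid)
        nodes.append(dendropy.Node(taxon=taxon))

    def _edge(length: float) -> float:
        return max(0.0, length) if clamp_negative else length

    tree = dendropy.Tree(taxon_namespace=tns)

    if n == 2:
        half = M[0, 1] / 2.0  # one observed distance: split evenly by convention
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = _edge(half)
        nodes[1].edge.length = _edge(half)
        tree.is_rooted = False
        return tree

    m = n  # active count; active entries occupy M[:m, :m] and nodes[:m]
    row_sums = M.sum(axis=1)

    while m > 3:
        sub = M[:m, :m]
        rs = row_sums[:m]
        Q = (m - 2) * sub - rs[:, None] - rs[None, :]
        iu = np.arange(m)
        Q[iu, iu] = np.inf
        flat = int(np.argmin(Q))  # row-major: first minimum = lexicographic (i, j)
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (rs[i] - rs[j]) / (2.0 * (m - 2))
        lj = dij - li

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = _edge(li)
        nodes[j].edge.length = _edge(lj)

        # distances from the new node u to every other active node
        new_d = 0.5 * (sub[i, :m] + sub[j, :m] - dij)
        new_d[i] = 0.0
        new_d[j] = 0.0

        # place u in slot i; move the last active slot into j; shrink
        last = m - 1
        M[:m, i] = new_d
        M[i, :m] = new_d
        nodes[i] = parent
        if j != last:
            M[:m, j] = M[:m, last]
            M[j, :m] = M[last, :m]
            M[j, j] = 0.0
            nodes[j] = nodes[last]
        m -= 1
        row_sums[:m] = M[:m, :m].sum(axis=1)

    # join the final three nodes at the trifurcating root
    a, b, c = M[0, 1], M[0, 2], M[1, 2]
    lens = (0.5 * (a + b - c), 0.5 * (a + c - b), 0.5 * (b + c - a))
    for node, length in zip(nodes[:3], lens):
        tree.seed_node.add_child(node)
        node.edge.length = _edge(length)
    tree.is_rooted = False
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Newick with full float precision; labels quoted when they contain
    reserved characters; trailing semicolon and newline."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
        preserve_spaces=True,
        unquoted_underscores=True,
    )
    Path(path).write_text(text if text.endswith("\n") else text + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the unique path between every leaf pair,
    ordered by leaf label."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = d
            values[j, i] = d
    return DistanceMatrix(ids=labels, values=values, metric="patristic")
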