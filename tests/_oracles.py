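"""Independent brute-force oracles and instance generators shared by tests.

Everything here is deliberately naive (character loops, explicit formulas,
exhaustive enumeration) and independent of the library code paths it checks.
"""

from __future__ import annotations

import math
from collections import Counter

import dendropy
import numpy as np


def naive_kmer_counts(seq: str, k: int, canonical: set[str] | frozenset[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(ch in canonical for ch in w):
            counts[w] = counts.get(w, 0) + 1
    return counts


def naive_p(seq: str, alpha: str) -> float:
    k = len(alpha)
    hits = sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == alpha)
    return hits / (len(seq) - k + 1)


def naive_pi(seq: str, alpha: str) -> float:
    """Composition value from first principles (single canonical sequence)."""
    p = naive_p(seq, alpha)
    mid = naive_p(seq, alpha[1:-1])
    if mid == 0:
        q = 0.0
    else:
        q = naive_p(seq, alpha[:-1]) * naive_p(seq, alpha[1:]) / mid
    if q == 0.0:
        return 0.0
    return (p - q) / q


def naive_ccv(seq: str, k_min: int, k_max: int) -> dict[str, float]:
    out: dict[str, float] = {}
    for k in range(k_min, min(k_max, len(seq)) + 1):
        for i in range(len(seq) - k + 1):
            a = seq[i : i + k]
            if a not in out:
                out[a] = naive_pi(seq, a)
    return out


def naive_pooled_pi(seqs: list[str], alpha: str) -> float:
    """Background composition value over pooled per-sequence windows."""

    def pooled_p(a: str) -> float:
        k = len(a)
        hits = tot = 0
        for s in seqs:
            if len(s) < k:
                continue
            tot += len(s) - k + 1
            hits += sum(1 for i in range(len(s) - k + 1) if s[i : i + k] == a)
        return hits / tot if tot else 0.0

    p = pooled_p(alpha)
    mid = pooled_p(alpha[1:-1])
    q = 0.0 if mid == 0 else pooled_p(alpha[:-1]) * pooled_p(alpha[1:]) / mid
    if q == 0.0:
        return 0.0
    return (p - q) / q


def naive_re(per_seq_pi: list[dict[str, float]], background_pi: dict[str, float]) -> dict[str, float]:
    keys = set().union(*per_seq_pi) if per_seq_pi else set()
    out: dict[str, float] = {}
    for a in keys:
        bg = background_pi.get(a, 0.0)
        total = 0.0
        for v in per_seq_pi:
            pi = v.get(a, 0.0)
            if pi != 0.0 and bg != 0.0 and pi / bg > 0.0:
                total += pi * math.log(pi / bg)
        out[a] = total
    return out


def random_additive_tree(rng: np.random.Generator, n: int) -> dendropy.Tree:
    """Random binary unrooted tree with branch lengths in [0.1, 2)."""
    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.new_taxon(label=f"L{i}")) for i in range(n)]
    tree = dendropy.Tree(taxon_namespace=tns)
    active = list(range(n))
    all_nodes = list(nodes)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(all_nodes[a])
        all_nodes[a].edge.length = float(rng.uniform(0.1, 2.0))
        parent.add_child(all_nodes[b])
        all_nodes[b].edge.length = float(rng.uniform(0.1, 2.0))
        all_nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(all_nodes) - 1]
    for idx in active:
        tree.seed_node.add_child(all_nodes[idx])
        all_nodes[idx].edge.length = float(rng.uniform(0.1, 2.0))
    tree.is_rooted = False
    return tree


def two_blob_instance(rng: np.random.Generator) -> np.ndarray:
    """Points forming two tight 2-D blobs (radius 0.5) with centers >= 10
    apart: between/within distance ratio well above 5, n <= 8, group
    sizes >= 3 so the net-similarity optimum is not on a knife edge."""
    sizes = [(3, 3), (3, 4), (4, 4), (3, 5)][int(rng.integers(0, 4))]
    centers: list[np.ndarray] = []
    while len(centers) < len(sizes):
        c = rng.uniform(-20, 20, size=2)
        if all(np.linalg.norm(c - o) >= 10.0 for o in centers):
            centers.append(c)
    return np.vstack(
        [c + 0.5 * rng.uniform(-1, 1, size=(s, 2)) for c, s in zip(centers, sizes)]
    )


def rf_distance(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson-Foulds distance via a shared taxon namespace."""
    import dendropy.calculate.treecompare as tc

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(
        data=tree_a.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    t2 = dendropy.Tree.get(
        data=tree_b.as_string(schema="newick"), schema="newick", taxon_namespace=tns
    )
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(tc.symmetric_difference(t1, t2))
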