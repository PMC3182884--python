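"""Validation of clusterings and trees.

The Adjusted Rand Index (Hubert-Arabie form) scores the agreement of two
partitions from the pair-count contingency table:

    ARI = (Index - E[Index]) / (Max Index - E[Index])

with expected value 0 for independent partitions and maximum 1 for
identical ones; it is invariant to label permutations.

Tree agreement is measured by pairing the patristic distances of the two
trees over every unordered leaf pair and computing their correlation
(Pearson by default — a linear leaf-to-leaf relationship is the hallmark of
two trees that tell the same evolutionary story on different scales).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import pearsonr, spearmanr

from .tree import patristic_distances

__all__ = ["PartitionComparison", "adjusted_rand_index", "partition_comparison", "patristic_comparison"]


@dataclass
class PartitionComparison:
    contingency: pd.DataFrame
    ari: float
    n: int


def _align_labels(
    labels_a: Mapping[str, object] | Sequence[object],
    labels_b: Mapping[str, object] | Sequence[object],
) -> tuple[list[object], list[object]]:
    if isinstance(labels_a, Mapping) or isinstance(labels_b, Mapping):
        if not (isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping)):
            raise TypeError("supply both labelings as mappings or both as sequences")
        diff = set(labels_a) ^ set(labels_b)
        if diff:
            raise ValueError(f"labelings cover different ids: {sorted(map(str, diff))}")
        ids = sorted(labels_a)
        return [labels_a[i] for i in ids], [labels_b[i] for i in ids]
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"labelings have different sizes: {len(labels_a)} vs {len(labels_b)}"
        )
    return list(labels_a), list(labels_b)


def partition_comparison(labels_a, labels_b) -> PartitionComparison:
    """Contingency table and Hubert-Arabie ARI between two labelings.

    Labelings may be dicts keyed by sample id (ids must match exactly) or
    aligned sequences.
    """
    a, b = _align_labels(labels_a, labels_b)
    n = len(a)
    if n < 2:
        raise ValueError("ARI requires at least 2 samples")
    table = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    nij = table.to_numpy()
    sum_ij = comb(nij, 2).sum()
    sum_a = comb(nij.sum(axis=1), 2).sum()
    sum_b = comb(nij.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        ari = 1.0  # both partitions trivial (all-singletons or single cluster)
    else:
        ari = float((sum_ij - expected) / (max_index - expected))
    return PartitionComparison(contingency=table, ari=ari, n=n)


def adjusted_rand_index(labels_a, labels_b) -> float:
    return partition_comparison(labels_a, labels_b).ari


def patristic_comparison(
    tree_a: dendropy.Tree,
    tree_b: dendropy.Tree,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[pd.DataFrame, float]:
    """Pair the patristic distances of two trees over shared leaf pairs.

    Returns a table with one row per unordered leaf pair and the correlation
    between the two distance columns.
    """
    Da = patristic_distances(tree_a)
    Db = patristic_distances(tree_b)
    if Da.ids != Db.ids:
        raise ValueError(
            "trees have different leaf sets: "
            f"{sorted(set(Da.ids) ^ set(Db.ids))}"
        )
    n = Da.n
    iu = np.triu_indices(n, k=1)
    table = pd.DataFrame(
        {
            "leaf_1": [Da.ids[i] for i in iu[0]],
            "leaf_2": [Da.ids[j] for j in iu[1]],
            "distance_a": Da.values[iu],
            "distance_b": Db.values[iu],
        }
    )
    if method == "pearson":
        r = float(pearsonr(table["distance_a"], table["distance_b"]).statistic)
    elif method == "spearman":
        r = float(spearmanr(table["distance_a"], table["distance_b"]).statistic)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return table, r
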