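"""Synthetic sequence datasets with planted cluster and tree structure.

A random root sequence is evolved down a star-of-stars tree: g group
ancestors diverge from the root at the between-group rate, then each leaf
diverges from its ancestor at the within-group rate.  Substitutions are
i.i.d. per site with uniform choice among the alternative residues
(Jukes-Cantor-like); there are no indels, because the composition-vector
representation consumes ungapped text anyway.  The planted truth (group of
origin) and the generating tree (branch lengths = expected substitutions
per site, i.e. the rates) are returned alongside the sequences, so every
pipeline stage can be validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .seqio import LabelTable, SequenceRecord, write_fasta, write_labels
from .tree import write_newick

__all__ = [
    "SimulationSpec",
    "simulate_dataset",
    "write_dataset",
    "random_binary_tree",
    "separated_point_groups",
]

_DNA = np.array(list("ACGT"))
_PROTEIN = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimulationSpec:
    """Conditions for one planted-structure dataset.

    Defaults describe four well-separated groups of ten sequences — within
    groups ~1% of sites differ from the ancestor while groups sit ~15%
    (x2 branches) apart, comfortably below DNA saturation (0.75).
    """

    seed: int
    groups: int = 4
    per_group: int = 10
    length: int = 1000
    within_rate: float = 0.01
    between_rate: float = 0.15
    alphabet: str = "DNA"

    def __post_init__(self) -> None:
        saturation = 0.75 if self.alphabet == "DNA" else 0.95
        for name, rate in (("within_rate", self.within_rate), ("between_rate", self.between_rate)):
            if not (0.0 <= rate < saturation):
                raise ValueError(f"{name}={rate} outside [0, {saturation})")
        if self.length < 50:
            raise ValueError("length must be >= 50")
        if self.groups < 1 or self.per_group < 1:
            raise ValueError("groups and per_group must be >= 1")


def _mutate(seq: np.ndarray, rate: float, residues: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        # uniform choice among the 3 (or 19) alternative residues
        k = residues.size
        offsets = rng.integers(1, k, size=hit.size)
        idx = (np.searchsorted(residues, seq[hit]) + offsets) % k
        out[hit] = residues[idx]
    return out


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[SequenceRecord], LabelTable, dendropy.Tree]:
    """Generate (records, truth labels, true tree) from a simulation spec.

    Fully reproducible: the same seed yields byte-identical sequences.
    """
    rng = np.random.default_rng(spec.seed)
    residues = _DNA if spec.alphabet == "DNA" else _PROTEIN
    root = rng.choice(residues, size=spec.length)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for g in range(spec.groups):
        ancestor = _mutate(root, spec.between_rate, residues, rng)
        anc_node = dendropy.Node()
        tree.seed_node.add_child(anc_node)
        anc_node.edge.length = spec.between_rate
        for s in range(spec.per_group):
            leaf_seq = _mutate(ancestor, spec.within_rate, residues, rng)
            sid = f"g{g + 1}_s{s + 1}"
            records.append(
                SequenceRecord(
                    id=sid,
                    residues="".join(leaf_seq),
                    alphabet="DNA" if spec.alphabet == "DNA" else "PROTEIN",
                    description=f"group {g + 1}",
                )
            )
            labels[sid] = f"group{g + 1}"
            leaf = dendropy.Node(taxon=tns.new_taxon(label=sid))
            anc_node.add_child(leaf)
            leaf.edge.length = spec.within_rate
    tree.is_rooted = False
    return records, LabelTable(labels=labels, source=f"simulated(seed={spec.seed})"), tree


def random_binary_tree(n: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random binary unrooted tree with branch lengths uniform in [0.1, 2).

    Its patristic matrix is additive by construction, which makes it the
    standard input for neighbour-joining recovery checks.
    """
    tns = dendropy.TaxonNamespace()
    all_nodes = [dendropy.Node(taxon=tns.new_taxon(label=f"L{i}")) for i in range(n)]
    tree = dendropy.Tree(taxon_namespace=tns)
    active = list(range(n))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        parent = dendropy.Node()
        for child in (a, b):
            parent.add_child(all_nodes[child])
            all_nodes[child].edge.length = float(rng.uniform(0.1, 2.0))
        all_nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(all_nodes) - 1]
    for idx in active:
        tree.seed_node.add_child(all_nodes[idx])
        all_nodes[idx].edge.length = float(rng.uniform(0.1, 2.0))
    tree.is_rooted = False
    return tree


def separated_point_groups(rng: np.random.Generator) -> np.ndarray:
    """Two tight 2-D point groups (radius 0.5) of 3-5 points each, centers
    at least 10 apart (n <= 8): the standard instance family on which
    affinity propagation provably matches exhaustive exemplar search."""
    sizes = [(3, 3), (3, 4), (4, 4), (3, 5)][int(rng.integers(0, 4))]
    centers: list[np.ndarray] = []
    while len(centers) < len(sizes):
        c = rng.uniform(-20, 20, size=2)
        if all(np.linalg.norm(c - o) >= 10.0 for o in centers):
            centers.append(c)
    return np.vstack(
        [c + 0.5 * rng.uniform(-1, 1, size=(s, 2)) for c, s in zip(centers, sizes)]
    )


def write_dataset(
    spec: SimulationSpec, out_dir: str | Path, prefix: str = "sim"
) -> dict[str, Path]:
    """Materialize a simulated dataset as FASTA + truth TSV + Newick."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth, tree = simulate_dataset(spec)
    paths = {
        "fasta": out / f"{prefix}.fasta",
        "truth": out / f"{prefix}.truth.tsv",
        "tree": out / f"{prefix}.true_tree.nwk",
    }
    write_fasta(records, paths["fasta"])
    write_labels(truth, paths["truth"])
    write_newick(tree, paths["tree"])
    return paths
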