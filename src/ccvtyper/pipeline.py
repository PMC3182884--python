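"""End-to-end genotyping pipeline.

Per input segment (one multi-FASTA per gene): complete composition vectors
-> pooled background -> revised-relative-entropy feature selection ->
z-normalization -> distance matrix -> (a) preference-swept affinity
propagation clusters and (b) a neighbour-joining tree.  With several
segments, per-segment cluster labels are combined into composite genotype
profiles: samples sharing the label tuple across all segments share one
whole-genome genotype.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .ccv import CCVVectorizer
from .cluster import (
    ClusterResult,
    SweepReport,
    composite_genotypes,
    preference_sweep,
    similarity_from_distance,
)
from .distance import DistanceMatrix, distance_matrix, write_phylip_square
from .seqio import SequenceRecord, read_fasta
from .tree import neighbour_joining, write_newick

logger = logging.getLogger("ccvtyper")

__all__ = ["PipelineConfig", "SegmentResult", "run_segment", "genotype"]


@dataclass
class PipelineConfig:
    """Parameters of a genotyping run; defaults reproduce the method's
    standard settings (k = 3..9, |RE| >= 1.0, cosine distance, four-point
    preference sweep)."""

    inputs: list[str]
    out_dir: str = "ccvtyper_out"
    k_min: int = 3
    k_max: int = 9
    re_threshold: float = 1.0
    metric: str = "cosine"
    damping: float = 0.9
    max_iter: int = 1000
    convergence_iter: int = 100
    jitter: float = 0.0
    seed: int | None = None
    n_workers: int = 1
    absent_pi: str = "zero"

    def __post_init__(self) -> None:
        if not (3 <= self.k_min <= self.k_max):
            raise ValueError("need 3 <= k_min <= k_max")
        if self.re_threshold < 0:
            raise ValueError("re_threshold must be >= 0")
        if self.metric not in ("cosine", "euclidean"):
            raise ValueError(f"metric must be cosine or euclidean, got {self.metric!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class SegmentResult:
    name: str
    ids: list[str]
    features: list[str]
    distances: DistanceMatrix
    clusters: ClusterResult
    sweep: SweepReport
    tree: object  # dendropy.Tree
    n_candidate_features: int = 0


def run_segment(
    records: Sequence[SequenceRecord],
    name: str = "segment",
    k_min: int = 3,
    k_max: int = 9,
    re_threshold: float = 1.0,
    metric: str = "cosine",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 100,
    jitter: float = 0.0,
    seed: int | None = None,
    n_workers: int = 1,
    absent_pi: str = "zero",
) -> SegmentResult:
    """Run the full per-segment analysis in memory (no files)."""
    if len(records) < 3:
        raise ValueError(
            f"segment {name!r}: n >= 3 sequences required for the preference sweep, "
            f"got {len(records)}"
        )
    t0 = time.perf_counter()
    vec = CCVVectorizer(
        k_min=k_min, k_max=k_max, re_threshold=re_threshold, absent_pi=absent_pi
    ).fit(records)
    fm = vec.feature_matrix_
    if not fm.features:
        raise ValueError(
            f"segment {name!r}: no substring passed |RE| >= {re_threshold}; "
            "lower --re-threshold"
        )
    logger.info(
        "segment %s: %d sequences, %d/%d substrings retained (%.2fs)",
        name, len(fm.ids), len(fm.features), len(vec.re_scores_), time.perf_counter() - t0,
    )
    D = distance_matrix(fm.matrix, fm.ids, metric=metric, n_workers=n_workers)
    S = similarity_from_distance(D)
    clusters, sweep = preference_sweep(
        S,
        D,
        damping=damping,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
        jitter=jitter,
        seed=seed,
    )
    tree = neighbour_joining(D)
    logger.info(
        "segment %s: K=%d (preference %.4g, mean silhouette %.3f), total %.2fs",
        name, clusters.n_clusters, clusters.preference, clusters.mean_silhouette,
        time.perf_counter() - t0,
    )
    return SegmentResult(
        name=name,
        ids=fm.ids,
        features=fm.features,
        distances=D,
        clusters=clusters,
        sweep=sweep,
        tree=tree,
        n_candidate_features=len(vec.re_scores_),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def genotype(config: PipelineConfig) -> dict:
    """Run the pipeline over every input segment and write run artifacts.

    Writes, per segment: ``<seg>.clusters.tsv``, ``<seg>.tree.nwk``,
    ``<seg>.distances.phylip``, ``<seg>.sweep.json``; for multi-segment
    runs additionally ``genotypes.tsv``; always ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "ccvtyper",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "segments": {},
        "complete": False,
    }
    per_segment_labels: dict[str, dict[str, int]] = {}
    try:
        for inp in config.inputs:
            path = Path(inp)
            name = path.stem
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}
            records = read_fasta(path)
            seg = run_segment(
                records,
                name=name,
                k_min=config.k_min,
                k_max=config.k_max,
                re_threshold=config.re_threshold,
                metric=config.metric,
                damping=config.damping,
                max_iter=config.max_iter,
                convergence_iter=config.convergence_iter,
                jitter=config.jitter,
                seed=config.seed,
                n_workers=config.n_workers,
            )
            _write_clusters_tsv(seg, out / f"{name}.clusters.tsv")
            write_phylip_square(seg.distances, out / f"{name}.distances.phylip")
            write_newick(seg.tree, out / f"{name}.tree.nwk")
            (out / f"{name}.sweep.json").write_text(
                json.dumps(seg.sweep.to_dict(), indent=2) + "\n"
            )
            per_segment_labels[name] = seg.clusters.labels_by_id()
            manifest["segments"][name] = {
                "n_sequences": len(seg.ids),
                "n_retained_substrings": len(seg.features),
                "n_candidate_substrings": seg.n_candidate_features,
                "n_clusters": seg.clusters.n_clusters,
                "preference": seg.clusters.preference,
                "mean_silhouette": seg.clusters.mean_silhouette,
                "converged": seg.clusters.converged,
            }
        if len(per_segment_labels) > 1:
            profiles = composite_genotypes(per_segment_labels)
            _write_genotypes_tsv(profiles, list(per_segment_labels), out / "genotypes.tsv")
            manifest["n_composite_genotypes"] = len({p.genotype for p in profiles})
        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _write_clusters_tsv(seg: SegmentResult, path: Path) -> None:
    sil = seg.clusters.silhouette
    with path.open("w") as fh:
        fh.write("sample\tsegment\tcluster\texemplar\tsilhouette\n")
        for i, sid in enumerate(seg.ids):
            fh.write(
                f"{sid}\t{seg.name}\t{seg.clusters.labels[i]}\t"
                f"{int(i in seg.clusters.exemplar_indices)}\t"
                f"{sil.samples[i]:.6f}\n"
            )


def _write_genotypes_tsv(profiles, segment_names: list[str], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("sample\t" + "\t".join(segment_names) + "\tgenotype\n")
        for p in profiles:
            fh.write(
                p.sample_id
                + "\t"
                + "\t".join(str(l) for l in p.segment_labels)
                + f"\t{p.genotype}\n"
            )
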