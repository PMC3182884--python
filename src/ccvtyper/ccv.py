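"""Complete composition vectors (CCV) and revised relative entropy selection.

A sequence S of length L is represented without alignment by the composition
values of its k-mers for k = 3..M (default M = 9).  For a k-mer alpha,

    p(alpha) = f(alpha) / (L - k + 1)

is its observed occurrence probability over the L - k + 1 sliding windows,
and the Markov-model expectation from the (k-1)- and (k-2)-mer statistics is

    q(alpha) = p(alpha_1..alpha_{k-1}) * p(alpha_2..alpha_k) / p(alpha_2..alpha_{k-1}).

The composition value pi(alpha) = (p - q) / q (0 when q = 0) measures the
background-corrected deviation of the observed from the expected frequency,
highlighting selective rather than compositional signal.

Feature selection scores each substring by revised relative entropy against
the dataset-wide background vector Pi (the CCV of the pooled dataset):

    RE(alpha) = sum_i  pi(alpha, i) * ln( pi(alpha, i) / Pi(alpha) )

and keeps substrings with |RE| >= threshold (default 1.0).  Because
composition values may be negative or zero, a term contributes 0 whenever
pi = 0, Pi = 0, or the ratio is non-positive; this keeps RE finite and makes
it vanish exactly on a single-sequence dataset or when every sequence is
identical.  Retained columns are z-score normalized (population standard
deviation) and zero-variance columns are dropped.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import SequenceRecord, canonical_characters

__all__ = [
    "KmerCountTable",
    "CompositionVector",
    "BackgroundVector",
    "FeatureMatrix",
    "count_kmers",
    "probability",
    "expected_probability",
    "composition_value",
    "complete_composition_vector",
    "background_vector",
    "revised_relative_entropy",
    "select_features",
    "build_feature_matrix",
    "CCVVectorizer",
]


@dataclass
class KmerCountTable:
    """Sliding-window k-mer occurrence counts for one sequence.

    ``window_total`` is L - k + 1 — the denominator of p(alpha) — regardless
    of how many windows were skipped for ambiguity codes.
    """

    k: int
    counts: dict[str, int]
    window_total: int


@dataclass
class CompositionVector:
    """Sparse map substring -> pi(alpha) over k in [k_min, k_max] for one sequence."""

    sequence_id: str
    k_min: int
    k_max: int
    values: dict[str, float]


@dataclass
class BackgroundVector:
    """Composition values of the pooled dataset (the background Pi)."""

    values: dict[str, float]
    n: int
    k_min: int
    k_max: int


@dataclass
class FeatureMatrix:
    """Samples x retained substrings, z-normalized.

    ``matrix`` rows follow ``ids``; columns follow ``features`` (sorted by
    k then lexicographically).  ``mean`` and ``scale`` are the per-column
    statistics used for normalization; ``dropped`` lists zero-variance
    columns removed before normalization.
    """

    ids: list[str]
    features: list[str]
    matrix: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    re_values: dict[str, float] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    k_min: int = 3
    k_max: int = 9
    re_threshold: float = 1.0

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("id\t" + "\t".join(self.features) + "\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")
        if sidecar is not None:
            meta = {
                "k_min": self.k_min,
                "k_max": self.k_max,
                "re_threshold": self.re_threshold,
                "n_samples": len(self.ids),
                "n_features": len(self.features),
                "dropped_zero_variance": self.dropped,
                "re_values": {f: self.re_values[f] for f in self.features if f in self.re_values},
            }
            Path(sidecar).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            features = header[1:]
            ids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        m = np.asarray(rows, dtype=float)
        return cls(
            ids=ids,
            features=features,
            matrix=m,
            mean=np.zeros(m.shape[1]),
            scale=np.ones(m.shape[1]),
        )


def _feature_sort_key(s: str) -> tuple[int, str]:
    return (len(s), s)


def count_kmers(record: SequenceRecord | str, k: int) -> KmerCountTable:
    """Count the L - k + 1 overlapping length-k windows of a sequence.

    Windows containing a non-canonical character (IUPAC ambiguity code) are
    skipped, but ``window_total`` stays L - k + 1.
    """
    if isinstance(record, SequenceRecord):
        seq = record.residues
        canonical = canonical_characters(record.alphabet)
    else:
        seq = record
        canonical = canonical_characters("DNA")
    L = len(seq)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > L:
        raise ValueError(f"k={k} exceeds sequence length L={L}")
    counts = Counter(seq[i : i + k] for i in range(L - k + 1))
    if set(seq) - canonical:
        counts = Counter({kmer: c for kmer, c in counts.items() if set(kmer) <= canonical})
    return KmerCountTable(k=k, counts=dict(counts), window_total=L - k + 1)


def probability(table: KmerCountTable, alpha: str) -> float:
    """p(alpha) = f(alpha) / (L - k + 1); 0 for an unobserved substring."""
    if len(alpha) != table.k:
        raise ValueError(f"substring {alpha!r} has length {len(alpha)}, table k={table.k}")
    return table.counts.get(alpha, 0) / table.window_total


def expected_probability(
    table_km1: KmerCountTable, table_km2: KmerCountTable, alpha: str
) -> float:
    """Markov-model expected probability q(alpha) from (k-1)- and (k-2)-mers.

    Returns 0 when the denominator p(alpha_2..alpha_{k-1}) is 0.
    """
    k = len(alpha)
    if k < 3:
        raise ValueError(f"q(alpha) requires k >= 3, got k={k}")
    if table_km1.k != k - 1 or table_km2.k != k - 2:
        raise ValueError("count tables must have orders k-1 and k-2")
    denom = probability(table_km2, alpha[1:-1])
    if denom == 0.0:
        return 0.0
    return probability(table_km1, alpha[:-1]) * probability(table_km1, alpha[1:]) / denom


def composition_value(p: float, q: float) -> float:
    """pi = (p - q) / q for q > 0, else 0."""
    if q > 0.0:
        return (p - q) / q
    return 0.0


def _ccv_from_tables(
    tables: dict[int, KmerCountTable], k_min: int, k_max: int
) -> dict[str, float]:
    values: dict[str, float] = {}
    for k in range(k_min, k_max + 1):
        tk = tables.get(k)
        if tk is None:
            continue
        tk1, tk2 = tables[k - 1], tables[k - 2]
        wt_k, wt_k1, wt_k2 = tk.window_total, tk1.window_total, tk2.window_total
        c1, c2 = tk1.counts, tk2.counts
        for alpha, f in tk.counts.items():
            p = f / wt_k
            mid = c2.get(alpha[1:-1], 0)
            if mid == 0:
                values[alpha] = 0.0
                continue
            q = (c1.get(alpha[:-1], 0) / wt_k1) * (c1.get(alpha[1:], 0) / wt_k1) / (mid / wt_k2)
            values[alpha] = (p - q) / q if q > 0.0 else 0.0
    return values


def complete_composition_vector(
    record: SequenceRecord, k_min: int = 3, k_max: int = 9
) -> CompositionVector:
    """CCV of one sequence: pi(alpha) for every observed alpha, k in [k_min, k_max].

    Substrings with p = 0 are omitted (sparse representation).  Orders with
    k > L yield no windows and are silently empty; the hard floor is
    L >= k_min + 2 so that the (k-2)-mer statistics exist.
    """
    if k_min < 3:
        raise ValueError(f"k_min must be >= 3, got {k_min}")
    if k_max < k_min:
        raise ValueError(f"k_max ({k_max}) < k_min ({k_min})")
    L = len(record.residues)
    if L < k_min:
        raise ValueError(
            f"record {record.id!r} has length {L} < k_min = {k_min}; "
            "too short for composition-vector statistics"
        )
    top = min(k_max, L)
    tables = {k: count_kmers(record, k) for k in range(k_min - 2, top + 1)}
    return CompositionVector(
        sequence_id=record.id,
        k_min=k_min,
        k_max=k_max,
        values=_ccv_from_tables(tables, k_min, top),
    )


def background_vector(
    records: Sequence[SequenceRecord], k_min: int = 3, k_max: int = 9
) -> BackgroundVector:
    """CCV of the pooled dataset: counts summed per k across all sequences.

    Windows never span two sequences; window totals are summed.  This equals
    the "concatenation of all sequences" with boundary windows excluded, and
    for n = 1 it reduces exactly to that sequence's CCV.
    """
    if not records:
        raise ValueError("background_vector requires at least one record")
    alphabets = {r.alphabet for r in records}
    if len(alphabets) != 1:
        raise ValueError(f"mixed alphabets in dataset: {sorted(alphabets)}")
    top = min(k_max, max(len(r) for r in records))
    pooled: dict[int, KmerCountTable] = {}
    for k in range(k_min - 2, top + 1):
        counts: Counter[str] = Counter()
        total = 0
        for r in records:
            if k > len(r):
                continue
            t = count_kmers(r, k)
            counts.update(t.counts)
            total += t.window_total
        pooled[k] = KmerCountTable(k=k, counts=dict(counts), window_total=total)
    return BackgroundVector(
        values=_ccv_from_tables(pooled, k_min, top),
        n=len(records),
        k_min=k_min,
        k_max=k_max,
    )


def revised_relative_entropy(
    vectors: Sequence[CompositionVector], background: BackgroundVector
) -> dict[str, float]:
    """RE(alpha) = sum_i pi(alpha, i) * ln(pi(alpha, i) / Pi(alpha)).

    A term contributes 0 when pi = 0, Pi = 0, or the ratio is non-positive.
    """
    ranges = {(v.k_min, v.k_max) for v in vectors}
    if ranges and ranges != {(background.k_min, background.k_max)}:
        raise ValueError(
            f"vector k ranges {sorted(ranges)} do not match background "
            f"({background.k_min}, {background.k_max})"
        )
    keys: set[str] = set()
    for v in vectors:
        keys.update(v.values)
    order = sorted(keys, key=_feature_sort_key)
    index = {a: j for j, a in enumerate(order)}
    pi_bg = np.array([background.values.get(a, 0.0) for a in order])
    re = np.zeros(len(order))
    for v in vectors:
        if not v.values:
            continue
        idx = np.fromiter((index[a] for a in v.values), dtype=np.intp, count=len(v.values))
        pi = np.fromiter(v.values.values(), dtype=float, count=len(v.values))
        bg = pi_bg[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(bg != 0.0, pi / bg, 0.0)
        valid = (pi != 0.0) & (ratio > 0.0)
        contrib = np.where(valid, pi * np.log(np.where(valid, ratio, 1.0)), 0.0)
        np.add.at(re, idx, contrib)
    return {a: float(re[j]) for a, j in index.items()}


def select_features(re_map: dict[str, float], threshold: float = 1.0) -> list[str]:
    """Substrings with |RE| >= threshold, ordered by (k, substring)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return sorted(
        (a for a, v in re_map.items() if abs(v) >= threshold), key=_feature_sort_key
    )


def build_feature_matrix(
    vectors: Sequence[CompositionVector],
    retained: Sequence[str],
    re_values: dict[str, float] | None = None,
    absent_pi: Literal["zero", "minus-one"] = "zero",
    k_min: int = 3,
    k_max: int = 9,
    re_threshold: float = 1.0,
) -> FeatureMatrix:
    """Assemble and z-normalize the samples x retained-substrings matrix.

    A substring absent from a sequence contributes ``absent_pi`` (0 by
    default; "minus-one" scores it as p = 0 against a positive expectation).
    Columns with zero population variance are dropped and recorded.
    """
    if len(vectors) < 2:
        raise ValueError(
            "z-score normalization needs at least 2 sequences; "
            "use the raw composition vectors for a single sequence"
        )
    fill = 0.0 if absent_pi == "zero" else -1.0
    cols = sorted(retained, key=_feature_sort_key)
    col_index = {a: j for j, a in enumerate(cols)}
    m = np.full((len(vectors), len(cols)), fill, dtype=float)
    for i, v in enumerate(vectors):
        for a, pi in v.values.items():
            j = col_index.get(a)
            if j is not None:
                m[i, j] = pi
    mean = m.mean(axis=0)
    sd = m.std(axis=0)  # population standard deviation
    keep = sd > 0.0
    dropped = [a for a, k in zip(cols, keep) if not k]
    kept_cols = [a for a, k in zip(cols, keep) if k]
    z = (m[:, keep] - mean[keep]) / sd[keep]
    return FeatureMatrix(
        ids=[v.sequence_id for v in vectors],
        features=kept_cols,
        matrix=z,
        mean=mean[keep],
        scale=sd[keep],
        re_values=dict(re_values or {}),
        dropped=dropped,
        k_min=k_min,
        k_max=k_max,
        re_threshold=re_threshold,
    )


class CCVVectorizer(TransformerMixin, BaseEstimator):
    """Transform sequence records into z-normalized CCV feature rows.

    ``fit`` computes per-sequence composition vectors, the pooled background,
    revised-relative-entropy feature selection and the z-normalization
    statistics from the fitted dataset; ``transform`` projects records onto
    the retained substrings using those statistics, so held-out sequences can
    be embedded in the fitted feature space.

    Parameters
    ----------
    k_min, k_max
        Range of k-mer orders; the composition vector concatenates all of
        them (default 3..9).
    re_threshold
        Minimum |RE| for a substring to be retained (default 1.0).
    absent_pi
        Composition value assigned to a retained substring that a sequence
        does not contain: "zero" (default) or "minus-one".
    """

    def __init__(
        self,
        k_min: int = 3,
        k_max: int = 9,
        re_threshold: float = 1.0,
        absent_pi: Literal["zero", "minus-one"] = "zero",
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.re_threshold = re_threshold
        self.absent_pi = absent_pi

    def fit(self, X: Sequence[SequenceRecord], y=None) -> "CCVVectorizer":
        records = list(X)
        vectors = [
            complete_composition_vector(r, self.k_min, self.k_max) for r in records
        ]
        background = background_vector(records, self.k_min, self.k_max)
        re_map = revised_relative_entropy(vectors, background)
        retained = select_features(re_map, self.re_threshold)
        fm = build_feature_matrix(
            vectors,
            retained,
            re_values=re_map,
            absent_pi=self.absent_pi,
            k_min=self.k_min,
            k_max=self.k_max,
            re_threshold=self.re_threshold,
        )
        self.background_ = background
        self.re_scores_ = re_map
        self.features_ = fm.features
        self.mean_ = fm.mean
        self.scale_ = fm.scale
        self.dropped_features_ = fm.dropped
        self.feature_matrix_ = fm
        self.ids_ = fm.ids
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> np.ndarray:
        if not hasattr(self, "features_"):
            raise RuntimeError("CCVVectorizer is not fitted")
        fill = 0.0 if self.absent_pi == "zero" else -1.0
        col_index = {a: j for j, a in enumerate(self.features_)}
        m = np.full((len(X), len(self.features_)), fill, dtype=float)
        for i, r in enumerate(X):
            v = complete_composition_vector(r, self.k_min, self.k_max)
            for a, pi in v.values.items():
                j = col_index.get(a)
                if j is not None:
                    m[i, j] = pi
        return (m - self.mean_) / self.scale_

    def fit_transform(self, X: Sequence[SequenceRecord], y=None) -> np.ndarray:
        return self.fit(X).feature_matrix_.matrix
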