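"""Genotyping by affinity propagation with silhouette-driven model selection.

Affinity propagation (AP) treats every sample as a potential exemplar and
exchanges two kinds of messages over a similarity matrix s(i, k):

    responsibility  r(i,k) = s(i,k) - max_{k' != k} [ a(i,k') + s(i,k') ]
    availability    a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
                    a(k,k) = sum_{i' != k} max(0, r(i',k))

both damped by a factor lambda.  The shared self-similarity ("preference")
on the diagonal controls how readily points become exemplars and therefore
the number of clusters, without fixing K in advance.  Exemplars are the
points with r(k,k) + a(k,k) > 0; every other point joins the exemplar it is
most similar to.  The run is fully deterministic: no noise is added and
argmax ties break toward the lowest index.

Similarities come from the distance matrix: s = 1 - D for cosine distances
(which live in [0, 1]) and s = -D for Euclidean or Manhattan distances.

The preference is selected by sweeping four equally spaced values between
the minimum and the median off-diagonal similarity and keeping the run with
the highest mean silhouette, s(i) = (b_i - a_i) / max(a_i, b_i), computed
from the distance matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distance import DistanceMatrix, distance_matrix

__all__ = [
    "SimilarityMatrix",
    "ClusterResult",
    "GenotypeProfile",
    "similarity_from_distance",
    "affinity_propagation",
    "silhouette",
    "preference_sweep",
    "composite_genotypes",
    "exhaustive_exemplar_search",
    "AffinityPropagation",
    "PreferenceSweepAP",
]


@dataclass
class SimilarityMatrix:
    """Pairwise similarities s(i, k); the diagonal is set per AP run."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match ids")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.values[off])):
            raise ValueError("similarity matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def off_diagonal(self) -> np.ndarray:
        n = self.n
        if n < 2:
            return np.array([])
        return self.values[~np.eye(n, dtype=bool)]


@dataclass
class SilhouetteReport:
    mean: float
    samples: np.ndarray
    a: np.ndarray
    b: np.ndarray


@dataclass
class ClusterResult:
    """Outcome of one affinity-propagation run."""

    ids: list[str]
    labels: np.ndarray  # dense cluster labels 0..K-1
    exemplar_of: np.ndarray  # index of each sample's exemplar
    exemplar_indices: np.ndarray  # sorted unique exemplars
    preference: float
    n_iter: int
    converged: bool
    silhouette: SilhouetteReport | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.exemplar_indices)

    @property
    def mean_silhouette(self) -> float:
        return self.silhouette.mean if self.silhouette is not None else float("nan")

    def labels_by_id(self) -> dict[str, int]:
        return {sid: int(lab) for sid, lab in zip(self.ids, self.labels)}


@dataclass
class GenotypeProfile:
    """Per-sample tuple of per-segment cluster labels; identical tuples share
    one composite genotype id."""

    sample_id: str
    segment_labels: tuple[int, ...]
    genotype: int


def similarity_from_distance(D: DistanceMatrix) -> SimilarityMatrix:
    """cosine -> s = 1 - D; euclidean/manhattan -> s = -D."""
    if D.metric == "cosine":
        s = 1.0 - D.values
    elif D.metric in ("euclidean", "manhattan"):
        s = -D.values
    else:
        raise ValueError(
            f"no similarity rule for metric {D.metric!r}; expected cosine, "
            "euclidean or manhattan"
        )
    return SimilarityMatrix(ids=list(D.ids), values=s)


def affinity_propagation(
    S: SimilarityMatrix,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 100,
    jitter: float = 0.0,
    seed: int | None = None,
) -> ClusterResult:
    """Deterministic affinity propagation at a fixed scalar preference.

    Convergence is declared when the exemplar set is unchanged for
    ``convergence_iter`` consecutive sweeps.  ``jitter`` adds tiny seeded
    noise to the similarities to break degenerate oscillations; it is off by
    default because it breaks bit-reproducibility.
    """
    n = S.n
    if n == 0:
        raise ValueError("cannot cluster an empty dataset")
    if not (0.5 <= damping < 1.0):
        raise ValueError(f"damping must be in [0.5, 1), got {damping}")
    if n == 1:
        return ClusterResult(
            ids=list(S.ids),
            labels=np.zeros(1, dtype=int),
            exemplar_of=np.zeros(1, dtype=int),
            exemplar_indices=np.zeros(1, dtype=int),
            preference=preference,
            n_iter=0,
            converged=True,
        )

    s = S.values.copy()
    np.fill_diagonal(s, preference)
    if jitter:
        rng = np.random.default_rng(seed)
        s = s + jitter * rng.standard_normal(s.shape)
    if not np.all(np.isfinite(s)):
        raise ValueError("similarity matrix contains non-finite entries")

    A = np.zeros((n, n))
    R = np.zeros((n, n))
    rows = np.arange(n)
    stable = 0
    prev_exemplars: np.ndarray | None = None
    n_iter = 0
    converged = False

    for n_iter in range(1, max_iter + 1):
        # responsibilities
        AS = A + s
        first_idx = np.argmax(AS, axis=1)  # ties -> lowest index
        first_val = AS[rows, first_idx]
        AS[rows, first_idx] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = s - first_val[:, None]
        Rnew[rows, first_idx] = s[rows, first_idx] - second_val
        R = damping * R + (1.0 - damping) * Rnew

        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diagonal(R))
        col_sums = Rp.sum(axis=0)
        Anew = col_sums[None, :] - Rp
        diag_new = np.diagonal(Anew).copy()
        np.minimum(Anew, 0.0, out=Anew)
        np.fill_diagonal(Anew, diag_new)
        A = damping * A + (1.0 - damping) * Anew

        exemplars = np.flatnonzero(np.diagonal(R) + np.diagonal(A) > 0.0)
        if prev_exemplars is not None and np.array_equal(exemplars, prev_exemplars):
            stable += 1
            if stable >= convergence_iter and exemplars.size > 0:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    exemplars = np.flatnonzero(np.diagonal(R) + np.diagonal(A) > 0.0)
    if exemplars.size == 0:
        # degenerate run: fall back to the single best self-evidence point
        exemplars = np.array([int(np.argmax(np.diagonal(R) + np.diagonal(A)))])
        converged = False

    # refinement (as in the reference implementation): within each cluster,
    # re-elect the member that maximizes the intra-cluster similarity sum
    assign = np.argmax(s[:, exemplars], axis=1)
    assign[exemplars] = np.arange(exemplars.size)
    refined = []
    for k in range(exemplars.size):
        ii = np.flatnonzero(assign == k)
        j = int(np.argmax(s[np.ix_(ii, ii)].sum(axis=0)))  # ties -> lowest index
        refined.append(int(ii[j]))
    exemplars = np.array(sorted(set(refined)), dtype=int)

    exemplar_of = exemplars[np.argmax(s[:, exemplars], axis=1)]
    exemplar_of[exemplars] = exemplars
    label_of = {int(e): lab for lab, e in enumerate(exemplars)}
    labels = np.array([label_of[int(e)] for e in exemplar_of], dtype=int)
    return ClusterResult(
        ids=list(S.ids),
        labels=labels,
        exemplar_of=exemplar_of,
        exemplar_indices=exemplars,
        preference=preference,
        n_iter=n_iter,
        converged=converged,
    )


def silhouette(labels: Sequence[int] | np.ndarray, D: DistanceMatrix) -> SilhouetteReport:
    """Per-sample silhouettes s(i) = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the sample's own-cluster co-members and b_i
    the smallest mean distance to any other cluster.  Samples in singleton
    clusters score 0; a single-cluster partition gets the sentinel mean -1
    (no separation can be measured, so it can never win model selection).
    """
    labels = np.asarray(labels, dtype=int)
    n = D.n
    if labels.shape[0] != n:
        raise ValueError(f"{labels.shape[0]} labels for {n} samples")
    uniq = np.unique(labels)
    d = D.values
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    if uniq.size == 1:
        return SilhouetteReport(mean=-1.0, samples=s, a=a, b=b)
    members = {int(c): np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[int(labels[i])]
        others = [members[int(c)] for c in uniq if c != labels[i]]
        b[i] = min(d[i, idx].mean() for idx in others)
        if own.size == 1:
            a[i] = 0.0
            s[i] = 0.0
            continue
        a[i] = d[i, own].sum() / (own.size - 1)
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0.0 else (b[i] - a[i]) / denom
    return SilhouetteReport(mean=float(s.mean()), samples=s, a=a, b=b)


@dataclass
class SweepEntry:
    preference: float
    n_clusters: int
    mean_silhouette: float
    converged: bool


@dataclass
class SweepReport:
    entries: list[SweepEntry]
    chosen_preference: float

    def to_dict(self) -> dict:
        return {
            "chosen_preference": self.chosen_preference,
            "candidates": [
                {
                    "preference": e.preference,
                    "n_clusters": e.n_clusters,
                    "mean_silhouette": e.mean_silhouette,
                    "converged": e.converged,
                }
                for e in self.entries
            ],
        }


def preference_sweep(
    S: SimilarityMatrix,
    D: DistanceMatrix,
    n_preferences: int = 4,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 100,
    jitter: float = 0.0,
    seed: int | None = None,
) -> tuple[ClusterResult, SweepReport]:
    """Run AP at preferences spanning the minimum-to-median similarity.

    Four equally spaced preferences (inclusive endpoints) are evaluated and
    the run with the highest mean silhouette wins; ties prefer fewer
    clusters, then the lower preference.
    """
    if S.n < 3:
        raise ValueError("preference sweep requires n >= 3 samples")
    off = S.off_diagonal()
    lo, med = float(off.min()), float(np.median(off))
    if lo == med:
        warnings.warn(
            "all off-diagonal similarities are equal; running a single "
            "degenerate preference",
            stacklevel=2,
        )
        prefs = np.array([lo])
    else:
        prefs = np.linspace(lo, med, n_preferences)
    entries: list[SweepEntry] = []
    results: list[ClusterResult] = []
    for p in prefs:
        res = affinity_propagation(
            S,
            preference=float(p),
            damping=damping,
            max_iter=max_iter,
            convergence_iter=convergence_iter,
            jitter=jitter,
            seed=seed,
        )
        res.silhouette = silhouette(res.labels, D)
        results.append(res)
        entries.append(
            SweepEntry(
                preference=float(p),
                n_clusters=res.n_clusters,
                mean_silhouette=res.mean_silhouette,
                converged=res.converged,
            )
        )
    best = min(
        range(len(results)),
        key=lambda i: (
            -results[i].mean_silhouette,
            results[i].n_clusters,
            results[i].preference,
        ),
    )
    return results[best], SweepReport(entries=entries, chosen_preference=float(prefs[best]))


def composite_genotypes(
    per_segment: dict[str, dict[str, int]],
    segment_order: Sequence[str] | None = None,
) -> list[GenotypeProfile]:
    """Combine per-segment cluster labels into whole-genome genotypes.

    Each sample gets a tuple of labels in fixed segment order; distinct
    tuples are numbered 1..G in order of first appearance.
    """
    if not per_segment:
        raise ValueError("no segments supplied")
    segments = list(segment_order) if segment_order is not None else list(per_segment)
    sample_ids = list(per_segment[segments[0]])
    for seg in segments:
        missing = set(sample_ids) ^ set(per_segment[seg])
        if missing:
            raise ValueError(
                f"segment {seg!r} sample ids differ from the first segment: "
                f"{sorted(missing)}"
            )
    genotype_of: dict[tuple[int, ...], int] = {}
    profiles: list[GenotypeProfile] = []
    for sid in sample_ids:
        tup = tuple(int(per_segment[seg][sid]) for seg in segments)
        if tup not in genotype_of:
            genotype_of[tup] = len(genotype_of) + 1
        profiles.append(GenotypeProfile(sample_id=sid, segment_labels=tup, genotype=genotype_of[tup]))
    return profiles


def exhaustive_exemplar_search(
    S: SimilarityMatrix, preference: float
) -> tuple[tuple[int, ...], float]:
    """Globally optimal exemplar set for the net-similarity objective.

    Enumerates every non-empty exemplar subset (exponential; intended for
    n <= ~12 as an independent oracle) and maximizes
    sum_i max_{e in E} s(i, e) + |E| * preference, with exemplars counted
    through the preference term only.
    """
    n = S.n
    s = S.values
    best: tuple[float, tuple[int, ...]] | None = None
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            E = np.array(subset)
            mask = np.ones(n, dtype=bool)
            mask[E] = False
            net = r * preference + s[np.ix_(mask, E)].max(axis=1).sum() if mask.any() else r * preference
            if best is None or net > best[0] + 1e-12:
                best = (net, subset)
    assert best is not None
    return best[1], best[0]


class AffinityPropagation(ClusterMixin, BaseEstimator):
    """sklearn-style estimator: cluster feature rows (or a precomputed
    distance matrix) by affinity propagation at a fixed preference.

    Parameters
    ----------
    metric : "cosine", "euclidean" or "precomputed"
        With "precomputed", ``fit`` expects a :class:`DistanceMatrix`.
    preference : float or None
        Shared self-similarity; ``None`` uses the median off-diagonal
        similarity (the moderate-cluster-count setting).
    """

    def __init__(
        self,
        metric: Literal["cosine", "euclidean", "precomputed"] = "cosine",
        preference: float | None = None,
        damping: float = 0.9,
        max_iter: int = 1000,
        convergence_iter: int = 100,
    ):
        self.metric = metric
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter

    def _distances(self, X, ids) -> DistanceMatrix:
        if self.metric == "precomputed":
            if not isinstance(X, DistanceMatrix):
                raise TypeError("metric='precomputed' expects a DistanceMatrix")
            return X
        X = np.asarray(X, dtype=float)
        ids = list(ids) if ids is not None else [str(i) for i in range(X.shape[0])]
        return distance_matrix(X, ids, metric=self.metric)

    def fit(self, X, y=None, ids: Sequence[str] | None = None) -> "AffinityPropagation":
        D = self._distances(X, ids)
        S = similarity_from_distance(D)
        pref = (
            float(np.median(S.off_diagonal()))
            if self.preference is None
            else self.preference
        )
        res = affinity_propagation(
            S,
            preference=pref,
            damping=self.damping,
            max_iter=self.max_iter,
            convergence_iter=self.convergence_iter,
        )
        res.silhouette = silhouette(res.labels, D)
        self.result_ = res
        self.labels_ = res.labels
        self.cluster_centers_indices_ = res.exemplar_indices
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.preference_ = pref
        return self

    def fit_predict(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, **kw).labels_


class PreferenceSweepAP(ClusterMixin, BaseEstimator):
    """Affinity propagation with the preference selected by mean silhouette
    over four values spanning the minimum-to-median similarity."""

    def __init__(
        self,
        metric: Literal["cosine", "euclidean", "precomputed"] = "cosine",
        n_preferences: int = 4,
        damping: float = 0.9,
        max_iter: int = 1000,
        convergence_iter: int = 100,
    ):
        self.metric = metric
        self.n_preferences = n_preferences
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter

    def fit(self, X, y=None, ids: Sequence[str] | None = None) -> "PreferenceSweepAP":
        if self.metric == "precomputed":
            if not isinstance(X, DistanceMatrix):
                raise TypeError("metric='precomputed' expects a DistanceMatrix")
            D = X
        else:
            Xa = np.asarray(X, dtype=float)
            the_ids = list(ids) if ids is not None else [str(i) for i in range(Xa.shape[0])]
            D = distance_matrix(Xa, the_ids, metric=self.metric)
        S = similarity_from_distance(D)
        res, report = preference_sweep(
            S,
            D,
            n_preferences=self.n_preferences,
            damping=self.damping,
            max_iter=self.max_iter,
            convergence_iter=self.convergence_iter,
        )
        self.result_ = res
        self.sweep_report_ = report
        self.labels_ = res.labels
        self.cluster_centers_indices_ = res.exemplar_indices
        self.preference_ = res.preference
        self.mean_silhouette_ = res.mean_silhouette
        return self

    def fit_predict(self, X, y=None, **kw) -> np.ndarray:
        return self.fit(X, **kw).labels_
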