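"""Pairwise distance matrices over feature vectors, plus exchange formats.

Cosine distance follows the composition-vector convention D = (1 - C) / 2
with C the cosine of the angle between the two feature rows, so D lies in
[0, 1]: identical directions give 0, opposite directions give 1, and the
clustering similarity s = 1 - D increases monotonically with C.

Matrix exchange formats: PHYLIP square, a packed strictly-lower-triangle
text dialect (row-major, suited to streaming neighbour joining), and a
labelled TSV for spreadsheets.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DistanceMatrix",
    "cosine_distance",
    "euclidean_distance",
    "distance_matrix",
    "write_phylip_square",
    "read_phylip_square",
    "write_packed_rows",
    "read_packed_rows",
    "write_tsv_matrix",
]

_ROW_CHUNK = 128  # fixed chunk size so worker count cannot change results


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix with a metric tag."""

    ids: list[str]
    values: np.ndarray
    metric: str = "cosine"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])


def cosine_distance(v_i: np.ndarray, v_j: np.ndarray) -> float:
    """D = (1 - C) / 2 in [0, 1]; errors on a zero vector."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    ni, nj = np.linalg.norm(v_i), np.linalg.norm(v_j)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    c = float(np.dot(v_i, v_j) / (ni * nj))
    return min(1.0, max(0.0, (1.0 - c) / 2.0))


def euclidean_distance(v_i: np.ndarray, v_j: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(v_i, float) - np.asarray(v_j, float)))


def _cosine_block(N: np.ndarray, rows: slice) -> np.ndarray:
    return (1.0 - N[rows] @ N.T) / 2.0


def _euclidean_block(X: np.ndarray, rows: slice) -> np.ndarray:
    out = np.empty((rows.stop - rows.start, X.shape[0]))
    for r, i in enumerate(range(rows.start, rows.stop)):
        out[r] = np.sqrt(((X[i] - X) ** 2).sum(axis=1))
    return out


def distance_matrix(
    X: np.ndarray,
    ids: Sequence[str],
    metric: Literal["cosine", "euclidean"] = "cosine",
    n_workers: int = 1,
) -> DistanceMatrix:
    """All-pairs distances over the rows of X.

    Rows are processed in fixed-size chunks; ``n_workers`` only parallelizes
    across those chunks (threads), so the result is byte-identical for any
    worker count.  Symmetry and the zero diagonal are enforced exactly by
    mirroring the upper triangle.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(ids):
        raise ValueError("X must be 2-D with one row per id")
    if X.shape[0] < 2:
        raise ValueError("distance matrix requires at least 2 samples")
    n = X.shape[0]
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0.0)
        if zero.size:
            raise ValueError(
                f"zero feature vector for sample {ids[zero[0]]!r}; "
                "cosine distance is undefined"
            )
        N = X / norms[:, None]
        block = lambda rows: _cosine_block(N, rows)  # noqa: E731
    elif metric == "euclidean":
        block = lambda rows: _euclidean_block(X, rows)  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")

    D = np.empty((n, n), dtype=float)
    chunks = [slice(s, min(s + _ROW_CHUNK, n)) for s in range(0, n, _ROW_CHUNK)]
    if n_workers > 1 and len(chunks) > 1:
        with concurrent.futures.ThreadPoolExecutor(max_workers=n_workers) as ex:
            for rows, out in zip(chunks, ex.map(block, chunks)):
                D[rows] = out
    else:
        for rows in chunks:
            D[rows] = block(rows)
    # exact symmetry: keep the upper triangle, mirror it, zero the diagonal
    iu = np.triu_indices(n, k=1)
    D[(iu[1], iu[0])] = D[iu]
    np.fill_diagonal(D, 0.0)
    if metric == "cosine":
        np.clip(D, 0.0, 1.0, out=D)
    return DistanceMatrix(ids=list(ids), values=D, metric=metric)


def write_phylip_square(D: DistanceMatrix, path: str | Path, classic_names: bool = False) -> None:
    """PHYLIP square format: count line, then one row per sample.

    Values use 6 fixed decimal places.  ``classic_names`` pads/truncates
    names to the classic 10-character field; by default names are written
    as-is (relaxed PHYLIP).
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{D.n}\n")
        for sid, row in zip(D.ids, D.values):
            name = f"{sid[:10]:<10}" if classic_names else sid
            fh.write(name + " " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip_square(path: str | Path, metric: str = "unknown") -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().split()
        if not first:
            raise ValueError(f"{path}:1: missing sample count line")
        try:
            n = int(first[0])
        except ValueError as exc:
            raise ValueError(f"{path}:1: malformed count line {first!r}") from exc
        ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != n + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected name + {n} values, got {len(parts)} fields"
                )
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if len(rows) != n:
        raise ValueError(f"{path}: header says {n} rows but found {len(rows)}")
    values = np.asarray(rows)
    values = (values + values.T) / 2.0  # 6-decimal text can break exact symmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=ids, values=values, metric=metric)


def write_packed_rows(D: DistanceMatrix, path: str | Path) -> None:
    """Strictly-lower-triangle packed text: header "n label0", then for
    i = 1..n-1 a line with label_i followed by D(i, 0..i-1)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{D.n} {D.ids[0]}\n")
        for i in range(1, D.n):
            fh.write(D.ids[i] + " " + " ".join(f"{v:.6f}" for v in D.values[i, :i]) + "\n")


def read_packed_rows(path: str | Path, metric: str = "unknown") -> DistanceMatrix:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().split()
        if len(first) != 2:
            raise ValueError(f"{path}:1: expected 'n label0' header")
        n = int(first[0])
        ids = [first[1]]
        values = np.zeros((n, n))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            i = len(ids)
            if i >= n:
                raise ValueError(f"{path}:{lineno}: more rows than header count {n}")
            if len(parts) != i + 1:
                raise ValueError(
                    f"{path}:{lineno}: row {i} must hold a label and {i} values, "
                    f"got {len(parts)} fields"
                )
            ids.append(parts[0])
            row = [float(v) for v in parts[1:]]
            values[i, :i] = row
            values[:i, i] = row
    if len(ids) != n:
        raise ValueError(f"{path}: header says {n} samples but found {len(ids)}")
    return DistanceMatrix(ids=ids, values=values, metric=metric)


def write_tsv_matrix(D: DistanceMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(D.ids) + "\n")
        for sid, row in zip(D.ids, D.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
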