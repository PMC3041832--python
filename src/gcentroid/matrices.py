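"""Probability-matrix containers and their TSV serialization.

Two marginal-probability matrices drive every estimator here:

* :class:`MatchProbMatrix` — aligned-base (matching) probabilities
  p(x_i ~ y_j), an m x n matrix whose row and column sums cannot exceed 1
  because an alignment is one-to-one in each coordinate;
* :class:`BasePairProbMatrix` — base-pairing probabilities p_ij, a strictly
  upper-triangular L x L matrix in which the total probability mass touching
  any one position cannot exceed 1 because a base joins at most one pair.

The on-disk dialect is a plain TSV: a header line ``#dims m n`` followed by
0-based ``i<TAB>j<TAB>p`` triples; absent entries are zero.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MatchProbMatrix",
    "BasePairProbMatrix",
    "load_matrix",
    "save_matrix",
]

_TOL = 1e-9


class MatchProbMatrix:
    """Aligned-base probability matrix with one-to-one marginal invariants."""

    def __init__(self, values, tol: float = _TOL):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("match-probability matrix must be 2-D")
        if np.any(values < -tol) or np.any(values > 1 + tol):
            raise ValueError("match probabilities must lie in [0, 1]")
        rows = values.sum(axis=1)
        cols = values.sum(axis=0)
        if np.any(rows > 1 + 1e-6) or np.any(cols > 1 + 1e-6):
            raise ValueError(
                "row/column sums exceed 1: inconsistent with the one-to-one "
                "alignment constraint"
            )
        self.values = np.clip(values, 0.0, 1.0)

    @property
    def shape(self):
        return self.values.shape

    @property
    def len_x(self) -> int:
        return self.values.shape[0]

    @property
    def len_y(self) -> int:
        return self.values.shape[1]

    def __getitem__(self, idx):
        return self.values[idx]

    def gap_probs(self):
        """(q_x, q_y): probability of each position being unaligned."""
        qx = np.clip(1.0 - self.values.sum(axis=1), 0.0, 1.0)
        qy = np.clip(1.0 - self.values.sum(axis=0), 0.0, 1.0)
        return qx, qy


class BasePairProbMatrix:
    """Base-pairing probability matrix; strictly upper-triangular."""

    def __init__(self, values, tol: float = _TOL):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("base-pair probability matrix must be square")
        if np.any(np.tril(values) != 0.0):
            raise ValueError("matrix must be strictly upper-triangular")
        if np.any(values < -tol) or np.any(values > 1 + tol):
            raise ValueError("base-pair probabilities must lie in [0, 1]")
        sums = values.sum(axis=0) + values.sum(axis=1)
        if np.any(sums > 1 + 1e-6):
            raise ValueError(
                "per-position pair-probability sums exceed 1: a base can join "
                "at most one pair"
            )
        self.values = np.clip(values, 0.0, 1.0)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, idx):
        return self.values[idx]

    def position_sums(self):
        return self.values.sum(axis=0) + self.values.sum(axis=1)

    def unpaired_probs(self):
        """q_i = 1 - sum of pair probabilities touching position i."""
        return np.clip(1.0 - self.position_sums(), 0.0, 1.0)


def load_matrix(path, kind: str = "auto"):
    """Read a probability matrix from the ``#dims m n`` TSV dialect.

    ``kind`` is ``"match"``, ``"basepair"`` or ``"auto"`` (square matrices
    with all entries strictly above the diagonal load as base-pair
    matrices).  Violations of the matrix invariants are rejected with the
    offending line number.
    """
    entries = []
    dims = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#dims"):
                parts = line.split()
                if len(parts) != 3:
                    raise ValueError(f"line {lineno}: malformed #dims header")
                dims = (int(parts[1]), int(parts[2]))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 'i j p'")
            i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"line {lineno}: probability {p} outside [0, 1]")
            entries.append((lineno, i, j, p))
    if dims is None:
        raise ValueError("missing '#dims m n' header")
    m, n = dims
    values = np.zeros((m, n))
    seen = set()
    for lineno, i, j, p in entries:
        if not (0 <= i < m and 0 <= j < n):
            raise ValueError(f"line {lineno}: index ({i}, {j}) out of range")
        if (i, j) in seen:
            raise ValueError(f"line {lineno}: duplicate entry ({i}, {j})")
        seen.add((i, j))
        values[i, j] = p
    if kind == "auto":
        kind = (
            "basepair"
            if m == n and all(i < j for _, i, j, _ in entries)
            else "match"
        )
    if kind == "basepair":
        return BasePairProbMatrix(values)
    if kind == "match":
        return MatchProbMatrix(values)
    raise ValueError(f"unknown matrix kind {kind!r}")


def save_matrix(matrix, path, threshold: float = 0.0):
    """Write a matrix in the ``#dims m n`` TSV dialect (entries > threshold)."""
    values = matrix.values
    m, n = values.shape
    with open(path, "w") as fh:
        fh.write(f"#dims {m} {n}\n")
        for i in range(m):
            for j in range(n):
                if values[i, j] > threshold:
                    fh.write(f"{i}\t{j}\t{values[i, j]:.12g}\n")
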