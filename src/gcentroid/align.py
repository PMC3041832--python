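"""Gamma-centroid pairwise alignment.

Given an aligned-base probability matrix p, the gamma-centroid alignment
maximizes  sum over predicted pairs of (gamma+1)*p_ij - 1  over the
alignment space, by a Needleman-Wunsch-style recursion

    M[i][j] = max(M[i-1][j], M[i][j-1], M[i-1][j-1] + (gamma+1) p_ij - 1).

For gamma <= 1 the same prediction objective is attained without dynamic
programming by collecting every pair with p_ij > 1/(gamma+1): two
conflicting pairs cannot both exceed 1/2 when the matrix comes from a
distribution on the alignment space.

A generic pointwise-reward engine is also exposed; it realizes the
gamma-centroid (reward (gamma+1)p - 1, zero gap rewards), the Holmes /
ProbCons sum-of-probabilities variant (reward p) and the AMA estimator
(reward 2p, gap rewards gap_factor * q) in one recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .gains import threshold
from .matrices import MatchProbMatrix
from .spaces import AlignmentSpaceSpec, BinaryPrediction

__all__ = [
    "PairwiseAlignment",
    "gamma_centroid_align",
    "align_consensus",
    "pointwise_reward_align",
]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A pairwise alignment as a set of aligned position pairs."""

    aligned_pairs: frozenset
    len_x: int
    len_y: int
    objective: float = 0.0

    def __post_init__(self):
        spec = AlignmentSpaceSpec(self.len_x, self.len_y)
        if not spec.is_valid(self.aligned_pairs):
            raise ValueError("aligned pairs violate the alignment space")

    @property
    def space(self) -> AlignmentSpaceSpec:
        return AlignmentSpaceSpec(self.len_x, self.len_y)

    def to_prediction(self) -> BinaryPrediction:
        return BinaryPrediction(self.aligned_pairs, self.len_x * self.len_y)

    def render(self, x: str, y: str) -> tuple:
        """Gapped-text rendering; between consecutive matches the unaligned
        x residues are placed before the unaligned y residues."""
        if len(x) != self.len_x or len(y) != self.len_y:
            raise ValueError("sequence lengths disagree with the alignment")
        rx, ry = [], []
        pi, pj = 0, 0
        for i, j in sorted(self.aligned_pairs) + [(self.len_x, self.len_y)]:
            for k in range(pi, i):
                rx.append(x[k])
                ry.append("-")
            for k in range(pj, j):
                rx.append("-")
                ry.append(y[k])
            if i < self.len_x:
                rx.append(x[i])
                ry.append(y[j])
            pi, pj = i + 1, j + 1
        return "".join(rx), "".join(ry)


def pointwise_reward_align(
    reward: np.ndarray,
    gap_reward_x: np.ndarray | None = None,
    gap_reward_y: np.ndarray | None = None,
) -> PairwiseAlignment:
    """Maximize sum of per-pair match rewards plus per-position gap rewards
    over the alignment space.

    Traceback prefers diagonal > up > left on ties (fixed, so outputs are
    reproducible; oracle comparisons are made on objective value).  The
    empty alignment is always a legal output.
    """
    reward = np.asarray(reward, dtype=float)
    m, n = reward.shape
    gx = np.zeros(m) if gap_reward_x is None else np.asarray(gap_reward_x, float)
    gy = np.zeros(n) if gap_reward_y is None else np.asarray(gap_reward_y, float)

    M = np.zeros((m + 1, n + 1))
    M[:, 0] = np.concatenate([[0.0], np.cumsum(gx)])
    M[0, :] = np.concatenate([[0.0], np.cumsum(gy)])
    for i in range(1, m + 1):
        diag = M[i - 1, :-1] + reward[i - 1, :]
        up = M[i - 1, 1:] + gx[i - 1]
        row = M[i, 0]
        out = M[i]
        for j in range(1, n + 1):
            row = max(diag[j - 1], up[j - 1], out[j - 1] + gy[j - 1])
            out[j] = row

    pairs = []
    i, j = m, n
    while i > 0 or j > 0:
        here = M[i, j]
        if i > 0 and j > 0 and math.isclose(
            here, M[i - 1, j - 1] + reward[i - 1, j - 1], abs_tol=1e-12
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and math.isclose(here, M[i - 1, j] + gx[i - 1], abs_tol=1e-12):
            i -= 1
        else:
            j -= 1
    return PairwiseAlignment(frozenset(pairs), m, n, objective=float(M[m, n]))


def gamma_centroid_align(p: MatchProbMatrix, gamma: float) -> PairwiseAlignment:
    """Alignment maximizing sum over predicted pairs of (gamma+1)p_ij - 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    reward = (gamma + 1.0) * p.values - 1.0
    return pointwise_reward_align(reward)


def align_consensus(p: MatchProbMatrix, gamma: float) -> PairwiseAlignment:
    """Collect pairs with p_ij > 1/(gamma+1); valid for gamma <= 1.

    Attains the gamma-centroid DP objective without dynamic programming.
    Raises if the collected pairs violate the alignment space, which can
    only happen with matrices inconsistent with a distribution on it.
    """
    if not 0 < gamma <= 1:
        raise ValueError("consensus shortcut requires 0 < gamma <= 1; use the DP")
    cut = threshold(gamma)
    m, n = p.shape
    pairs = frozenset(
        (i, j) for i in range(m) for j in range(n) if p[i, j] > cut
    )
    obj = math.fsum((gamma + 1.0) * p[i, j] - 1.0 for i, j in pairs)
    return PairwiseAlignment(pairs, m, n, objective=obj)
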