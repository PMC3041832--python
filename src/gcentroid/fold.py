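"""Gamma-centroid RNA secondary-structure prediction.

Given a base-pairing probability matrix p, the gamma-centroid structure
maximizes  sum over predicted pairs of (gamma+1)*p_ij - 1  over the
pseudoknot-free structure space, by a Nussinov-style interval recursion

    M[i][j] = max( M[i+1][j],                    # i unpaired
                   M[i][j-1],                    # j unpaired
                   M[i+1][j-1] + r_ij,           # (i, j) paired, r_ij > 0
                   max_k M[i][k] + M[k+1][j] )   # bifurcation

with r_ij = (gamma+1) p_ij - 1.  Pairs with non-positive reward are never
introduced, which makes the DP view and the threshold view (predict exactly
where p_ij > 1/(gamma+1)) coincide.  For gamma <= 1 the threshold
collection alone is already a valid structure — two conflicting pairs
cannot both exceed probability 1/2 — and is returned without DP.

The Do et al. MEA-style decoder (pair reward 2*gamma*p_ij, unpaired reward
q_i) is included as a comparison estimator only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .gains import threshold
from .matrices import BasePairProbMatrix
from .spaces import BinaryPrediction, StructureSpaceSpec

__all__ = [
    "SecondaryStructure",
    "gamma_centroid_fold",
    "fold_consensus",
    "mea_fold",
]


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure as a set of base pairs."""

    pairs: frozenset
    length: int
    objective: float = 0.0

    def __post_init__(self):
        spec = StructureSpaceSpec(self.length, min_loop=0)
        if not spec.is_valid(self.pairs):
            raise ValueError("pairs violate the secondary-structure space")

    def to_prediction(self) -> BinaryPrediction:
        return BinaryPrediction(self.pairs, self.length * (self.length - 1) // 2)

    def dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)


def _masked_rewards(
    p: BasePairProbMatrix, gamma: float, min_loop: int
) -> np.ndarray:
    L = p.length
    reward = (gamma + 1.0) * p.values - 1.0
    band = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(i + 1, min(i + min_loop + 1, L)):
            band[i, j] = True
    if np.any((p.values > 0) & band):
        warnings.warn(
            "probability entries inside the forbidden min-loop band are "
            "ignored at prediction time",
            stacklevel=3,
        )
    reward[band] = -math.inf
    return reward


def _interval_fold(reward_fn, unpaired_fn, L: int, min_loop: int):
    """Shared interval DP; reward_fn(i, j) is the pair reward or -inf,
    unpaired_fn(i) the per-position reward for leaving i unpaired.

    Traceback tie-break order: i unpaired < j unpaired < pair (i, j) <
    bifurcation (fixed, documented)."""
    M = np.zeros((L + 1, L + 1))  # M[i][j] over half-open-ish i..j inclusive

    def get(i, j):
        return 0.0 if i > j else M[i, j]

    for span in range(0, L):
        for i in range(0, L - span):
            j = i + span
            best = get(i + 1, j) + unpaired_fn(i)
            cand = get(i, j - 1) + unpaired_fn(j)
            best = max(best, cand)
            r = reward_fn(i, j)
            if j - i > min_loop and r > -math.inf:
                best = max(best, get(i + 1, j - 1) + r)
            for k in range(i, j):
                best = max(best, get(i, k) + get(k + 1, j))
            M[i, j] = best

    pairs = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if i > j:
            continue
        val = M[i, j]
        if math.isclose(val, get(i + 1, j) + unpaired_fn(i), abs_tol=1e-12):
            stack.append((i + 1, j))
            continue
        if math.isclose(val, get(i, j - 1) + unpaired_fn(j), abs_tol=1e-12):
            stack.append((i, j - 1))
            continue
        r = reward_fn(i, j)
        if (
            j - i > min_loop
            and r > -math.inf
            and math.isclose(val, get(i + 1, j - 1) + r, abs_tol=1e-12)
        ):
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            if math.isclose(val, get(i, k) + get(k + 1, j), abs_tol=1e-12):
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return pairs, float(M[0, L - 1]) if L else 0.0


def gamma_centroid_fold(
    p: BasePairProbMatrix, gamma: float, min_loop: int = 3
) -> SecondaryStructure:
    """Structure maximizing sum over predicted pairs of (gamma+1)p_ij - 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    L = p.length
    reward = _masked_rewards(p, gamma, min_loop)

    def rfn(i, j):
        r = reward[i, j]
        return r if r > 0 else -math.inf  # never introduce non-positive pairs

    pairs, obj = _interval_fold(rfn, lambda i: 0.0, L, min_loop)
    return SecondaryStructure(frozenset(pairs), L, objective=obj)


def fold_consensus(
    p: BasePairProbMatrix, gamma: float, min_loop: int = 3
) -> SecondaryStructure:
    """Collect pairs with p_ij > 1/(gamma+1); valid for gamma <= 1, no DP.

    Attains the same prediction objective as :func:`gamma_centroid_fold`.
    """
    if not 0 < gamma <= 1:
        raise ValueError("consensus shortcut requires 0 < gamma <= 1; use the DP")
    cut = threshold(gamma)
    L = p.length
    pairs = frozenset(
        (i, j)
        for i in range(L)
        for j in range(i + min_loop + 1, L)
        if p[i, j] > cut
    )
    obj = math.fsum((gamma + 1.0) * p[i, j] - 1.0 for i, j in pairs)
    return SecondaryStructure(pairs, L, objective=obj)


def mea_fold(
    p: BasePairProbMatrix, gamma: float, min_loop: int = 3
) -> SecondaryStructure:
    """Do et al. MEA-style decoder (comparison estimator): maximize
    2*gamma*sum of predicted pair probabilities plus sum of q_i over
    unpaired positions."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    L = p.length
    q = p.unpaired_probs()

    def rfn(i, j):
        return 2.0 * gamma * p[i, j]

    pairs, obj = _interval_fold(rfn, lambda i: float(q[i]), L, min_loop)
    return SecondaryStructure(frozenset(pairs), L, objective=obj)
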