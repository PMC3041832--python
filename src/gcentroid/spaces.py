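"""Discrete predictive spaces and the brute-force maximum-expected-gain oracle.

An estimation problem on a binary space asks for a point in a predictive
space Y, a constrained subset of {0,1}^n.  Three concrete spaces are used
throughout this package:

* pairwise alignments of two sequences — a set of aligned position pairs
  (i, j) that is one-to-one in each coordinate and non-crossing;
* RNA secondary structures — a set of base pairs (i, j), i < j, in which
  every position belongs to at most one pair, pairs never cross
  (no pseudoknots) and each pair spans more than ``min_loop`` bases;
* phylogenetic trees encoded by their bipartitions (handled in
  :mod:`gcentroid.phylo`; tree space is too large to enumerate).

The alignment and structure spaces are small enough to enumerate for toy
instances, which makes an exact, assumption-free oracle possible: evaluate
the expected gain of every member of the space under an explicitly
enumerated distribution and take the argmax.  Every dynamic-programming
estimator in this package is validated against that oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "BinaryPrediction",
    "AlignmentSpaceSpec",
    "StructureSpaceSpec",
    "EnumeratedDistribution",
    "MarginalVector",
    "enumerate_alignments",
    "enumerate_structures",
    "brute_force_meg",
    "marginals_from_distribution",
]

# Enumeration guards: keep full test suites in seconds.
MAX_ALIGN_LEN = 8
MAX_STRUCT_LEN = 14


@dataclass(frozen=True)
class BinaryPrediction:
    """A point y in a binary predictive space.

    ``on_indices`` is the set of base indices set to 1 (index pairs for
    alignments/structures, bipartition ids for trees); ``dimension`` is the
    size of the base index set, needed for true-negative counts.
    """

    on_indices: frozenset
    dimension: int

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], dimension: int) -> "BinaryPrediction":
        return cls(frozenset(tuple(p) for p in pairs), dimension)

    def sort_key(self) -> tuple:
        return tuple(sorted(self.on_indices))

    def validate(self, space) -> bool:
        return space.is_valid(self.on_indices)

    def __len__(self) -> int:
        return len(self.on_indices)


@dataclass(frozen=True)
class AlignmentSpaceSpec:
    """Space of pairwise alignments of sequences of length len_x and len_y.

    Members are sets of aligned pairs (i, j), 0-based, where each position
    of either sequence aligns with at most one position of the other and
    aligned pairs are mutually non-crossing (strictly monotone in both
    coordinates).  The empty alignment is a valid member.
    """

    len_x: int
    len_y: int

    @property
    def dimension(self) -> int:
        return self.len_x * self.len_y

    def base_indices(self) -> list:
        return [(i, j) for i in range(self.len_x) for j in range(self.len_y)]

    def is_valid(self, pairs: Iterable[tuple]) -> bool:
        pairs = sorted(pairs)
        for i, j in pairs:
            if not (0 <= i < self.len_x and 0 <= j < self.len_y):
                return False
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        if len(set(xs)) != len(xs) or len(set(ys)) != len(ys):
            return False
        # sorted by i: non-crossing iff j strictly increasing
        return all(ys[k] < ys[k + 1] for k in range(len(ys) - 1))

    def members(self) -> list:
        return enumerate_alignments(self)


@dataclass(frozen=True)
class StructureSpaceSpec:
    """Space of pseudoknot-free secondary structures of a given length.

    Members are sets of base pairs (i, j), i < j; each position is in at
    most one pair, pairs are nested (non-crossing) and j - i > min_loop.
    The default min_loop of 3 is the standard steric constraint; the space
    definition itself imposes none, hence the parameter.
    """

    length: int
    min_loop: int = 3

    @property
    def dimension(self) -> int:
        return self.length * (self.length - 1) // 2

    def base_indices(self) -> list:
        return [
            (i, j) for i in range(self.length) for j in range(i + 1, self.length)
        ]

    def is_valid(self, pairs: Iterable[tuple]) -> bool:
        pairs = sorted(pairs)
        seen = set()
        for i, j in pairs:
            if not (0 <= i < j < self.length):
                return False
            if j - i <= self.min_loop:
                return False
            if i in seen or j in seen:
                return False
            seen.add(i)
            seen.add(j)
        for (i, j), (k, l) in itertools.combinations(pairs, 2):
            if i < k < j < l or k < i < l < j:
                return False
        return True

    def members(self) -> list:
        return enumerate_structures(self)


@dataclass
class MarginalVector:
    """Marginalized probabilities p_i = P(theta_i = 1), one per base index."""

    probs: dict
    dimension: int

    def __getitem__(self, index) -> float:
        return self.probs.get(index, 0.0)

    def items(self):
        return self.probs.items()


@dataclass
class EnumeratedDistribution:
    """Explicit probability table over an enumerable predictive space."""

    members: list
    probs: list
    space: object = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("distribution needs at least one member")
        if len(self.members) != len(self.probs):
            raise ValueError("members/probs length mismatch")
        total = math.fsum(self.probs)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("negative probability")
        keys = {m.on_indices for m in self.members}
        if len(keys) != len(self.members):
            raise ValueError("duplicate members in distribution")
        if self.space is not None:
            for m in self.members:
                if not m.validate(self.space):
                    raise ValueError(f"member {sorted(m.on_indices)} not in space")


def _sorted_members(raw: Iterable[frozenset], dimension: int) -> list:
    preds = [BinaryPrediction(frozenset(s), dimension) for s in raw]
    preds.sort(key=BinaryPrediction.sort_key)
    return preds


def enumerate_alignments(spec: AlignmentSpaceSpec) -> list:
    """Every valid alignment of the space, exactly once, in deterministic
    (lexicographic) order."""
    if spec.len_x > MAX_ALIGN_LEN or spec.len_y > MAX_ALIGN_LEN:
        raise ValueError(
            f"alignment enumeration limited to lengths <= {MAX_ALIGN_LEN}, "
            f"got ({spec.len_x}, {spec.len_y})"
        )

    results = []

    def rec(i: int, min_j: int, acc: tuple):
        if i == spec.len_x:
            results.append(frozenset(acc))
            return
        rec(i + 1, min_j, acc)  # x_i unaligned
        for j in range(min_j, spec.len_y):
            rec(i + 1, j + 1, acc + ((i, j),))

    rec(0, 0, ())
    return _sorted_members(results, spec.dimension)


def enumerate_structures(spec: StructureSpaceSpec) -> list:
    """Every non-crossing, min-loop-respecting matching, exactly once, in
    deterministic (lexicographic) order."""
    if spec.length > MAX_STRUCT_LEN:
        raise ValueError(
            f"structure enumeration limited to length <= {MAX_STRUCT_LEN}, "
            f"got {spec.length}"
        )

    cache: dict = {}

    def interval(i: int, j: int) -> list:
        # all structures on positions i..j inclusive, as tuples of pairs
        if i >= j:
            return [()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out = list(interval(i + 1, j))  # i unpaired
        for k in range(i + spec.min_loop + 1, j + 1):
            for left in interval(i + 1, k - 1):
                for right in interval(k + 1, j):
                    out.append(((i, k),) + left + right)
        cache[key] = out
        return out

    raw = [frozenset(s) for s in interval(0, spec.length - 1)]
    return _sorted_members(raw, spec.dimension)


def _as_gain_callable(gain) -> Callable:
    if callable(gain):
        return gain
    # GainSpec-like object with an evaluate method
    return gain.evaluate


def brute_force_meg(
    dist: EnumeratedDistribution,
    gain,
    candidates: Sequence[BinaryPrediction] | None = None,
) -> tuple:
    """Exact maximum-expected-gain estimate by exhaustive evaluation.

    Evaluates E[G(theta, y)] = sum_theta P(theta) G(theta, y) for every
    candidate y and returns ``(argmax, expected_gain)``.  Candidates default
    to the full enumeration of ``dist.space`` (or, lacking a space, the
    distribution's support).  Ties go to the first candidate in the
    deterministic enumeration order.
    """
    g = _as_gain_callable(gain)
    if candidates is None:
        if dist.space is not None:
            candidates = dist.space.members()
        else:
            candidates = dist.members
    best = None
    best_val = -math.inf
    for y in candidates:
        val = math.fsum(
            p * g(theta, y) for theta, p in zip(dist.members, dist.probs)
        )
        if val > best_val + 1e-15:
            best, best_val = y, val
    return best, best_val


def marginals_from_distribution(dist: EnumeratedDistribution) -> MarginalVector:
    """p_i = sum over members with theta_i = 1 of P(theta)."""
    probs: dict = {}
    for theta, p in zip(dist.members, dist.probs):
        for idx in theta.on_indices:
            probs[idx] = probs.get(idx, 0.0) + p
    dim = dist.members[0].dimension
    return MarginalVector(probs, dim)
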