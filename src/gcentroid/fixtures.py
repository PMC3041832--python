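"""Deterministic generators of synthetic test inputs.

Every "random probability matrix" produced here is derived as the marginal
vector of an actual random distribution over the relevant predictive space
— never as i.i.d. entries — so the structural preconditions of the
consensus-estimator results genuinely hold for the fixtures.  All
generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .matrices import BasePairProbMatrix, MatchProbMatrix
from .spaces import (
    AlignmentSpaceSpec,
    EnumeratedDistribution,
    StructureSpaceSpec,
    marginals_from_distribution,
)

__all__ = [
    "random_enumerated_distribution",
    "random_match_matrix",
    "random_basepair_matrix",
    "random_tree_sample",
    "random_sequences",
]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_enumerated_distribution(
    space, seed, kind: str = "boltzmann", support: int | None = None
) -> EnumeratedDistribution:
    """Random distribution over an enumerable space.

    kind: ``uniform`` (equal mass), ``boltzmann`` (exp of Gaussian scores)
    or ``sparse`` (mass on a random subset of ``support`` members).
    """
    rng = _rng(seed)
    members = space.members()
    n = len(members)
    if kind == "uniform":
        probs = np.full(n, 1.0 / n)
    elif kind == "boltzmann":
        w = np.exp(rng.normal(0.0, 1.5, size=n))
        probs = w / w.sum()
    elif kind == "sparse":
        k = min(support or max(2, n // 4), n)
        idx = sorted(rng.choice(n, size=k, replace=False))
        members = [members[i] for i in idx]
        w = np.exp(rng.normal(0.0, 1.5, size=k))
        probs = w / w.sum()
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    probs = probs / probs.sum()
    # remove fp residue so the sum-to-1 invariant holds exactly enough
    probs[-1] = 1.0 - probs[:-1].sum()
    return EnumeratedDistribution(list(members), list(probs), space=space)


def random_match_matrix(len_x: int, len_y: int, seed, kind="boltzmann", support=None):
    """MatchProbMatrix realized as marginals of a random alignment-space
    distribution (invariants hold by construction)."""
    space = AlignmentSpaceSpec(len_x, len_y)
    dist = random_enumerated_distribution(space, seed, kind, support)
    marg = marginals_from_distribution(dist)
    values = np.zeros((len_x, len_y))
    for (i, j), p in marg.items():
        values[i, j] = p
    return MatchProbMatrix(values), dist


def random_basepair_matrix(length: int, seed, min_loop=0, kind="boltzmann", support=None):
    """BasePairProbMatrix realized as marginals of a random structure-space
    distribution."""
    space = StructureSpaceSpec(length, min_loop=min_loop)
    dist = random_enumerated_distribution(space, seed, kind, support)
    marg = marginals_from_distribution(dist)
    values = np.zeros((length, length))
    for (i, j), p in marg.items():
        values[i, j] = p
    return BasePairProbMatrix(values), dist


def random_tree_sample(n_taxa: int, n_trees: int, seed, contract_prob=0.3):
    """Random multifurcating topologies as Newick strings.

    Random binary topologies by sequential leaf attachment, then each
    internal edge contracted independently with ``contract_prob`` to mimic
    the multifurcating trees of a posterior sample.
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = _rng(seed)
    taxa = [f"T{k}" for k in range(n_taxa)]

    def one_tree():
        # nested-list representation; leaves are labels
        nodes = [taxa[0], taxa[1], taxa[2]]
        for label in taxa[3:]:
            # attach to a random edge: pick a random node and split it
            k = rng.integers(0, len(nodes))
            nodes[k] = [nodes[k], label]
        # nodes now: children of the (unrooted) central node

        def newick(node):
            if isinstance(node, str):
                return node
            if rng.random() < contract_prob:
                # contract: splice children into parent level
                return ",".join(newick(c) for c in node)
            return "(" + ",".join(newick(c) for c in node) + ")"

        return "(" + ",".join(newick(n) for n in nodes) + ");"

    return [one_tree() for _ in range(n_trees)]


def random_sequences(
    n: int, length_range: tuple, alphabet: str = "ACGU", seed=0
):
    """(id, sequence) pairs with lengths uniform in the inclusive range."""
    rng = _rng(seed)
    lo, hi = length_range
    out = []
    for k in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=L))
        out.append((f"seq{k}", seq))
    return out
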