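"""Approximated gamma-type estimators using homologous sequences.

Marginalizing a joint model of the targets plus their homologs (a triplet
HMM, or a structural-alignment model) is exact but intractable; these
estimators factorize it into pairwise marginal matrices and decode the
combined evidence with the ordinary gamma-centroid machinery.

* :func:`pct_match_probs` — the probabilistic consistency transformation
  (PCT): with Z = {x, y} plus the homologs and identity self-match
  matrices, p_tilde = (1/|Z|) * sum over z of P_xz . P_zy.  Transitive
  evidence through a homolog reinforces weakly supported pairs; a homolog
  with no links simply dilutes.  The empty homolog set reduces exactly to
  the direct matrix.
* :func:`homologous_basepair_probs` — pseudo base-pairing probabilities:
  the target's own matrix averaged with each homolog's matrix transported
  through the match probabilities,
  p_tilde_ij = (1/(1+|H|)) [ p^x_ij + sum_h sum_{k<l} P_xh(i,k) P_xh(j,l) p^h_kl ].

Both decoders check the factorization-consistency condition before using
the gamma <= 1 componentwise shortcut: the combined matrix must satisfy
the marginal-matrix invariants and the collected set must be a valid
member of the predictive space.
"""

from __future__ import annotations

import warnings

import numpy as np

from .align import PairwiseAlignment, align_consensus, gamma_centroid_align
from .fold import SecondaryStructure, fold_consensus, gamma_centroid_fold
from .matrices import BasePairProbMatrix, MatchProbMatrix
from .probmodels import boltzmann_basepair_probs, pairhmm_match_probs

__all__ = [
    "HomologSet",
    "pct_match_probs",
    "pct_align",
    "homologous_basepair_probs",
    "homologous_fold",
]


class HomologSet:
    """Named homologous sequences supporting a target pair or sequence."""

    def __init__(self, sequences: dict):
        if any(not k for k in sequences):
            raise ValueError("homolog ids must be non-empty")
        self.sequences = dict(sequences)

    @classmethod
    def from_records(cls, records) -> "HomologSet":
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate homolog ids")
        return cls({r.id: r.residues for r in records})

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


def _sanitize(values: np.ndarray, what: str) -> np.ndarray:
    """Clip tiny numerical overshoots; larger invariant violations are
    errors (they signal genuinely inconsistent external inputs)."""
    if np.any(values > 1 + 1e-6):
        raise ValueError(f"{what} exceed 1 by more than 1e-6")
    if np.any(values > 1):
        warnings.warn(f"{what} clipped to 1 (numerical noise)", stacklevel=3)
    return np.clip(values, 0.0, 1.0)


def pct_match_probs(
    x: str, y: str, homologs: HomologSet | None = None, engine=None
) -> MatchProbMatrix:
    """Probabilistic consistency transformation of the match probabilities.

    Z = {x, y} plus the homologs, with identity self-match matrices, so an
    empty homolog set returns exactly the direct pairwise matrix.
    """
    engine = engine or pairhmm_match_probs
    homologs = homologs or HomologSet({})
    p_xy = engine(x, y).values
    m, n = p_xy.shape
    # z = x and z = y contribute I.P_xy and P_xy.I
    acc = 2.0 * p_xy.copy()
    for _, z in homologs.items():
        p_xz = engine(x, z).values
        p_zy = engine(z, y).values
        if p_xz.shape[1] != p_zy.shape[0]:
            raise ValueError("homolog matrix dimensions disagree")
        acc += p_xz @ p_zy
    values = acc / (2 + len(homologs))
    return MatchProbMatrix(_sanitize(values, "PCT match probabilities"))


def _check_consensus_valid(matrix, prediction, space) -> None:
    """Factorization-consistency check required before any componentwise
    shortcut output: matrix invariants plus space membership."""
    if isinstance(matrix, MatchProbMatrix):
        rows = matrix.values.sum(axis=1)
        cols = matrix.values.sum(axis=0)
        ok = np.all(rows <= 1 + 1e-6) and np.all(cols <= 1 + 1e-6)
    else:
        ok = np.all(matrix.position_sums() <= 1 + 1e-6)
    if not ok or not space.is_valid(
        prediction.aligned_pairs
        if isinstance(prediction, PairwiseAlignment)
        else prediction.pairs
    ):
        raise ValueError(
            "combined marginals are inconsistent with the predictive space; "
            "the consensus shortcut is invalid for this input"
        )


def pct_align(
    x: str,
    y: str,
    homologs: HomologSet | None = None,
    gamma: float = 1.0,
    engine=None,
) -> PairwiseAlignment:
    """Gamma-centroid alignment on the PCT-transformed matrix."""
    p = pct_match_probs(x, y, homologs, engine)
    if gamma <= 1:
        out = align_consensus(p, gamma)
        _check_consensus_valid(p, out, out.space)
        return out
    return gamma_centroid_align(p, gamma)


def homologous_basepair_probs(
    x: str,
    homologs: HomologSet | None = None,
    fold_engine=None,
    match_engine=None,
) -> BasePairProbMatrix:
    """Pseudo base-pairing probabilities supported by homologs.

    p_tilde = (1/(1+|H|)) [ p^x + sum_h P_xh . p^h . P_xh^T ] restricted to
    the upper triangle; an empty homolog set returns the target's matrix.
    """
    fold_engine = fold_engine or boltzmann_basepair_probs
    match_engine = match_engine or pairhmm_match_probs
    homologs = homologs or HomologSet({})
    p_x = fold_engine(x).values
    L = p_x.shape[0]
    acc = p_x.copy()
    for _, h in homologs.items():
        p_xh = match_engine(x, h).values
        p_h = fold_engine(h).values
        if p_xh.shape[1] != p_h.shape[0]:
            raise ValueError("homolog matrix dimensions disagree")
        transported = p_xh @ p_h @ p_xh.T  # sum_{k<l} P(i,k) P(j,l) p^h_kl
        acc += np.triu(transported, k=1)
    values = np.triu(acc / (1 + len(homologs)), k=1)
    return BasePairProbMatrix(_sanitize(values, "pseudo base-pair probabilities"))


def homologous_fold(
    x: str,
    homologs: HomologSet | None = None,
    gamma: float = 1.0,
    fold_engine=None,
    match_engine=None,
    min_loop: int = 3,
) -> SecondaryStructure:
    """Gamma-centroid fold of the homolog-supported pseudo matrix."""
    p = homologous_basepair_probs(x, homologs, fold_engine, match_engine)
    if gamma <= 1:
        out = fold_consensus(p, gamma, min_loop)
        from .spaces import StructureSpaceSpec

        _check_consensus_valid(p, out, StructureSpaceSpec(p.length, min_loop))
        return out
    return gamma_centroid_fold(p, gamma, min_loop)
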