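"""Representative estimators: one prediction standing for many sequences.

When a prediction must represent several sequences at once — a common
secondary structure for an aligned RNA family, or an alignment of two
alignments — the natural gain is homogeneous: the single-sequence gain
summed over every member.  Maximizing its expectation over the product of
the per-sequence distributions is equivalent to running the ordinary
gamma-centroid estimator on the *averaged* marginal matrix in alignment-
column coordinates.

Per-sequence probabilities are always computed on the degapped sequences
and then mapped into column space; a row contributes probability 0 to any
column pair at which it has a gap (a mapped structure or alignment cannot
place a pair on a gap).  Averages are uniform over rows.
"""

from __future__ import annotations

import numpy as np

from .align import PairwiseAlignment, gamma_centroid_align, align_consensus
from .fold import SecondaryStructure, fold_consensus, gamma_centroid_fold
from .io import MultipleAlignment
from .matrices import BasePairProbMatrix, MatchProbMatrix
from .probmodels import boltzmann_basepair_probs, pairhmm_match_probs

__all__ = [
    "averaged_basepair_probs",
    "common_structure",
    "averaged_match_probs",
    "align_alignments",
]


def averaged_basepair_probs(
    aln: MultipleAlignment, engine=None
) -> BasePairProbMatrix:
    """Column-space average of per-row base-pairing probability matrices.

    p_bar(u, v) = (1/N) * sum over rows of p_row(pos(u), pos(v)), a row
    contributing 0 when either column is a gap in it.
    """
    engine = engine or boltzmann_basepair_probs
    if aln.n_rows == 0:
        raise ValueError("empty alignment")
    W = aln.width
    acc = np.zeros((W, W))
    for r in range(aln.n_rows):
        p = engine(aln.degapped(r))
        cmap = aln.column_map[r]
        cols = [u for u in range(W) if cmap[u] is not None]
        for a, u in enumerate(cols):
            for v in cols[a + 1:]:
                acc[u, v] += p[cmap[u], cmap[v]]
    return BasePairProbMatrix(acc / aln.n_rows)


def common_structure(
    aln: MultipleAlignment, gamma: float, engine=None, min_loop: int = 3
) -> SecondaryStructure:
    """Common secondary structure of an aligned family: the gamma-centroid
    fold of the averaged base-pairing matrix (consensus shortcut for
    gamma <= 1)."""
    p = averaged_basepair_probs(aln, engine)
    if gamma <= 1:
        return fold_consensus(p, gamma, min_loop)
    return gamma_centroid_fold(p, gamma, min_loop)


def averaged_match_probs(
    alnA: MultipleAlignment, alnB: MultipleAlignment, engine=None
) -> MatchProbMatrix:
    """Averaged aligned-base probabilities between two alignment groups.

    p_bar(u, v) = (1/(N_A N_B)) * sum over row pairs (a, b) of
    p_ab(posA(a, u), posB(b, v)), with gap contributions 0.
    """
    engine = engine or pairhmm_match_probs
    if alnA.n_rows == 0 or alnB.n_rows == 0:
        raise ValueError("empty alignment group")
    WA, WB = alnA.width, alnB.width
    acc = np.zeros((WA, WB))
    for a in range(alnA.n_rows):
        for b in range(alnB.n_rows):
            p = engine(alnA.degapped(a), alnB.degapped(b))
            cma, cmb = alnA.column_map[a], alnB.column_map[b]
            for u in range(WA):
                if cma[u] is None:
                    continue
                for v in range(WB):
                    if cmb[v] is None:
                        continue
                    acc[u, v] += p[cma[u], cmb[v]]
    return MatchProbMatrix(acc / (alnA.n_rows * alnB.n_rows))


def _merge(alnA, alnB, colalign: PairwiseAlignment) -> MultipleAlignment:
    """Merged alignment realizing a column-level pairwise alignment; the
    within-group columns of both inputs are preserved intact."""
    rows = [[] for _ in range(alnA.n_rows + alnB.n_rows)]

    def emit(colA, colB):
        for r in range(alnA.n_rows):
            rows[r].append(alnA.rows[r][colA] if colA is not None else "-")
        for r in range(alnB.n_rows):
            rows[alnA.n_rows + r].append(
                alnB.rows[r][colB] if colB is not None else "-"
            )

    pu, pv = 0, 0
    for u, v in sorted(colalign.aligned_pairs) + [(alnA.width, alnB.width)]:
        for k in range(pu, u):
            emit(k, None)
        for k in range(pv, v):
            emit(None, k)
        if u < alnA.width:
            emit(u, v)
        pu, pv = u + 1, v + 1
    return MultipleAlignment(
        ids=list(alnA.ids) + list(alnB.ids),
        rows=["".join(r) for r in rows],
    )


def align_alignments(
    alnA: MultipleAlignment,
    alnB: MultipleAlignment,
    gamma: float,
    engine=None,
) -> tuple:
    """Align two alignments: gamma-centroid alignment of the averaged
    matrix, plus the merged multiple alignment it induces.

    Returns ``(column_alignment, merged_alignment)``.
    """
    p = averaged_match_probs(alnA, alnB, engine)
    if gamma <= 1:
        colalign = align_consensus(p, gamma)
    else:
        colalign = gamma_centroid_align(p, gamma)
    return colalign, _merge(alnA, alnB, colalign)
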