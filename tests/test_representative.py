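"""Representative estimators: averaging into column space, reductions."""

import itertools
import math

import numpy as np
import pytest

from gcentroid.fixtures import random_enumerated_distribution
from gcentroid.io import MultipleAlignment
from gcentroid.matrices import BasePairProbMatrix, MatchProbMatrix
from gcentroid.representative import (
    align_alignments,
    averaged_basepair_probs,
    averaged_match_probs,
    common_structure,
)
from gcentroid.spaces import BinaryPrediction, StructureSpaceSpec


class TableFoldEngine:
    """Fixed per-sequence base-pair matrices, keyed by sequence string."""

    def __init__(self, tables):
        self.tables = tables

    def __call__(self, seq):
        return BasePairProbMatrix(self.tables[seq])


class TableMatchEngine:
    def __init__(self, tables):
        self.tables = tables

    def __call__(self, a, b):
        return MatchProbMatrix(self.tables[(a, b)])


def test_single_ungapped_row_reduces_to_plain_matrix():
    values = np.zeros((5, 5))
    values[0, 4] = 0.7
    engine = TableFoldEngine({"GGAAC": values})
    aln = MultipleAlignment(ids=["a"], rows=["GGAAC"])
    p = averaged_basepair_probs(aln, engine)
    assert np.allclose(p.values, values)


def test_identical_rows_average_to_the_same_matrix():
    values = np.zeros((5, 5))
    values[0, 4] = 0.7
    engine = TableFoldEngine({"GGAAC": values})
    aln = MultipleAlignment(ids=["a", "b"], rows=["GGAAC", "GGAAC"])
    assert np.allclose(averaged_basepair_probs(aln, engine).values, values)


def test_gap_column_halves_the_contribution():
    v5 = np.zeros((5, 5))
    v5[0, 4] = 0.8
    v4 = np.zeros((4, 4))
    engine = TableFoldEngine({"GGAAC": v5, "GAAC": v4})
    aln = MultipleAlignment(ids=["a", "b"], rows=["GGAAC", "G-AAC"])
    p = averaged_basepair_probs(aln, engine)
    assert p[0, 4] == pytest.approx(0.4)


def test_common_structure_cutoff_on_averaged_pair():
    v = np.zeros((5, 5))
    v[0, 4] = 0.9
    w = np.zeros((5, 5))
    w[0, 4] = 0.3
    engine = TableFoldEngine({"GGAAC": v, "GGAAU": w})
    aln = MultipleAlignment(ids=["a", "b"], rows=["GGAAC", "GGAAU"])
    s = common_structure(aln, 1.0, engine=engine)  # averaged 0.6 > 0.5
    assert s.pairs == {(0, 4)}


def test_common_structure_matches_product_space_brute_force(rng):
    """The representative MEG — homogeneous gain over the product of the
    per-row structure distributions, rows mapped to column space — equals
    the gamma-centroid on the averaged marginals, in expected gain."""
    L = 6
    space = StructureSpaceSpec(L, 0)
    gamma = 1.0
    d1 = random_enumerated_distribution(space, rng)
    d2 = random_enumerated_distribution(space, rng)

    def to_matrix(dist):
        from gcentroid.spaces import marginals_from_distribution

        values = np.zeros((L, L))
        for (i, j), p in marginals_from_distribution(dist).items():
            values[i, j] = p
        return values

    engine = TableFoldEngine({"AAAAAA": to_matrix(d1), "CCCCCC": to_matrix(d2)})
    aln = MultipleAlignment(ids=["r1", "r2"], rows=["AAAAAA", "CCCCCC"])
    s = common_structure(aln, gamma, engine=engine, min_loop=0)

    def hom_gain(t1, t2, y):
        from gcentroid.gains import GainSpec

        g = GainSpec(gamma=gamma)
        return g.evaluate(t1, y) + g.evaluate(t2, y)

    best = -math.inf
    candidates = space.members()
    for y in candidates:
        e = math.fsum(
            p1 * p2 * hom_gain(t1, t2, y)
            for t1, p1 in zip(d1.members, d1.probs)
            for t2, p2 in zip(d2.members, d2.probs)
        )
        best = max(best, e)
    got = math.fsum(
        p1 * p2 * hom_gain(t1, t2, s.to_prediction())
        for t1, p1 in zip(d1.members, d1.probs)
        for t2, p2 in zip(d2.members, d2.probs)
    )
    assert got == pytest.approx(best, abs=1e-9)


def test_averaged_match_probs_reductions_and_gap_halving():
    direct = np.array([[0.8, 0.0], [0.0, 0.6]])
    eng = TableMatchEngine({("AC", "AC"): direct, ("C", "AC"): np.array([[0.0, 0.9]])})
    a1 = MultipleAlignment(ids=["x"], rows=["AC"])
    b1 = MultipleAlignment(ids=["y"], rows=["AC"])
    assert np.allclose(averaged_match_probs(a1, b1, eng).values, direct)

    a2 = MultipleAlignment(ids=["x", "x2"], rows=["AC", "AC"])
    assert np.allclose(averaged_match_probs(a2, b1, eng).values, direct)

    a3 = MultipleAlignment(ids=["x", "xg"], rows=["AC", "-C"])
    p = averaged_match_probs(a3, b1, eng)
    assert p[0, 0] == pytest.approx(0.4)  # gapped row contributes 0 at column 0
    assert p[1, 1] == pytest.approx((0.6 + 0.9) / 2)


def test_align_alignments_merges_and_degaps_back():
    direct = np.array([[0.9, 0.0], [0.0, 0.8]])
    eng = TableMatchEngine({("AC", "AG"): direct})
    a = MultipleAlignment(ids=["x"], rows=["AC"])
    b = MultipleAlignment(ids=["y"], rows=["AG"])
    colalign, merged = align_alignments(a, b, 1.0, engine=eng)
    assert colalign.aligned_pairs == {(0, 0), (1, 1)}
    assert merged.rows == ["AC", "AG"]
    # round trip: degapping reproduces the inputs
    assert merged.degapped(0) == "AC"
    assert merged.degapped(1) == "AG"


def test_align_alignments_consensus_equals_dp_for_small_gamma(rng):
    from gcentroid.align import gamma_centroid_align
    from gcentroid.fixtures import random_match_matrix

    p, _ = random_match_matrix(3, 3, rng)
    eng = TableMatchEngine({("AAA", "CCC"): p.values})
    a = MultipleAlignment(ids=["x"], rows=["AAA"])
    b = MultipleAlignment(ids=["y"], rows=["CCC"])
    colalign, _ = align_alignments(a, b, 1.0, engine=eng)
    dp = gamma_centroid_align(p, 1.0)
    assert colalign.objective == pytest.approx(dp.objective, abs=1e-12)


def test_empty_alignment_group_is_an_error():
    with pytest.raises(ValueError):
        MultipleAlignment(ids=[], rows=[])
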