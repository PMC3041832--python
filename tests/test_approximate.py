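"""Consistency-transformed alignment and homolog-supported folding."""

import numpy as np
import pytest

from gcentroid.align import gamma_centroid_align
from gcentroid.approximate import (
    HomologSet,
    homologous_basepair_probs,
    homologous_fold,
    pct_align,
    pct_match_probs,
)
from gcentroid.fixtures import random_match_matrix
from gcentroid.fold import gamma_centroid_fold
from gcentroid.matrices import BasePairProbMatrix, MatchProbMatrix


class TableMatchEngine:
    def __init__(self, tables):
        self.tables = tables

    def __call__(self, a, b):
        return MatchProbMatrix(self.tables[(a, b)])


class TableFoldEngine:
    def __init__(self, tables):
        self.tables = tables

    def __call__(self, seq):
        return BasePairProbMatrix(self.tables[seq])


def test_pct_with_no_homologs_is_the_direct_matrix(rng):
    p, _ = random_match_matrix(3, 4, rng)
    eng = TableMatchEngine({("x", "y"): p.values})
    out = pct_match_probs("x", "y", HomologSet({}), engine=eng)
    assert np.array_equal(out.values, p.values)


def test_pct_transitive_toy_gives_two_thirds():
    eng = TableMatchEngine(
        {("x", "y"): [[0.5]], ("x", "h"): [[1.0]], ("h", "y"): [[1.0]]}
    )
    out = pct_match_probs("x", "y", HomologSet({"h": "h"}), engine=eng)
    assert out[0, 0] == pytest.approx(2.0 / 3.0, abs=1e-12)


def test_pct_unlinked_homolog_dilutes():
    eng = TableMatchEngine(
        {("x", "y"): [[0.6]], ("x", "h"): [[0.0]], ("h", "y"): [[0.0]]}
    )
    out = pct_match_probs("x", "y", HomologSet({"h": "h"}), engine=eng)
    assert out[0, 0] == pytest.approx(2 * 0.6 / 3, abs=1e-12)


def test_pct_preserves_matrix_invariants_on_random_valid_inputs(rng):
    for _ in range(10):
        pxy, _ = random_match_matrix(3, 3, rng)
        pxh, _ = random_match_matrix(3, 4, rng)
        phy, _ = random_match_matrix(4, 3, rng)
        eng = TableMatchEngine(
            {("x", "y"): pxy.values, ("x", "h"): pxh.values, ("h", "y"): phy.values}
        )
        out = pct_match_probs("x", "y", HomologSet({"h": "h"}), engine=eng)
        assert np.all(out.values.sum(axis=0) <= 1 + 1e-9)
        assert np.all(out.values.sum(axis=1) <= 1 + 1e-9)


def test_pct_align_reduces_to_plain_estimator_without_homologs(rng):
    p, _ = random_match_matrix(4, 4, rng)
    eng = TableMatchEngine({("x", "y"): p.values})
    plain = gamma_centroid_align(p, 1.0)
    via_pct = pct_align("x", "y", HomologSet({}), gamma=1.0, engine=eng)
    assert via_pct.aligned_pairs == plain.aligned_pairs
    assert via_pct.objective == pytest.approx(plain.objective, abs=0)


def test_pct_align_recovers_pair_through_transitive_evidence():
    eng = TableMatchEngine(
        {("x", "y"): [[0.4]], ("x", "h"): [[0.9]], ("h", "y"): [[0.9]]}
    )
    weak = pct_align("x", "y", HomologSet({}), gamma=1.0,
                     engine=TableMatchEngine({("x", "y"): [[0.4]]}))
    assert weak.aligned_pairs == frozenset()
    strong = pct_align("x", "y", HomologSet({"h": "h"}), gamma=1.0, engine=eng)
    # (0.4 + 0.4 + 0.81)/3 = 0.5366... > 1/2
    assert strong.aligned_pairs == {(0, 0)}


def test_pct_large_gamma_maximizes_transformed_probability_mass(rng):
    p, _ = random_match_matrix(3, 3, rng)
    eng = TableMatchEngine({("x", "y"): p.values})
    a = pct_align("x", "y", HomologSet({}), gamma=1e6, engine=eng)
    b = gamma_centroid_align(p, 1e6)
    assert a.aligned_pairs == b.aligned_pairs


def test_homologous_probs_reductions():
    px = np.zeros((5, 5))
    px[0, 4] = 0.2
    fe = TableFoldEngine({"x": px})
    out = homologous_basepair_probs("x", HomologSet({}), fold_engine=fe)
    assert np.array_equal(out.values, px)

    # homolog identical to the target with an identity match matrix
    fe2 = TableFoldEngine({"x": px, "h": px})
    me = TableMatchEngine({("x", "h"): np.eye(5)})
    out2 = homologous_basepair_probs(
        "x", HomologSet({"h": "h"}), fold_engine=fe2, match_engine=me
    )
    assert np.allclose(out2.values, px)


@pytest.mark.parametrize("ph,expected_pairs", [(0.8, frozenset()), (0.9, {(0, 4)})])
def test_homologous_fold_toy_cutoff_is_strict(ph, expected_pairs):
    # target evidence 0.2; homolog ph through a perfect match matrix:
    # pseudo probability (0.2 + ph)/2 — exactly 0.5 is excluded
    px = np.zeros((5, 5))
    px[0, 4] = 0.2
    phm = np.zeros((5, 5))
    phm[0, 4] = ph
    fe = TableFoldEngine({"x": px, "h": phm})
    me = TableMatchEngine({("x", "h"): np.eye(5)})
    s = homologous_fold(
        "x", HomologSet({"h": "h"}), gamma=1.0, fold_engine=fe, match_engine=me,
        min_loop=3,
    )
    assert s.pairs == expected_pairs


def test_homologous_fold_consensus_agrees_with_dp(rng):
    from gcentroid.fixtures import random_basepair_matrix

    px, _ = random_basepair_matrix(6, rng, min_loop=0)
    phm, _ = random_basepair_matrix(6, rng, min_loop=0)
    pm, _ = random_match_matrix(6, 6, rng)
    fe = TableFoldEngine({"x": px.values, "h": phm.values})
    me = TableMatchEngine({("x", "h"): pm.values})
    hs = HomologSet({"h": "h"})
    s1 = homologous_fold("x", hs, 1.0, fold_engine=fe, match_engine=me, min_loop=0)
    p = homologous_basepair_probs("x", hs, fold_engine=fe, match_engine=me)
    s2 = gamma_centroid_fold(p, 1.0, min_loop=0)
    assert s1.objective == pytest.approx(s2.objective, abs=1e-12)


def test_homolog_set_rejects_bad_ids():
    with pytest.raises(ValueError):
        HomologSet({"": "ACGU"})

    class R:
        def __init__(self, id, residues):
            self.id, self.residues = id, residues

    with pytest.raises(ValueError, match="duplicate"):
        HomologSet.from_records([R("a", "AC"), R("a", "GU")])


def test_dimension_mismatch_is_an_error():
    eng = TableMatchEngine(
        {("x", "y"): [[0.5]], ("x", "h"): [[1.0, 0.0]], ("h", "y"): [[1.0]]}
    )
    with pytest.raises(ValueError, match="dimensions"):
        pct_match_probs("x", "y", HomologSet({"h": "h"}), engine=eng)
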