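"""Tree bipartitions, Robinson-Foulds distance, gamma-centroid consensus."""

import itertools

import dendropy
import pytest

from gcentroid.fixtures import random_tree_sample
from gcentroid.phylo import (
    Bipartition,
    bipartitions_of_tree,
    consensus_tree,
    parse_tree_lines,
    partition_probs,
    topological_distance,
)


def sides(splits):
    return {tuple(sorted(b.side)) for b in splits}


def test_star_tree_has_no_internal_bipartitions():
    assert bipartitions_of_tree("(A,B,C,D);") == set()


def test_balanced_quartet_has_one_split():
    assert sides(bipartitions_of_tree("((A,B),(C,D));")) == {("C", "D")}


def test_caterpillar_five_taxa_has_two_internal_splits():
    splits = bipartitions_of_tree("((((A,B),C),D),E);")
    assert sides(splits) == {("A", "B"), ("A", "B", "C")} or sides(splits) == {
        ("C", "D", "E"), ("D", "E")
    }
    assert len(splits) == 2


def test_duplicate_taxa_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        bipartitions_of_tree("((A,A),(C,D));")


def test_distance_examples():
    assert topological_distance("((A,B),(C,D));", "((A,B),(C,D));") == 0
    assert topological_distance("((A,B),(C,D));", "((A,C),(B,D));") == 2
    # vs star: one side empty, distance = #internal edges
    assert topological_distance("((((A,B),C),D),E);", "(A,B,C,D,E);") == 2


def test_distance_requires_shared_taxa():
    with pytest.raises(ValueError, match="different taxon"):
        topological_distance("((A,B),(C,D));", "((A,B),(C,E));")


def test_distance_matches_dendropy_rf_on_random_trees():
    trees = random_tree_sample(6, 12, seed=11)
    tns = dendropy.TaxonNamespace()
    for t1, t2 in itertools.combinations(trees[:6], 2):
        d1 = dendropy.Tree.get(data=t1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert topological_distance(t1, t2) == expected


def test_distance_is_a_metric_on_random_triples():
    trees = random_tree_sample(5, 9, seed=3)
    for a, b, c in itertools.combinations(trees[:6], 3):
        dab = topological_distance(a, b)
        dba = topological_distance(b, a)
        assert dab == dba
        assert topological_distance(a, a) == 0
        assert dab <= topological_distance(a, c) + topological_distance(c, b)


def test_partition_probs_counts_frequencies():
    sample = ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]
    table = partition_probs(sample)
    freqs = {tuple(sorted(b.side)): f for b, f in table.frequencies.items()}
    assert freqs[("C", "D")] == pytest.approx(2 / 3)
    assert freqs[("B", "D")] == pytest.approx(1 / 3)

    same = partition_probs(["((A,B),(C,D));"] * 4)
    assert all(f == 1.0 for f in same.frequencies.values())

    stars = partition_probs(["(A,B,C,D);"] * 3)
    assert stars.frequencies == {}


def test_majority_splits_are_pairwise_compatible():
    trees = random_tree_sample(7, 15, seed=5)
    table = partition_probs(trees)
    majority = [b for b, f in table.frequencies.items() if f > 0.5]
    for a, b in itertools.combinations(majority, 2):
        assert (
            not (a.side & b.side) or a.side <= b.side or b.side <= a.side
        ), "majority splits must be laminar after canonical orientation"


def test_consensus_examples():
    sample = ["((A,B),(C,D));", "((A,B),(C,D));", "((A,C),(B,D));"]
    cons = consensus_tree(partition_probs(sample), 1.0)
    assert sides(bipartitions_of_tree(cons)) == {("C", "D")}

    stars = partition_probs(["(A,B,C,D);"] * 3)
    assert bipartitions_of_tree(consensus_tree(stars, 1.0)) == set()

    with pytest.raises(ValueError, match="gamma"):
        consensus_tree(partition_probs(sample), 2.0)


def test_consensus_tree_displays_exactly_the_majority_splits():
    trees = random_tree_sample(6, 11, seed=7)
    table = partition_probs(trees)
    cons = consensus_tree(table, 1.0)
    expected = {b for b, f in table.frequencies.items() if f > 0.5}
    assert bipartitions_of_tree(cons) == expected


def test_consensus_minimizes_expected_distance_over_displayable_trees():
    """Among every tree displayable from subsets of the sampled splits, the
    gamma = 1 consensus minimizes the sample-averaged topological distance."""
    trees = random_tree_sample(5, 9, seed=13)
    table = partition_probs(trees)
    sample_splits = [bipartitions_of_tree(t) for t in trees]
    universe = list(table.frequencies)

    def avg_dist(split_set):
        return sum(len(split_set ^ s) for s in sample_splits) / len(sample_splits)

    best = min(
        avg_dist(set(sub))
        for r in range(len(universe) + 1)
        for sub in itertools.combinations(universe, r)
        if _compatible(sub)
    )
    cons_splits = bipartitions_of_tree(consensus_tree(table, 1.0))
    assert avg_dist(cons_splits) == pytest.approx(best)


def _compatible(splits):
    for a, b in itertools.combinations(splits, 2):
        if a.side & b.side and not (a.side <= b.side or b.side <= a.side):
            return False
    return True


def test_bipartition_canonicalization():
    u = frozenset("ABCD")
    b1 = Bipartition.from_split({"A", "B"}, u)
    b2 = Bipartition.from_split({"C", "D"}, u)
    assert b1 == b2  # orientation-free
    with pytest.raises(ValueError):
        Bipartition.from_split({"B", "C", "D"}, u)  # trivial split


def test_parse_tree_lines_skips_blanks():
    assert parse_tree_lines("(A,B,(C,D));\n\n(A,(B,C),D);\n") == [
        "(A,B,(C,D));",
        "(A,(B,C),D);",
    ]
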