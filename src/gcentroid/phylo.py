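"""Gamma-centroid consensus of phylogenetic trees from a sampled ensemble.

An unrooted, possibly multifurcating tree over a taxon set is encoded as a
binary vector over bipartitions: cutting any internal edge splits the taxa
into two sides.  The Hamming distance between two such vectors is the
Robinson-Foulds (topological) distance — the size of the symmetric
difference of the bipartition sets.

Tree space cannot be enumerated, and no dynamic program is known for the
gamma-centroid with gamma > 1 here, so the estimator works from a sample
of trees (e.g. an MCMC posterior sample, consumed as Newick, one per
line): bipartition frequencies estimate the partitioning probabilities,
and for gamma <= 1 the consensus estimator — collect every split with
frequency > 1/(gamma+1) — is exact.  The cutoff is at least 1/2, so any
two collected splits co-occur in some sampled tree and are automatically
compatible; the unique multifurcating tree displaying exactly those splits
is assembled and returned.  At gamma = 1 this is the majority-rule
consensus, the minimizer of the expected topological distance.

Splits are canonicalized as the side *not* containing a fixed reference
taxon (the alphabetically first), making them hashable and orientation-
free.  Trivial (single-taxon) splits are excluded: they are shared by all
trees over the same taxa and cancel in every distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO

import dendropy

__all__ = [
    "Bipartition",
    "BipartitionTable",
    "bipartitions_of_tree",
    "topological_distance",
    "partition_probs",
    "consensus_tree",
    "parse_tree_lines",
]


@dataclass(frozen=True)
class Bipartition:
    """A taxon split, stored as the (frozen) side excluding the reference
    taxon of its universe."""

    side: frozenset
    universe: frozenset

    def __post_init__(self):
        ref = min(self.universe)
        if ref in self.side:
            raise ValueError("canonical side must exclude the reference taxon")
        if not self.side or len(self.side) >= len(self.universe) - 1:
            raise ValueError("bipartition sides must each hold >= 2 taxa")

    @classmethod
    def from_split(cls, side, universe) -> "Bipartition":
        universe = frozenset(universe)
        side = frozenset(side)
        ref = min(universe)
        if ref in side:
            side = universe - side
        return cls(side, universe)


@dataclass
class BipartitionTable:
    """Bipartition -> sample frequency, from a sample of trees."""

    frequencies: dict
    sample_size: int
    universe: frozenset


def _load_tree(newick: str, taxa=None) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", taxon_namespace=tns,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # normalize parser errors (incl. duplicate taxa)
        raise ValueError(f"invalid Newick tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxa in tree")
    if taxa is not None and frozenset(labels) != frozenset(taxa):
        raise ValueError(
            f"tree taxa {sorted(labels)} do not match expected {sorted(taxa)}"
        )
    return tree


def bipartitions_of_tree(newick: str, taxa=None) -> set:
    """One canonical bipartition per internal edge; leaf edges excluded.

    Branch lengths are ignored.  Rooted input is treated as unrooted, so
    the two clades meeting at a root bifurcation yield a single split.
    """
    tree = _load_tree(newick, taxa)
    universe = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    splits = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 2 <= len(clade) <= len(universe) - 2:
            splits.add(Bipartition.from_split(clade, universe))
    return splits


def topological_distance(newick1: str, newick2: str) -> int:
    """Robinson-Foulds distance: |symmetric difference| of the two trees'
    bipartition sets (equivalently the Hamming distance between their
    bipartition indicator vectors)."""
    t1 = _load_tree(newick1)
    u1 = frozenset(l.taxon.label for l in t1.leaf_node_iter())
    t2 = _load_tree(newick2)
    u2 = frozenset(l.taxon.label for l in t2.leaf_node_iter())
    if u1 != u2:
        raise ValueError("trees are over different taxon sets")
    b1 = bipartitions_of_tree(newick1)
    b2 = bipartitions_of_tree(newick2)
    return len(b1 ^ b2)


def parse_tree_lines(text: str) -> list:
    """Newick trees, one per line; blank lines ignored."""
    return [line.strip() for line in text.splitlines() if line.strip()]


def partition_probs(tree_sample: list) -> BipartitionTable:
    """Bipartition frequencies across a sample of trees over shared taxa."""
    if not tree_sample:
        raise ValueError("empty tree sample")
    universe = None
    counts: dict = {}
    for newick in tree_sample:
        tree = _load_tree(newick)
        taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        if universe is None:
            universe = taxa
        elif taxa != universe:
            raise ValueError("trees in the sample are over different taxa")
        for bp in bipartitions_of_tree(newick):
            counts[bp] = counts.get(bp, 0) + 1
    n = len(tree_sample)
    return BipartitionTable(
        frequencies={bp: c / n for bp, c in counts.items()},
        sample_size=n,
        universe=universe,
    )


def _assemble(splits: set, universe: frozenset) -> str:
    """Build the unique multifurcating tree displaying exactly ``splits``.

    The canonical (reference-excluding) sides of compatible splits form a
    laminar family, so they nest into a forest; the reference taxon and the
    top-level groups hang off a common root in the Newick output.
    """
    ordered = sorted(splits, key=lambda b: (-len(b.side), sorted(b.side)))
    ref = min(universe)

    def render(members: frozenset, inner: list) -> str:
        # inner: disjoint child clades (already rendered), covering part of members
        covered = frozenset().union(*(c for c, _ in inner)) if inner else frozenset()
        parts = [text for _, text in inner]
        parts.extend(sorted(members - covered))
        return "(" + ",".join(parts) + ")"

    def build(members: frozenset, remaining: list) -> str:
        children = []
        used: set = set()
        for idx, bp in enumerate(remaining):
            if idx in used or not bp.side < members:
                continue
            # maximal: not contained in any other remaining split within members
            if any(
                j != idx
                and remaining[j].side < members
                and bp.side < remaining[j].side
                for j in range(len(remaining))
            ):
                continue
            inside = [b for b in remaining if b.side < bp.side]
            children.append((bp.side, build(bp.side, inside)))
        return render(members, children)

    body = build(universe - {ref}, ordered)
    if len(universe - {ref}) == 0:
        return f"({ref});"
    return f"({ref},{body[1:-1]});" if body.startswith("(") else f"({ref},{body});"


def consensus_tree(table: BipartitionTable, gamma: float = 1.0) -> str:
    """Gamma-centroid consensus tree for gamma <= 1, as Newick.

    Collects every bipartition with frequency > 1/(gamma+1) and assembles
    the multifurcating tree displaying exactly those splits.  For gamma > 1
    no efficient search of tree space is available and the call is refused.
    Ties at exactly the cutoff are excluded (strict inequality).
    """
    if not 0 < gamma <= 1:
        raise ValueError(
            "the tree gamma-centroid is only computable as a consensus for "
            "gamma <= 1; no efficient estimator exists for gamma > 1"
        )
    cut = 1.0 / (gamma + 1.0)
    chosen = {bp for bp, f in table.frequencies.items() if f > cut}
    # sanity: frequencies > 1/2 guarantee pairwise compatibility
    for a in chosen:
        for b in chosen:
            sa, sb = a.side, b.side
            if sa & sb and not (sa <= sb or sb <= sa):
                raise ValueError("incompatible majority splits (corrupt table)")
    return _assemble(chosen, table.universe)
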