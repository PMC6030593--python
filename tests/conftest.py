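"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: trees are
nested tuples, MIG is computed by direct recursion, and the Gmin/Gmax bounds
come from brute-force enumeration of every rooted binary labeled topology.
"""

from __future__ import annotations

import dendropy
import pytest

from stratcong import RangeTable, TaxonRange


# ---------------------------------------------------------------------------
# oracles (nested-tuple trees; a leaf is a label string)


def enumerate_rooted_binary(taxa: list[str]):
    """All rooted binary labeled topologies on ``taxa`` ((2n−3)!! of them).

    Built by sequential taxon addition: the k-th taxon is attached to every
    edge of every (k−1)-taxon tree, including above the root.
    """
    if not taxa:
        return []
    trees = [taxa[0]]
    for taxon in taxa[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_attach_everywhere(t, taxon))
        trees = nxt
    return trees


def _attach_everywhere(tree, taxon):
    out = [(tree, taxon)]  # new root above the old one
    if isinstance(tree, tuple):
        left, right = tree
        out.extend((l2, right) for l2 in _attach_everywhere(left, taxon))
        out.extend((left, r2) for r2 in _attach_everywhere(right, taxon))
    return out


def oracle_mig(tree, fads: dict[str, float]) -> float:
    """MIG by direct recursion over a nested-tuple tree."""

    def rec(node):
        if isinstance(node, str):
            return fads[node], 0.0
        ages_migs = [rec(ch) for ch in node]
        age = max(a for a, _ in ages_migs)
        mig = sum(m + (age - a) for a, m in ages_migs)
        return age, mig

    return rec(tree)[1]


def oracle_gmin_gmax(fads: dict[str, float]) -> tuple[float, float]:
    """Brute-force extremal MIG over every rooted binary topology."""
    migs = [
        oracle_mig(t, fads) for t in enumerate_rooted_binary(sorted(fads))
    ]
    return min(migs), max(migs)


def tuple_to_newick(tree) -> str:
    def rec(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(rec(ch) for ch in node) + ")"

    return rec(tree) + ";"


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial rooted clades as tip-label sets (independent of any
    package tree comparison code)."""
    out = set()
    for nd in tree.postorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        tips = frozenset(
            lf.taxon.label if lf.taxon else lf.label
            for lf in nd.leaf_iter()
        )
        out.add(tips)
    return out


def rf_distance(a: dendropy.Tree, b: dendropy.Tree) -> int:
    return len(bipartitions(a) ^ bipartitions(b))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def three_taxon_ranges() -> RangeTable:
    """The worked 3-taxon table: A(10,8), B(5,4), C(1,0)."""
    return RangeTable(
        [TaxonRange("A", 10, 8), TaxonRange("B", 5, 4), TaxonRange("C", 1, 0)]
    )


def parse_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        rooting="default-rooted",
    )


@pytest.fixture
def good_tree() -> dendropy.Tree:
    """((B,C),A): congruent with the worked ranges."""
    return parse_newick("((B,C),A);")


@pytest.fixture
def bad_tree() -> dendropy.Tree:
    """((A,B),C): the worst topology for the worked ranges."""
    return parse_newick("((A,B),C);")


def pectinate_newick(labels: list[str]) -> str:
    """Age-ordered ladder: labels[0] outermost (oldest first attains Gmin)."""
    inner = f"({labels[-2]},{labels[-1]})"
    for lab in reversed(labels[1:-2]):
        inner = f"({lab},{inner})"
    return f"({labels[0]},{inner});"


def make_ranges(fads: dict[str, float], duration: float = 0.0) -> RangeTable:
    return RangeTable(
        TaxonRange(t, f, max(0.0, f - duration)) for t, f in fads.items()
    )
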