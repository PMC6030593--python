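"""Synthetic studies: true trees, fossil ranges, and noisy tree sets.

The generator emulates the structure a stratigraphic-congruence
meta-analysis consumes, one dataset at a time:

1. a true rooted tree from a pure-birth (Yule) process, with node times in
   Ma (present = 0, root oldest);
2. fossil ranges per tip: the first appearance lags the lineage's
   origination (its parent node's time) by an exponential preservation gap,
   and the observed range length is an independent exponential draw — both
   truncated so that FAD >= LAD >= 0 always holds;
3. two or more "method" tree sets derived from the truth by random rooted
   nearest-neighbour-interchange (NNI) moves, the number of moves acting as
   an interpretable accuracy knob (0 moves = the true topology).

Because the FAD is lagged from the tip's origination, the true tree scored
with gap-free ranges (``preservation_gap_mean`` → 0) has MIG exactly equal
to the sum of its internal-edge durations — a useful analytic check.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .datasets import MatrixRecord
from .io import RangeTable, TaxonRange

__all__ = [
    "SimConfig",
    "simulate_tree",
    "simulate_ranges",
    "perturb_treeset",
    "random_nni",
    "generate_study",
]

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings.

    Defaults describe a modest fossil-tetrapod-like study: 30 datasets of
    20–40 tips each; a Yule birth rate of 0.1 per lineage-Myr (root ages on
    the order of tens of Myr); exponential preservation gaps and observed
    range lengths with 5 Myr means; 50 trees per method set; method A one
    NNI move from the truth per tree, method B ten.
    """

    n_datasets: int = 30
    tips_range: tuple[int, int] = (20, 40)
    birth_rate: float = 0.1  # per-lineage splits per Myr
    preservation_gap_mean: float = 5.0  # Myr
    range_length_mean: float = 5.0  # Myr
    trees_per_set: int = 50
    moves_a: int = 1
    moves_b: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tips_range
        if lo < 4 or hi < lo:
            raise ValueError("tips_range must satisfy 4 <= lo <= hi")
        if self.n_datasets < 1 or self.trees_per_set < 1:
            raise ValueError("n_datasets and trees_per_set must be >= 1")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.preservation_gap_mean < 0 or self.range_length_mean < 0:
            raise ValueError("gap and range means must be >= 0")
        if self.moves_a < 0 or self.moves_b < 0:
            raise ValueError("move counts must be >= 0")


def simulate_tree(n_tips: int, birth_rate: float, seed: SeedLike = 0) -> dendropy.Tree:
    """Grow a pure-birth tree to ``n_tips`` extant lineages.

    Every node carries its time in Ma before present as ``node.age`` (tips
    at 0, root oldest); edge lengths are set from the ages so the tree
    serializes with meaningful branch lengths, though downstream metrics
    never read them.  Tip labels are ``t1 … tn``.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    root.sim_time = 0.0
    active = []
    for _ in range(2):
        ch = root.new_child()
        active.append(ch)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.sim_time = t
        for _ in range(2):
            active.append(node.new_child())
    # let the last cherry age before the present so no terminal edge is 0
    total = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for k, leaf in enumerate(active):
        leaf.sim_time = total
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"t{k + 1}")
    for node in tree.preorder_node_iter():
        node.age = total - node.sim_time
        del node.sim_time
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return tree


def simulate_ranges(
    true_tree: dendropy.Tree,
    gap_mean: float,
    range_mean: float,
    seed: SeedLike = 0,
) -> RangeTable:
    """Draw fossil ranges for every tip of a tree with ``node.age`` times.

    FAD = (parent node age) − Exp(gap_mean), truncated below at 0;
    LAD = FAD − Exp(range_mean), truncated below at 0.
    """
    rng = _rng(seed)
    rows = []
    for leaf in true_tree.leaf_node_iter():
        if leaf.parent_node is None:
            raise ValueError("true tree must have >= 2 tips")
        orig = leaf.parent_node.age
        gap = rng.exponential(gap_mean) if gap_mean > 0 else 0.0
        fad = max(0.0, orig - gap)
        dur = rng.exponential(range_mean) if range_mean > 0 else 0.0
        lad = max(0.0, fad - dur)
        rows.append(TaxonRange(leaf.taxon.label, fad, lad))
    return RangeTable(rows)


def _nni_candidates(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Internal non-root nodes, i.e. heads of internal edges.

    This set is invariant under NNI (nodes change children, never their
    internal/leaf status), so callers may compute it once per tree and
    reuse it across moves.
    """
    return [
        nd
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]


def _fast_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Structure-only copy sharing the taxon namespace (no edge lengths)."""

    def rec(nd):
        new = dendropy.Node()
        new.taxon = nd.taxon
        for ch in nd.child_nodes():
            new.add_child(rec(ch))
        return new

    out = dendropy.Tree(taxon_namespace=tree.taxon_namespace)
    out.seed_node = rec(tree.seed_node)
    return out


def _nni_on(v: dendropy.Node, rng: np.random.Generator) -> None:
    u = v.parent_node
    u_kids = u.child_nodes()
    v_kids = v.child_nodes()
    if len(u_kids) != 2 or len(v_kids) != 2:
        raise ValueError("NNI requires a binary tree")
    sibling = u_kids[0] if u_kids[1] is v else u_kids[1]
    c = v_kids[int(rng.integers(2))]
    c_keep = v_kids[0] if v_kids[1] is c else v_kids[1]
    u.set_child_nodes([v, c])
    v.set_child_nodes([c_keep, sibling])


def random_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """Apply one random rooted NNI move in place.

    Picks a random internal edge (parent *u* → internal child *v*) and swaps
    a random child of *v* with *v*'s sibling.  Requires a binary tree; the
    move preserves binarity and the tip set.
    """
    cands = _nni_candidates(tree)
    if not cands:
        raise ValueError("tree has no internal edge: NNI undefined")
    _nni_on(cands[int(rng.integers(len(cands)))], rng)


def perturb_treeset(
    true_tree: dendropy.Tree,
    n_trees: int,
    n_moves: int,
    seed: SeedLike = 0,
) -> list[dendropy.Tree]:
    """``n_trees`` copies of the truth, each degraded by ``n_moves`` random
    NNI moves; tip sets are preserved and the trees stay binary.  Edge
    lengths are dropped (they are meaningless after topology moves)."""
    if n_trees < 1:
        raise ValueError(f"n_trees must be >= 1, got {n_trees}")
    if n_moves < 0:
        raise ValueError(f"n_moves must be >= 0, got {n_moves}")
    for nd in true_tree.preorder_node_iter():
        if not nd.is_leaf() and len(nd.child_nodes()) != 2:
            raise ValueError("perturbation requires a binary input tree")
    rng = _rng(seed)
    out = []
    for _ in range(n_trees):
        t = _fast_copy(true_tree)
        cands = _nni_candidates(t)
        if n_moves > 0 and not cands:
            raise ValueError("tree has no internal edge: NNI undefined")
        for _ in range(n_moves):
            _nni_on(cands[int(rng.integers(len(cands)))], rng)
        out.append(t)
    return out


def generate_study(config: SimConfig) -> list[MatrixRecord]:
    """Generate a full synthetic study: one :class:`MatrixRecord` per dataset
    with tree sets ``method_a`` and ``method_b`` at the configured noise
    levels, and ``strat_fig`` flags assigned alternately.  Fully reproducible
    from ``config.seed``."""
    root_ss = np.random.SeedSequence(config.seed)
    records = []
    for i, ss in enumerate(root_ss.spawn(config.n_datasets)):
        s_tips, s_tree, s_ranges, s_a, s_b = ss.spawn(5)
        lo, hi = config.tips_range
        n_tips = int(_rng(s_tips).integers(lo, hi + 1))
        tree = simulate_tree(n_tips, config.birth_rate, seed=s_tree)
        # each dataset gets its own taxa, as in independent published
        # matrices after overlap screening
        for taxon in tree.taxon_namespace:
            taxon.label = f"sim{i:03d}_{taxon.label}"
        ranges = simulate_ranges(
            tree, config.preservation_gap_mean, config.range_length_mean,
            seed=s_ranges,
        )
        rec = MatrixRecord(
            dataset_id=f"sim{i:03d}",
            ranges=ranges,
            tree_sets={
                "method_a": perturb_treeset(
                    tree, config.trees_per_set, config.moves_a, seed=s_a
                ),
                "method_b": perturb_treeset(
                    tree, config.trees_per_set, config.moves_b, seed=s_b
                ),
            },
            strat_fig=(i % 2 == 0),
        )
        rec.validate()
        records.append(rec)
    return records
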