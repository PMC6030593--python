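"""Stratigraphic congruence metrics for a single dated tree.

The four metrics compare a rooted tree's branching order with the first
appearances (FADs) of its tips in the fossil record:

* **MIG** — minimum implied gap: total ghost-range duration when every node
  is dated to the oldest FAD among its descendant tips ("basic" dating).
* **Gmin / Gmax** — the smallest / largest MIG attainable by any fully
  resolved rooted tree on the same taxa; the normalizing bounds below.
* **SCI** — stratigraphic consistency index: the proportion of assessed
  internal nodes whose sister group has a FAD at least as old as the oldest
  FAD in the node's own clade.
* **RCI** — relative completeness index, ``(1 − MIG/SRL) × 100`` where SRL is
  the summed observed range length; can be negative.
* **GER** — gap excess ratio, ``1 − (MIG − Gmin)/(Gmax − Gmin)``; 1 is a
  perfect fit, 0 the worst possible.
* **MSM*** — modified Manhattan stratigraphic measure, ``Gmin/MIG``.

All ages are in Ma before present (larger = older); all gaps are in Myr.
Topology is the only tree information used — input branch lengths are
ignored and node ages are recomputed from FADs.

Degenerate inputs (all FADs tied, zero summed range length) make GER, MSM*
or RCI undefined; the single-metric functions raise
:class:`UndefinedMetricError` while :func:`score_tree` carries the
undefined metric as ``None`` so downstream averaging can skip it, never
coercing it to 0 or 1.

Polytomies are allowed: dating and MIG generalize unchanged, and for SCI the
sister group of a child is the pooled set of its parent's remaining children.
Gmin and Gmax remain the published fully-resolved bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy

from .io import MissingTaxonError, RangeTable, StratcongError, normalize_label

__all__ = [
    "UndefinedMetricError",
    "METRIC_NAMES",
    "DatedPhylo",
    "CongruenceScores",
    "TreeIndex",
    "date_nodes",
    "compute_mig",
    "compute_gmin",
    "compute_gmax",
    "compute_sci",
    "compute_rci",
    "compute_ger",
    "compute_msm_star",
    "score_tree",
]

#: the four congruence metrics, in reporting order
METRIC_NAMES = ("sci", "rci", "ger", "msm_star")


class UndefinedMetricError(StratcongError, ArithmeticError):
    """A metric's defining ratio is degenerate for this input."""


class TreeIndex:
    """Flat, reusable index of a rooted tree's topology.

    Nodes are numbered in postorder (root last).  Built once per tree, an
    index lets permutation tests and tree-set summaries rescore the same
    topology under many FAD assignments without touching dendropy again.
    """

    __slots__ = ("parent", "children", "leaves", "labels", "n_nodes", "root")

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.parent: list[int] = [-1] * self.n_nodes
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.leaves: list[int] = []
        self.labels: list[str] = []
        for i, nd in enumerate(nodes):
            for ch in nd.child_nodes():
                j = index[id(ch)]
                self.parent[j] = i
                self.children[i].append(j)
            if not nd.child_nodes():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                self.leaves.append(i)
                self.labels.append(normalize_label(label))

    @property
    def n_tips(self) -> int:
        return len(self.leaves)

    def leaf_fads(self, ranges: RangeTable) -> list[float]:
        """FADs aligned with :attr:`leaves`; raises on missing taxa."""
        missing = [lab for lab in self.labels if lab not in ranges]
        if missing:
            raise MissingTaxonError(missing)
        return [ranges.fad(lab) for lab in self.labels]

    # -- fast kernels -------------------------------------------------------

    def clade_ages(self, leaf_fads: Sequence[float]) -> list[float]:
        """Basic node dating: per node, the oldest FAD among descendant tips."""
        age = [0.0] * self.n_nodes
        for i, fad in zip(self.leaves, leaf_fads):
            age[i] = fad
        for i in range(self.n_nodes):  # postorder: children precede parents
            kids = self.children[i]
            if kids:
                age[i] = max(age[j] for j in kids)
        return age

    def mig(self, leaf_fads: Sequence[float]) -> float:
        """Minimum implied gap: Σ over edges of (parent age − child age)."""
        age = self.clade_ages(leaf_fads)
        parent = self.parent
        return sum(age[parent[i]] - age[i] for i in range(self.n_nodes - 1))

    def sci(self, leaf_fads: Sequence[float], count_root: bool = False) -> float:
        """Stratigraphic consistency index.

        A non-root internal node is consistent iff the oldest FAD among its
        pooled sister group is >= the oldest FAD in its own clade (a tie is
        consistent: an equal-aged sister implies no ghost range).  With
        ``count_root`` the root joins the denominator as automatically
        consistent, matching the alternative published convention.
        """
        age = self.clade_ages(leaf_fads)
        assessed = 0
        consistent = 0
        for i in range(self.n_nodes - 1):
            if not self.children[i]:
                continue
            assessed += 1
            sibs = [j for j in self.children[self.parent[i]] if j != i]
            if max(age[j] for j in sibs) >= age[i]:
                consistent += 1
        if count_root:
            assessed += 1
            consistent += 1
        if assessed == 0:
            raise UndefinedMetricError(
                "SCI needs at least one assessable internal node (>= 3 tips)"
            )
        return consistent / assessed


# ---------------------------------------------------------------------------
# single-metric operations


@dataclass
class DatedPhylo:
    """A tree with node ages assigned by basic (oldest-descendant-FAD) dating."""

    tree: dendropy.Tree
    index: TreeIndex
    node_ages: list[float]  # aligned with index postorder numbering

    @property
    def root_age(self) -> float:
        return self.node_ages[self.index.root]


def date_nodes(tree: dendropy.Tree, ranges: RangeTable) -> DatedPhylo:
    """Date every node: tip age = its FAD, internal age = oldest descendant FAD.

    Raises :class:`MissingTaxonError` naming any tip absent from ``ranges``.
    """
    idx = TreeIndex(tree)
    fads = idx.leaf_fads(ranges)
    return DatedPhylo(tree=tree, index=idx, node_ages=idx.clade_ages(fads))


def compute_mig(dated: DatedPhylo) -> float:
    """Summed ghost-range duration (Myr) under basic dating."""
    age = dated.node_ages
    parent = dated.index.parent
    return sum(age[parent[i]] - age[i] for i in range(dated.index.n_nodes - 1))


def compute_gmin(ranges: RangeTable | Sequence[float]) -> float:
    """Minimum MIG over all fully resolved rooted trees on these taxa.

    Attained by the pectinate tree ordered oldest-to-outermost; closed form
    ``max(FAD) − min(FAD)``.  (The identity is verified against exhaustive
    topology enumeration in the test suite.)
    """
    fads = list(ranges.fads() if isinstance(ranges, RangeTable) else ranges)
    if len(fads) < 2:
        raise ValueError("Gmin requires at least 2 taxa")
    return max(fads) - min(fads)


def compute_gmax(ranges: RangeTable | Sequence[float]) -> float:
    """Maximum MIG over all fully resolved rooted trees on these taxa.

    Closed form: Σ over all taxa except one oldest of (max FAD − FAD), i.e.
    every lineage is forced back to the oldest first appearance.  (Verified
    against exhaustive topology enumeration in the test suite.)
    """
    fads = list(ranges.fads() if isinstance(ranges, RangeTable) else ranges)
    if len(fads) < 2:
        raise ValueError("Gmax requires at least 2 taxa")
    oldest = max(fads)
    return sum(oldest - f for f in fads) - 0.0  # oldest taxon contributes 0


def compute_sci(
    tree: dendropy.Tree, ranges: RangeTable, count_root: bool = False
) -> float:
    """Proportion of assessed internal nodes that are stratigraphically
    consistent; see :meth:`TreeIndex.sci` for the convention."""
    idx = TreeIndex(tree)
    if idx.n_tips < 3:
        raise ValueError("SCI requires at least 3 tips")
    return idx.sci(idx.leaf_fads(ranges), count_root=count_root)


def compute_rci(mig: float, srl: float) -> float:
    """Relative completeness index, ``(1 − MIG/SRL) × 100``.

    Undefined when SRL = 0 (all taxa are point occurrences).
    """
    if srl <= 0:
        raise UndefinedMetricError("RCI undefined: summed range length is 0")
    return (1.0 - mig / srl) * 100.0


def compute_ger(mig: float, g_min: float, g_max: float) -> float:
    """Gap excess ratio, ``1 − (MIG − Gmin)/(Gmax − Gmin)``; 1 = best fit.

    Undefined when Gmax = Gmin (all FADs tied).
    """
    if not (g_min <= mig <= g_max):
        raise ValueError(f"MIG {mig} outside bounds [{g_min}, {g_max}]")
    if g_max == g_min:
        raise UndefinedMetricError("GER undefined: Gmax equals Gmin")
    return 1.0 - (mig - g_min) / (g_max - g_min)


def compute_msm_star(g_min: float, mig: float) -> float:
    """Modified Manhattan stratigraphic measure, ``Gmin/MIG``; 1 = best fit.

    Undefined when MIG = 0 (which forces Gmin = 0: all FADs tied).
    """
    if g_min < 0 or mig < g_min:
        raise ValueError(f"need MIG >= Gmin >= 0, got Gmin={g_min}, MIG={mig}")
    if mig == 0:
        raise UndefinedMetricError("MSM* undefined: MIG is 0 (all ages tied)")
    return g_min / mig


# ---------------------------------------------------------------------------
# combined scoring


@dataclass
class CongruenceScores:
    """All congruence quantities for one tree.

    ``sci``, ``rci``, ``ger`` and ``msm_star`` are ``None`` when undefined
    for this input (degenerate denominators); ``None`` values are excluded
    from any downstream averaging.
    """

    mig: float
    g_min: float
    g_max: float
    srl: float
    sci: Optional[float]
    rci: Optional[float]
    ger: Optional[float]
    msm_star: Optional[float]

    def metric(self, name: str) -> Optional[float]:
        if name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def defined(self, name: str) -> bool:
        return self.metric(name) is not None

    def as_dict(self) -> dict:
        return {
            "mig": self.mig,
            "g_min": self.g_min,
            "g_max": self.g_max,
            "srl": self.srl,
            "sci": self.sci,
            "rci": self.rci,
            "ger": self.ger,
            "msm_star": self.msm_star,
        }


def _score_indexed(
    idx: TreeIndex,
    leaf_fads: Sequence[float],
    srl: float,
    count_root: bool = False,
) -> CongruenceScores:
    """Score a pre-indexed topology under an explicit FAD assignment."""
    mig = idx.mig(leaf_fads)
    g_min = compute_gmin(leaf_fads)
    g_max = compute_gmax(leaf_fads)
    try:
        sci = idx.sci(leaf_fads, count_root=count_root)
    except UndefinedMetricError:
        sci = None
    try:
        rci = compute_rci(mig, srl)
    except UndefinedMetricError:
        rci = None
    try:
        ger = compute_ger(mig, g_min, g_max)
    except UndefinedMetricError:
        ger = None
    try:
        msm_star = compute_msm_star(g_min, mig)
    except UndefinedMetricError:
        msm_star = None
    return CongruenceScores(
        mig=mig, g_min=g_min, g_max=g_max, srl=srl,
        sci=sci, rci=rci, ger=ger, msm_star=msm_star,
    )


def score_tree(
    tree: dendropy.Tree,
    ranges: RangeTable,
    count_root: bool = False,
    prune_unmatched: bool = False,
) -> CongruenceScores:
    """Compute MIG, Gmin, Gmax, SRL and the four congruence metrics.

    SRL is summed over the tree's tips only (Σ FAD − LAD).  Tips absent from
    ``ranges`` raise :class:`MissingTaxonError` unless ``prune_unmatched``
    is set, in which case they are pruned from a working copy of the tree —
    the opt-in exists so that silent data mismatches stay loud by default.
    """
    idx = TreeIndex(tree)
    if prune_unmatched:
        missing = [lab for lab in idx.labels if lab not in ranges]
        if missing:
            work = tree.clone(depth=1)
            keep = [
                leaf.taxon for leaf in work.leaf_node_iter()
                if normalize_label(leaf.taxon.label) not in missing
            ]
            if len(keep) < 3:
                raise ValueError(
                    "fewer than 3 tips remain after pruning unmatched taxa"
                )
            work.retain_taxa(keep)
            idx = TreeIndex(work)
    if idx.n_tips < 3:
        raise ValueError("scoring requires at least 3 tips")
    fads = idx.leaf_fads(ranges)
    srl = sum(ranges[lab].duration for lab in idx.labels)
    return _score_indexed(idx, fads, srl, count_root=count_root)
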