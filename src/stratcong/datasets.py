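"""Per-dataset tree-set summarization and cross-dataset overlap filtering.

A *dataset* bundles one taxon range table with one or more sets of trees,
one set per tree-search method (e.g. equal-weight parsimony versus a
Bayesian posterior sample).  Large tree sets are subsampled to a cap
(default 500) before scoring, and per-metric means are taken over the
sampled trees, skipping trees where a metric is undefined.

Because published matrices reuse taxa heavily, datasets are screened for
taxonomic overlap before any cross-dataset statistics: records are greedily
eliminated, lowest unique-taxon proportion first, until every retained
record has at least ``min_unique`` unique taxa and the mean proportion
reaches ``target_avg`` (defaults 50% / 75%).  Uniqueness is always evaluated
against the currently retained records, so proportions are recomputed after
every removal, and the full elimination sequence is logged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import RangeTable, ValidationError, read_ranges, read_trees, tip_labels
from .metrics import METRIC_NAMES, TreeIndex, _score_indexed

__all__ = [
    "DEFAULT_TREE_CAP",
    "MatrixRecord",
    "TreeSetSummary",
    "subsample_trees",
    "summarize_treeset",
    "filter_datasets",
    "read_manifest",
    "write_manifest",
]

#: default maximum number of trees scored per set
DEFAULT_TREE_CAP = 500


@dataclass
class MatrixRecord:
    """One dataset: ranges, per-method tree sets, and metadata flags.

    ``strat_fig`` records whether the source publication figured a tree
    optimized against stratigraphic ranges — carried through and exported,
    but not used by any computation here.
    """

    dataset_id: str
    ranges: RangeTable
    tree_sets: dict[str, list[dendropy.Tree]]
    strat_fig: bool = False

    def validate(self) -> None:
        if not self.tree_sets or not any(self.tree_sets.values()):
            raise ValidationError(
                f"dataset {self.dataset_id!r}: needs >= 1 method with >= 1 tree"
            )
        taxa = set(self.ranges.taxa)
        for method, trees in self.tree_sets.items():
            for i, t in enumerate(trees):
                extra = set(tip_labels(t)) - taxa
                if extra:
                    raise ValidationError(
                        f"dataset {self.dataset_id!r}, method {method!r}, tree {i}: "
                        f"tips not in range table: {sorted(extra)}"
                    )

    @property
    def taxa(self) -> set[str]:
        return set(self.ranges.taxa)


@dataclass
class TreeSetSummary:
    """Per-metric means over a (subsampled) tree set for one dataset+method."""

    dataset_id: str
    method: str
    n_trees_total: int
    n_sampled: int
    means: dict[str, Optional[float]]
    defined_counts: dict[str, int]

    def mean(self, metric: str) -> Optional[float]:
        if metric not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric!r}")
        return self.means[metric]

    def as_dict(self) -> dict:
        out: dict = {
            "dataset_id": self.dataset_id,
            "method": self.method,
            "n_trees_total": self.n_trees_total,
            "n_sampled": self.n_sampled,
        }
        for m in METRIC_NAMES:
            out[f"{m}_mean"] = self.means[m]
            out[f"{m}_n_defined"] = self.defined_counts[m]
        return out


def subsample_trees(
    trees: Sequence[dendropy.Tree], cap: int = DEFAULT_TREE_CAP, seed: int = 0
) -> list[dendropy.Tree]:
    """At most ``cap`` trees: all of them (original order) if the set fits,
    else a uniform random sample without replacement, reproducible by seed."""
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree collection")
    if len(trees) <= cap:
        return trees
    rng = np.random.default_rng(seed)
    keep = sorted(rng.choice(len(trees), size=cap, replace=False))
    return [trees[i] for i in keep]


def summarize_treeset(
    trees: Sequence[dendropy.Tree],
    ranges: RangeTable,
    cap: int = DEFAULT_TREE_CAP,
    seed: int = 0,
    dataset_id: str = "",
    method: str = "",
    count_root: bool = False,
) -> TreeSetSummary:
    """Score each sampled tree and average each metric over the trees where
    it is defined; a metric undefined on every tree is reported as ``None``
    with a defined-count of 0."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree set")
    sampled = subsample_trees(trees, cap=cap, seed=seed)
    sums = {m: 0.0 for m in METRIC_NAMES}
    counts = {m: 0 for m in METRIC_NAMES}
    for tree in sampled:
        idx = TreeIndex(tree)
        fads = idx.leaf_fads(ranges)
        srl = sum(ranges[lab].duration for lab in idx.labels)
        scores = _score_indexed(idx, fads, srl, count_root=count_root)
        for m in METRIC_NAMES:
            v = scores.metric(m)
            if v is not None:
                sums[m] += v
                counts[m] += 1
    if all(c == 0 for c in counts.values()):
        raise ValueError(
            f"dataset {dataset_id!r}, method {method!r}: "
            "no tree yields any defined metric"
        )
    means = {
        m: (sums[m] / counts[m] if counts[m] else None) for m in METRIC_NAMES
    }
    return TreeSetSummary(
        dataset_id=dataset_id,
        method=method,
        n_trees_total=len(trees),
        n_sampled=len(sampled),
        means=means,
        defined_counts=counts,
    )


# ---------------------------------------------------------------------------
# taxonomic-overlap elimination


def _unique_proportions(taxa_sets: dict[str, set[str]]) -> dict[str, float]:
    counts: dict[str, int] = {}
    for s in taxa_sets.values():
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    return {
        d: sum(1 for t in s if counts[t] == 1) / len(s)
        for d, s in taxa_sets.items()
    }


def filter_datasets(
    records: Sequence[MatrixRecord],
    min_unique: float = 0.5,
    target_avg: float = 0.75,
) -> tuple[list[MatrixRecord], pd.DataFrame]:
    """Greedy sequential elimination to limit taxonomic overlap.

    A taxon is *unique* to a record if it occurs in no other retained record.
    While any record's unique proportion < ``min_unique`` or the mean
    proportion < ``target_avg`` (and more than one record remains), remove
    the record with the lowest proportion; ties are broken toward the record
    sharing the most taxon occurrences with other retained records, then
    toward the lexicographically smallest ``dataset_id``.  Proportions are
    recomputed after every removal.

    Returns the retained records (input order) and an elimination log with
    one row per removal recording the proportions at that step.
    """
    if not (0 <= min_unique <= 1 and 0 <= target_avg <= 1):
        raise ValueError("min_unique and target_avg must lie in [0, 1]")
    records = list(records)
    if not records:
        raise ValueError("no datasets supplied")
    ids = [r.dataset_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate dataset_id among records")

    taxa_sets = {r.dataset_id: set(r.ranges.taxa) for r in records}
    retained = dict(taxa_sets)
    log_rows: list[dict] = []
    step = 0
    while len(retained) > 1:
        props = _unique_proportions(retained)
        mean_prop = sum(props.values()) / len(props)
        if min(props.values()) >= min_unique and mean_prop >= target_avg:
            break
        # shared-occurrence count: for each taxon, in how many *other*
        # retained records it also appears
        counts: dict[str, int] = {}
        for s in retained.values():
            for t in s:
                counts[t] = counts.get(t, 0) + 1
        shared = {
            d: sum(counts[t] - 1 for t in s) for d, s in retained.items()
        }
        victim = min(retained, key=lambda d: (props[d], -shared[d], d))
        step += 1
        log_rows.append(
            {
                "step": step,
                "eliminated": victim,
                "unique_proportion": props[victim],
                "min_proportion": min(props.values()),
                "mean_proportion": mean_prop,
                "n_retained_before": len(retained),
            }
        )
        del retained[victim]

    kept = [r for r in records if r.dataset_id in retained]
    log = pd.DataFrame(
        log_rows,
        columns=[
            "step",
            "eliminated",
            "unique_proportion",
            "min_proportion",
            "mean_proportion",
            "n_retained_before",
        ],
    )
    return kept, log


# ---------------------------------------------------------------------------
# manifests


def read_manifest(path: str | Path) -> list[MatrixRecord]:
    """Load a JSON dataset manifest.

    The manifest is a list of objects with keys ``dataset_id``, ``ranges``
    (path to a taxon,fad,lad table), ``trees`` (map from method label to a
    Newick/NEXUS file; format inferred from the extension), and optional
    ``strat_fig``.  Relative paths are resolved against the manifest's
    directory.
    """
    path = Path(path)
    with open(path) as fh:
        entries = json.load(fh)
    base = path.parent
    records = []
    for entry in entries:
        did = entry["dataset_id"]
        ranges = read_ranges(base / entry["ranges"])
        tree_sets = {}
        for method, tfile in entry["trees"].items():
            tpath = base / tfile
            if not tpath.exists():
                raise FileNotFoundError(
                    f"dataset {did!r}: tree file not found: {tpath}"
                )
            fmt = "nexus" if tpath.suffix.lower() in (".nex", ".nexus", ".trees") else "newick"
            tree_sets[method] = read_trees(tpath, format=fmt)
        rec = MatrixRecord(
            dataset_id=did,
            ranges=ranges,
            tree_sets=tree_sets,
            strat_fig=bool(entry.get("strat_fig", False)),
        )
        rec.validate()
        records.append(rec)
    if not records:
        raise ValidationError(f"empty manifest: {path}")
    return records


def write_manifest(
    records: Sequence[MatrixRecord], out_dir: str | Path
) -> Path:
    """Write records as a file bundle: per-dataset ranges CSV + per-method
    Newick files + ``manifest.json`` tying them together.  Returns the
    manifest path."""
    from .io import write_ranges, write_trees

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        rfile = f"{rec.dataset_id}_ranges.csv"
        write_ranges(rec.ranges, out_dir / rfile)
        trees_entry = {}
        for method, trees in rec.tree_sets.items():
            tfile = f"{rec.dataset_id}_{method}.nwk"
            write_trees(trees, out_dir / tfile, format="newick")
            trees_entry[method] = tfile
        entries.append(
            {
                "dataset_id": rec.dataset_id,
                "ranges": rfile,
                "trees": trees_entry,
                "strat_fig": rec.strat_fig,
            }
        )
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump(entries, fh, indent=1)
        fh.write("\n")
    return manifest
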