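"""Reading and writing trees, taxon age-range tables, and result tables.

Trees are handled as :class:`dendropy.Tree` objects (rooted; branch lengths,
if present, are carried but ignored by all downstream metrics — node dating is
always recomputed from first-appearance data).  Age ranges are plain tables of
(taxon, FAD, LAD) with ages in Ma before present: larger numbers are older,
and FAD >= LAD >= 0 for every taxon.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import pandas as pd

__all__ = [
    "StratcongError",
    "ValidationError",
    "MissingTaxonError",
    "TaxonRange",
    "RangeTable",
    "normalize_label",
    "read_trees",
    "write_trees",
    "read_ranges",
    "write_ranges",
    "write_results",
    "read_results",
    "tip_labels",
]


class StratcongError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(StratcongError, ValueError):
    """Input data violates a documented invariant."""


class MissingTaxonError(StratcongError, KeyError):
    """A tree tip has no entry in the range table."""

    def __init__(self, taxa: Sequence[str]):
        self.taxa = list(taxa)
        super().__init__(
            "tree tip(s) missing from range table: " + ", ".join(sorted(self.taxa))
        )

    def __str__(self) -> str:  # KeyError quotes its arg otherwise
        return self.args[0]


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Normalize a taxon label: trim, collapse internal whitespace to ``_``.

    This single normalization is applied to both tree tip labels and range
    table taxa before matching, because published matrices mix space and
    underscore conventions.
    """
    return _WS.sub("_", label.strip())


@dataclass(frozen=True)
class TaxonRange:
    """First (FAD) and last (LAD) appearance of one taxon, in Ma.

    Ages run positive into the past, so ``fad >= lad >= 0``.
    """

    taxon_id: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValidationError("taxon_id must be non-empty")
        if not (math.isfinite(self.fad) and math.isfinite(self.lad)):
            raise ValidationError(f"non-finite age for taxon {self.taxon_id!r}")
        if self.lad < 0:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: LAD {self.lad} is negative"
            )
        if self.fad < self.lad:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: FAD {self.fad} < LAD {self.lad} "
                "(ages are Ma before present; FAD must be the older bound)"
            )

    @property
    def duration(self) -> float:
        """Observed range length, FAD − LAD, in Myr."""
        return self.fad - self.lad


class RangeTable:
    """Ordered collection of :class:`TaxonRange` with unique taxon ids."""

    def __init__(self, ranges: Iterable[TaxonRange]):
        self._ranges: list[TaxonRange] = list(ranges)
        self._by_taxon: dict[str, TaxonRange] = {}
        for r in self._ranges:
            if r.taxon_id in self._by_taxon:
                raise ValidationError(f"duplicate taxon {r.taxon_id!r} in range table")
            self._by_taxon[r.taxon_id] = r

    def __len__(self) -> int:
        return len(self._ranges)

    def __iter__(self) -> Iterator[TaxonRange]:
        return iter(self._ranges)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._by_taxon

    def __getitem__(self, taxon_id: str) -> TaxonRange:
        return self._by_taxon[taxon_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RangeTable):
            return NotImplemented
        return self._ranges == other._ranges

    def __repr__(self) -> str:
        return f"RangeTable({len(self)} taxa)"

    @property
    def taxa(self) -> list[str]:
        return [r.taxon_id for r in self._ranges]

    def fad(self, taxon_id: str) -> float:
        return self._by_taxon[taxon_id].fad

    def lad(self, taxon_id: str) -> float:
        return self._by_taxon[taxon_id].lad

    def fads(self) -> list[float]:
        return [r.fad for r in self._ranges]

    def srl(self) -> float:
        """Summed observed range length (Σ FAD − LAD), in Myr."""
        return sum(r.duration for r in self._ranges)

    def subset(self, taxa: Iterable[str]) -> "RangeTable":
        """Rows for ``taxa``, in this table's order."""
        keep = set(taxa)
        missing = keep - set(self._by_taxon)
        if missing:
            raise MissingTaxonError(sorted(missing))
        return RangeTable(r for r in self._ranges if r.taxon_id in keep)

    def replace_pairs(self, taxa: Sequence[str], pairs: Sequence[tuple[float, float]]) -> "RangeTable":
        """New table assigning the (fad, lad) ``pairs`` to ``taxa`` in order."""
        return RangeTable(
            TaxonRange(t, fad, lad) for t, (fad, lad) in zip(taxa, pairs, strict=True)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon": self.taxa, "fad": self.fads(), "lad": [r.lad for r in self._ranges]}
        )


# ---------------------------------------------------------------------------
# trees


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Normalized tip labels of ``tree`` in leaf-iteration order."""
    labels = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        if label is None:
            raise ValidationError("tree contains an unlabelled tip")
        labels.append(normalize_label(label))
    return labels


def _validate_tree(tree: dendropy.Tree, index: int) -> None:
    labels = tip_labels(tree)
    if len(labels) < 2:
        raise ValidationError(f"tree {index}: fewer than 2 tips")
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"tree {index}: duplicate tip label {lab!r}")
        seen.add(lab)


def read_trees(
    path: str | Path,
    format: str = "newick",
    preserve_underscores: bool = True,
) -> list[dendropy.Tree]:
    """Read all rooted trees from a Newick or NEXUS file, in file order.

    Parameters
    ----------
    path:
        Tree file.  NEXUS TREES blocks (with or without a translate table)
        and multi-tree Newick files are both supported.
    format:
        ``"newick"`` or ``"nexus"``.
    preserve_underscores:
        If True (default), unquoted underscores in labels are kept verbatim
        rather than converted to spaces.  Labels are normalized with
        :func:`normalize_label` either way, so the setting only matters for
        labels that genuinely contain spaces.

    Raises
    ------
    ValidationError
        Malformed file, no trees, or duplicate tip labels within a tree.
    FileNotFoundError
        Missing file.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema=fmt,
            preserve_underscores=preserve_underscores,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises a zoo of parse error types
        if isinstance(exc, (StratcongError, FileNotFoundError)):
            raise
        raise ValidationError(f"malformed {fmt} file {path}: {exc}") from exc
    result = list(trees)
    if not result:
        raise ValidationError(f"no trees found in {path}")
    for i, t in enumerate(result):
        _validate_tree(t, i)
    return result


def write_trees(trees: Sequence[dendropy.Tree], path: str | Path, format: str = "newick") -> None:
    """Write trees to ``path`` as Newick or NEXUS."""
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format {format!r}")
    tl = dendropy.TreeList(trees)
    tl.write(path=str(path), schema=fmt, unquoted_underscores=True, suppress_rooting=True)


# ---------------------------------------------------------------------------
# range tables


def read_ranges(path: str | Path) -> RangeTable:
    """Read a taxon age-range table from delimited text.

    The file must have header columns ``taxon``, ``fad``, ``lad``
    (case-insensitive; extra columns are ignored); the delimiter is
    auto-detected between comma and tab.  Ages are Ma before present.

    Raises :class:`ValidationError` for non-numeric ages, FAD < LAD
    (naming the taxon), or duplicate taxa.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
    df = pd.read_csv(path, sep=delimiter)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("taxon", "fad", "lad"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    ranges = []
    for row in df.itertuples(index=False):
        taxon = normalize_label(str(getattr(row, "taxon")))
        try:
            fad = float(getattr(row, "fad"))
            lad = float(getattr(row, "lad"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-numeric age for taxon {taxon!r}") from exc
        if math.isnan(fad) or math.isnan(lad):
            raise ValidationError(f"{path}: non-numeric age for taxon {taxon!r}")
        ranges.append(TaxonRange(taxon, fad, lad))
    return RangeTable(ranges)


def write_ranges(ranges: RangeTable, path: str | Path) -> None:
    """Write a range table as ``taxon,fad,lad`` CSV."""
    ranges.to_frame().to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# result tables

#: decimal precision used for floats in CSV output (significant digits)
CSV_FLOAT_DIGITS = 12


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "as_dict"):
                rows.append(rec.as_dict())
            elif isinstance(rec, Mapping):
                rows.append(dict(rec))
            else:
                raise TypeError(f"cannot tabulate record of type {type(rec).__name__}")
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no records to write")
    return df


def write_results(records, path: str | Path, format: str = "csv") -> None:
    """Write tabular results (mappings, dataclasses with ``as_dict``, or a
    DataFrame) to CSV or JSON.

    Values round-trip to at least 12 significant digits in both formats.
    """
    fmt = format.lower()
    if fmt not in ("csv", "json"):
        raise ValueError(f"unknown results format {format!r}")
    df = _records_to_frame(records)
    if fmt == "csv":
        df.to_csv(path, index=False, float_format=f"%.{CSV_FLOAT_DIGITS}g")
    else:
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1, default=str)
            fh.write("\n")


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    fmt = format.lower()
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown results format {format!r}")
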