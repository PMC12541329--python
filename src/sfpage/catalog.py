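"""Catalog assembly and gene-age bookkeeping.

A seminal-fluid-protein (Sfp) catalog is the union of two independently
derived candidate gene lists; each member carries source flags, a
phylostratigraphic age class (A = oldest stratum, predating the
*Drosophila* radiation, through E = youngest), an optional reproductive
GO flag and an optional paralog-group label.  This module reads the
tabular inputs, assembles the catalog, attaches ages, cross-validates
them against independent deep-ortholog calls, and can collapse paralog
groups to single representatives.

Gene identifiers are opaque strings matched exactly and
case-sensitively.  All tables are tab-separated UTF-8 with a mandatory
header row; lines starting with ``#`` are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered age classes, oldest first.
AGE_CLASSES: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: Sentinel for genes without an age call (e.g. pseudogenes).
UNASSIGNED = "unassigned"

#: Age classes treated as "old" when validating against deep ortholog calls.
OLD_CLASSES: frozenset[str] = frozenset({"A", "B", "C"})

__all__ = [
    "AGE_CLASSES",
    "UNASSIGNED",
    "OLD_CLASSES",
    "GeneRecord",
    "Catalog",
    "ValidationReport",
    "read_gene_table",
    "write_gene_table",
    "read_mapping",
    "assemble_catalog",
    "assign_ages",
    "cross_validate_ages",
    "collapse_paralogs",
]


@dataclass(frozen=True)
class GeneRecord:
    """One cataloged gene with its source flags and annotations."""

    gene_id: str
    symbol: str | None = None
    in_list_a: bool = False
    in_list_b: bool = False
    age_class: str = UNASSIGNED
    reproductive_flag: bool | None = None
    paralog_group: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be a non-empty string")
        if not (self.in_list_a or self.in_list_b):
            raise ValueError(f"{self.gene_id}: catalog member must come from at least one source list")
        if self.age_class != UNASSIGNED and self.age_class not in AGE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown age class {self.age_class!r}")


@dataclass(frozen=True)
class Catalog:
    """An immutable collection of :class:`GeneRecord` with unique ids."""

    records: tuple[GeneRecord, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in catalog: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> GeneRecord:
        return self._index()[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index()

    def _index(self) -> dict[str, GeneRecord]:
        # rebuilt lazily; records tuple is immutable
        if not hasattr(self, "_idx"):
            object.__setattr__(self, "_idx", {r.gene_id: r for r in self.records})
        return self._idx  # type: ignore[attr-defined]

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.gene_id for r in self.records)

    @property
    def conservative_ids(self) -> frozenset[str]:
        """Genes present in both source lists (the intersection set)."""
        return frozenset(r.gene_id for r in self.records if r.in_list_a and r.in_list_b)

    @property
    def assigned_ids(self) -> frozenset[str]:
        return frozenset(r.gene_id for r in self.records if r.age_class != UNASSIGNED)

    @property
    def unassigned_ids(self) -> frozenset[str]:
        return frozenset(r.gene_id for r in self.records if r.age_class == UNASSIGNED)

    def age_of(self, gene_id: str) -> str:
        return self.get(gene_id).age_class

    def class_counts(self, subset: Iterable[str] | None = None) -> dict[str, int]:
        """Counts per age class A..E over assigned genes (optionally a subset)."""
        wanted = set(subset) if subset is not None else None
        counts = {c: 0 for c in AGE_CLASSES}
        for r in self.records:
            if r.age_class == UNASSIGNED:
                continue
            if wanted is not None and r.gene_id not in wanted:
                continue
            counts[r.age_class] += 1
        return counts

    def subset(self, gene_ids: Iterable[str]) -> "Catalog":
        wanted = set(gene_ids)
        return Catalog(
            tuple(r for r in self.records if r.gene_id in wanted),
            dict(self.provenance, subset_size=len(wanted)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "symbol": [r.symbol for r in self.records],
                "in_list_a": [r.in_list_a for r in self.records],
                "in_list_b": [r.in_list_b for r in self.records],
                "age_class": [r.age_class for r in self.records],
                "reproductive_flag": [r.reproductive_flag for r in self.records],
                "paralog_group": [r.paralog_group for r in self.records],
            }
        )


@dataclass(frozen=True)
class ValidationReport:
    """Cross-validation of age calls against independent deep-ortholog ids."""

    n_checked: int
    n_discrepant: int
    discrepant_ids: tuple[str, ...]
    skipped_ids: tuple[str, ...] = ()

    @property
    def rate_percent(self) -> float:
        if self.n_checked == 0:
            return 0.0
        return 100.0 * self.n_discrepant / self.n_checked

    def to_dict(self) -> dict:
        return {
            "n_checked": self.n_checked,
            "n_discrepant": self.n_discrepant,
            "discrepant_ids": list(self.discrepant_ids),
            "skipped_ids": list(self.skipped_ids),
            "rate_percent": self.rate_percent,
        }


# ---------------------------------------------------------------------------
# table IO


def read_gene_table(
    path: str | Path,
    id_column: str = "gene_id",
    on_duplicate: str = "error",
) -> pd.DataFrame:
    """Read a TSV gene table; enforce presence and uniqueness of the id column.

    ``on_duplicate`` is ``'error'`` (strict, default) or ``'first'``
    (keep the first occurrence of each id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r} (has {list(df.columns)})")
    dupes = df[id_column][df[id_column].duplicated()].unique()
    if len(dupes) > 0:
        if on_duplicate == "error":
            raise ValueError(f"{path}: duplicated gene ids: {sorted(dupes)[:5]}")
        if on_duplicate == "first":
            df = df.drop_duplicates(subset=id_column, keep="first")
        else:
            raise ValueError(f"unknown on_duplicate policy {on_duplicate!r}")
    return df.reset_index(drop=True)


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the package's TSV dialect (round-trips with the reader)."""
    pd.DataFrame(df).to_csv(path, sep="\t", index=False)


def read_mapping(
    path: str | Path,
    key_column: str,
    value_column: str,
) -> dict[str, str]:
    """Read a two-column TSV into a dict (e.g. gene -> age class / group)."""
    df = read_gene_table(path, id_column=key_column)
    if value_column not in df.columns:
        raise ValueError(f"{path}: missing column {value_column!r}")
    return dict(zip(df[key_column], df[value_column]))


# ---------------------------------------------------------------------------
# catalog operations


def assemble_catalog(
    list_a: Iterable[str],
    list_b: Iterable[str],
    symbols: Mapping[str, str] | None = None,
    provenance: Mapping[str, object] | None = None,
) -> Catalog:
    """Union two candidate id lists into a catalog with per-gene source flags.

    The intersection is retrievable as :attr:`Catalog.conservative_ids`.
    """
    set_a, set_b = set(list_a), set(list_b)
    if not set_a or not set_b:
        raise ValueError("both candidate lists must be non-empty")
    symbols = symbols or {}
    records = tuple(
        GeneRecord(
            gene_id=g,
            symbol=symbols.get(g),
            in_list_a=g in set_a,
            in_list_b=g in set_b,
        )
        for g in sorted(set_a | set_b)
    )
    prov = dict(provenance or {})
    prov.update(n_list_a=len(set_a), n_list_b=len(set_b), n_union=len(records),
                n_intersection=len(set_a & set_b))
    return Catalog(records, prov)


def assign_ages(
    catalog: Catalog,
    age_table: Mapping[str, str],
    exceptions: Iterable[str] = (),
) -> Catalog:
    """Attach age classes from a gene -> class mapping.

    Genes listed in ``exceptions`` (e.g. known pseudogenes) stay
    unassigned silently; any other gene missing from the table is left
    unassigned with a warning.  Unassigned genes are excluded from all
    age-stratified statistics downstream.
    """
    bad = sorted(set(age_table.values()) - set(AGE_CLASSES))
    if bad:
        raise ValueError(f"age table contains unknown classes: {bad}")
    exceptions = set(exceptions)
    missing: list[str] = []
    out = []
    for rec in catalog:
        if rec.gene_id in age_table:
            out.append(replace(rec, age_class=age_table[rec.gene_id]))
        else:
            out.append(replace(rec, age_class=UNASSIGNED))
            if rec.gene_id not in exceptions:
                missing.append(rec.gene_id)
    if missing:
        logger.warning("%d catalog genes missing from age table: %s%s",
                       len(missing), missing[:5], "..." if len(missing) > 5 else "")
    prov = dict(catalog.provenance, n_age_missing=len(missing),
                age_missing_ids=sorted(missing), n_exceptions=len(exceptions))
    return Catalog(tuple(out), prov)


def cross_validate_ages(
    catalog: Catalog,
    ortholog_ids: Iterable[str],
    old_classes: frozenset[str] | set[str] = OLD_CLASSES,
) -> ValidationReport:
    """Check age calls against genes with independent deep-ortholog support.

    Each id in ``ortholog_ids`` has a 1-to-1 ortholog in a lineage that
    diverged before the young strata, so its assigned class should be one
    of ``old_classes`` (default {A, B, C}).  A discrepancy is a checked
    gene assigned to a younger class.  Ids absent from the catalog or
    without an age call are excluded and reported, not counted.
    """
    ortho = set(ortholog_ids)
    checkable = sorted(ortho & catalog.assigned_ids)
    skipped = tuple(sorted(ortho - set(checkable)))
    if not checkable:
        raise ValueError("no ortholog-supported ids overlap the aged catalog")
    discrepant = tuple(g for g in checkable if catalog.age_of(g) not in old_classes)
    return ValidationReport(
        n_checked=len(checkable),
        n_discrepant=len(discrepant),
        discrepant_ids=discrepant,
        skipped_ids=skipped,
    )


def _completeness(rec: GeneRecord) -> int:
    return sum(
        [
            rec.symbol is not None,
            rec.age_class != UNASSIGNED,
            rec.reproductive_flag is not None,
        ]
    )


def collapse_paralogs(
    catalog: Catalog,
    groups: Mapping[str, str],
    strategy: str = "most_annotated",
) -> Catalog:
    """Collapse each paralog group to a single representative record.

    The mapping may be partial; ungrouped genes are singletons and pass
    through unchanged.  The representative is the member with the most
    non-missing annotations, ties broken lexicographically by gene id
    (deterministic).  If group members disagree on age class the oldest
    class is kept, with a warning, so the deduplicated set never looks
    younger than the full one.  The operation is idempotent.
    """
    if strategy != "most_annotated":
        raise ValueError(f"unknown collapse strategy {strategy!r}")
    by_group: dict[str, list[GeneRecord]] = {}
    singles: list[GeneRecord] = []
    for rec in catalog:
        grp = groups.get(rec.gene_id)
        if grp is None:
            singles.append(replace(rec, paralog_group=None) if rec.paralog_group else rec)
        else:
            by_group.setdefault(str(grp), []).append(replace(rec, paralog_group=str(grp)))
    collapsed: list[GeneRecord] = []
    for grp in sorted(by_group):
        members = by_group[grp]
        rep = min(members, key=lambda r: (-_completeness(r), r.gene_id))
        ages = {m.age_class for m in members if m.age_class != UNASSIGNED}
        if len(ages) > 1:
            oldest = min(ages, key=AGE_CLASSES.index)
            logger.warning("paralog group %s has conflicting age classes %s; keeping %s",
                           grp, sorted(ages), oldest)
            rep = replace(rep, age_class=oldest)
        collapsed.append(rep)
    records = tuple(sorted(singles + collapsed, key=lambda r: r.gene_id))
    prov = dict(catalog.provenance, n_collapsed_from=len(catalog),
                n_paralog_groups=len(by_group))
    return Catalog(records, prov)
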