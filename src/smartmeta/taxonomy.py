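"""Three-level taxonomy (species -> genus -> class) for vote aggregation.

The classifier resolves every reference record to a single lineage at three
ranks.  Genus and class votes are always derived from species votes through
this table, and the host-override rule ("any mammalian match makes the read
mammalian") is driven by the class label: a lineage is mammalian iff its
class equals the configured mammalian class label (``"Mammalia"`` by
default).

The on-disk format is a flat TSV, one row per reference record::

    record_id <TAB> species <TAB> genus <TAB> class

``#``-prefixed lines and blank lines are ignored.  The table enforces that a
species always maps to exactly one (genus, class) pair.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import (
    TaxonomyConsistencyError,
    TaxonomyLookupError,
    TaxonomyParseError,
)

DEFAULT_MAMMALIAN_CLASS = "Mammalia"

__all__ = [
    "DEFAULT_MAMMALIAN_CLASS",
    "TaxonAssignment",
    "TaxonomyTable",
    "load_taxonomy",
    "lineage_of",
]


@dataclass(frozen=True)
class TaxonAssignment:
    """Lineage of one reference record at species, genus and class rank."""

    species_id: str
    genus_id: str
    class_id: str
    is_mammalian: bool

    def __post_init__(self) -> None:
        for field in ("species_id", "genus_id", "class_id"):
            if not getattr(self, field):
                raise TaxonomyConsistencyError(
                    f"TaxonAssignment.{field} must be non-empty"
                )

    @classmethod
    def from_lineage(
        cls,
        species_id: str,
        genus_id: str,
        class_id: str,
        mammalian_class: str = DEFAULT_MAMMALIAN_CLASS,
    ) -> "TaxonAssignment":
        """Build an assignment, deriving the mammalian flag from the class."""
        return cls(species_id, genus_id, class_id, class_id == mammalian_class)

    def label_at(self, level: str) -> str:
        """Taxon label at ``level`` in {"species", "genus", "class"}."""
        return {
            "species": self.species_id,
            "genus": self.genus_id,
            "class": self.class_id,
        }[level]


class TaxonomyTable:
    """Mapping from reference-record id to :class:`TaxonAssignment`.

    Construction validates the single-lineage invariant: all entries that
    share a species_id must share genus_id and class_id.
    """

    def __init__(self, entries: Mapping[str, TaxonAssignment]):
        self._entries: dict[str, TaxonAssignment] = dict(entries)
        self._validate()

    def _validate(self) -> None:
        lineage_by_species: dict[str, tuple[str, str]] = {}
        for record_id, asn in self._entries.items():
            key = (asn.genus_id, asn.class_id)
            seen = lineage_by_species.setdefault(asn.species_id, key)
            if seen != key:
                raise TaxonomyConsistencyError(
                    f"species {asn.species_id!r} maps to conflicting lineages "
                    f"{seen} and {key} (record {record_id!r})"
                )

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, record_id: object) -> bool:
        return record_id in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TaxonomyTable) and other._entries == self._entries
        )

    def lineage_of(self, record_id: str) -> TaxonAssignment:
        """Lineage of one reference record; raises on unknown ids."""
        try:
            return self._entries[record_id]
        except KeyError:
            raise TaxonomyLookupError(
                f"record id {record_id!r} not present in taxonomy table"
            ) from None

    def species_lineage(self, species_id: str) -> TaxonAssignment:
        """Lineage of a species label (unique by the lineage invariant)."""
        for asn in self._entries.values():
            if asn.species_id == species_id:
                return asn
        raise TaxonomyLookupError(
            f"species {species_id!r} not present in taxonomy table"
        )

    @property
    def entries(self) -> Mapping[str, TaxonAssignment]:
        return dict(self._entries)

    def record_ids(self) -> list[str]:
        return sorted(self._entries)

    def species_index(self) -> dict[str, TaxonAssignment]:
        """species_id -> lineage, across all entries."""
        return {a.species_id: a for a in self._entries.values()}

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        """Canonical TSV text (rows sorted by record id)."""
        buf = io.StringIO()
        buf.write("#record_id\tspecies\tgenus\tclass\n")
        for record_id in sorted(self._entries):
            a = self._entries[record_id]
            buf.write(
                f"{record_id}\t{a.species_id}\t{a.genus_id}\t{a.class_id}\n"
            )
        return buf.getvalue()

    def digest(self) -> str:
        """sha256 of the canonical TSV; used by index manifests."""
        return hashlib.sha256(self.to_tsv().encode()).hexdigest()


def _parse_rows(
    lines: Iterable[str], mammalian_class: str
) -> dict[str, TaxonAssignment]:
    entries: dict[str, TaxonAssignment] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4 or any(not p.strip() for p in parts):
            raise TaxonomyParseError(
                f"line {lineno}: expected 4 non-empty tab-separated fields, "
                f"got {line!r}"
            )
        record_id, species, genus, klass = (p.strip() for p in parts)
        asn = TaxonAssignment.from_lineage(
            species, genus, klass, mammalian_class
        )
        if record_id in entries and entries[record_id] != asn:
            raise TaxonomyConsistencyError(
                f"record id {record_id!r} appears twice with conflicting "
                f"lineages"
            )
        entries[record_id] = asn
    return entries


def load_taxonomy(
    path: str | Path, mammalian_class: str = DEFAULT_MAMMALIAN_CLASS
) -> TaxonomyTable:
    """Load and validate a taxonomy TSV.

    Parameters
    ----------
    path : path to the TSV (``record_id  species  genus  class``).
    mammalian_class : class label that triggers the host-override rule.
    """
    with open(path, "r", encoding="utf-8") as fh:
        entries = _parse_rows(fh, mammalian_class)
    return TaxonomyTable(entries)


def lineage_of(table: TaxonomyTable, record_id: str) -> TaxonAssignment:
    """Functional alias for :meth:`TaxonomyTable.lineage_of`."""
    return table.lineage_of(record_id)
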