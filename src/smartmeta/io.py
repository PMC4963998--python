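"""Readers and writers for the pipeline's file formats.

Sequences come in as FASTA or FASTQ (auto-detected, via Biopython); FASTQ
qualities are ignored because quality trimming is expected to happen
upstream.  Intermediate and final results are plain TSV/JSON so every stage
can be inspected and diffed.

Match TSV format (``smart search`` output)::

    read_id  offset  strand  permuted  species_list  windows_scanned

One row per match event, species comma-joined; a read with zero matches is
still recorded, as a sentinel row with offset ``-1``, strand ``.``, empty
species list.  This keeps the file self-contained: sample reports (which
need unmatched counts) can be rebuilt from it alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from Bio import SeqIO

from .errors import SearchInputError

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ReadClassification
    from .search import ReadMatchSet

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_matches_tsv",
    "read_matches_tsv",
    "write_per_read_tsv",
    "read_per_read_tsv",
    "write_json",
]


def detect_format(path: str | Path) -> str:
    """"fasta" or "fastq", decided by the first non-blank byte."""
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise SearchInputError(
                    f"{path}: cannot detect FASTA/FASTQ (first record "
                    f"starts with {first!r})"
                )
    raise SearchInputError(f"{path}: empty sequence file")


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(record_id, sequence)`` from a FASTA or FASTQ file."""
    fmt = detect_format(path)
    for record in SeqIO.parse(str(path), fmt):
        yield record.id, str(record.seq)


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# match TSV
# ---------------------------------------------------------------------------

_MATCH_HEADER = "#read_id\toffset\tstrand\tpermuted\tspecies_list\twindows_scanned"


def write_matches_tsv(
    match_sets: dict[str, "ReadMatchSet"], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_MATCH_HEADER + "\n")
        for read_id, ms in match_sets.items():
            if not ms.matches:
                fh.write(
                    f"{read_id}\t-1\t.\t0\t\t{ms.windows_scanned}\n"
                )
                continue
            for m in ms.matches:
                fh.write(
                    "\t".join(
                        (
                            read_id,
                            str(m.offset),
                            m.strand,
                            "1" if m.permuted else "0",
                            ",".join(sorted(m.species_ids)),
                            str(ms.windows_scanned),
                        )
                    )
                    + "\n"
                )


def read_matches_tsv(path: str | Path) -> dict[str, "ReadMatchSet"]:
    from .search import ReadMatchSet, WindowMatch

    out: dict[str, ReadMatchSet] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, offset, strand, permuted, species, scanned = line.split(
                "\t"
            )
            ms = out.setdefault(
                read_id, ReadMatchSet(read_id, [], int(scanned))
            )
            if offset == "-1" and not species:
                continue  # sentinel row for a matchless read
            ms.matches.append(
                WindowMatch(
                    read_id=read_id,
                    offset=int(offset),
                    strand=strand,
                    permuted=permuted == "1",
                    species_ids=frozenset(species.split(",")),
                )
            )
    return out


# ---------------------------------------------------------------------------
# per-read classification TSV
# ---------------------------------------------------------------------------

_PER_READ_HEADER = (
    "#read_id\tspecies_verdict\tgenus_verdict\tclass_verdict\tcategory"
    "\tn_votes_species\tmammalian_override"
)


def write_per_read_tsv(
    classifications: Iterable["ReadClassification"], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_PER_READ_HEADER + "\n")
        for rc in classifications:
            fh.write(
                "\t".join(
                    (
                        rc.read_id,
                        rc.verdict_per_level["species"],
                        rc.verdict_per_level["genus"],
                        rc.verdict_per_level["class"],
                        rc.category,
                        str(sum(rc.tally.species.values())),
                        "1" if rc.mammalian_override else "0",
                    )
                )
                + "\n"
            )


def read_per_read_tsv(path: str | Path) -> list[dict]:
    """Parse a per-read TSV back into plain dicts (for evaluation)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, sp, ge, kl, cat, nv, over = line.split("\t")
            rows.append(
                {
                    "read_id": read_id,
                    "species": sp,
                    "genus": ge,
                    "class": kl,
                    "category": cat,
                    "n_votes_species": int(nv),
                    "mammalian_override": over == "1",
                }
            )
    return rows


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
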