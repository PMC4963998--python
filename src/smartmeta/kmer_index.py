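"""Prefix-sharded exact-match 30-mer database.

Reference genomes are tiled into NON-overlapping 30-mers (step = k), each
linked to the species of its source record.  The database is partitioned
into 4^prefix_len shards (256 at the defaults) keyed by the first
``prefix_len`` bases of each k-mer; within a shard the remaining
``k - prefix_len`` bases (26 at defaults) index a hashtable whose value is
the sorted set of species containing the full k-mer.  Every k-mer therefore
lives in exactly one deterministically addressable shard, which is what lets
search run as 256 independent programs and lets a single shard be loaded
without the other 255.

Only the forward strand of the references is stored; reverse complements are
handled at query time by the search layer.

The 2-bit base encoding is fixed: A=0, C=1, G=2, T=3, first base most
significant, so lexicographic order of k-mer strings equals numeric order of
their codes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EncodingError,
    IndexBuildError,
    IndexCompatibilityError,
    IndexIOError,
    QueryError,
)
from .taxonomy import DEFAULT_MAMMALIAN_CLASS, TaxonomyTable

__all__ = [
    "IndexParams",
    "KmerRecord",
    "Shard",
    "ShardedIndex",
    "encode_prefix",
    "decode_prefix",
    "tile_reference",
    "build_index",
    "lookup",
    "save_index",
    "load_index",
    "load_shard",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

# 256-entry lookup table: byte value of A/C/G/T -> 0..3, anything else 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_CODE.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

MANIFEST_NAME = "manifest.json"
TAXONOMY_NAME = "taxonomy.tsv"
FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexParams:
    """Database geometry.

    k : full window length in bases (30).
    prefix_len : shard-key length in bases (4 -> 256 shards).
    mammalian_class : class label used for the host-override rule.
    """

    k: int = 30
    prefix_len: int = 4
    mammalian_class: str = DEFAULT_MAMMALIAN_CLASS

    def __post_init__(self) -> None:
        if not (0 < self.prefix_len < self.k):
            raise ValueError(
                f"require 0 < prefix_len < k, got prefix_len={self.prefix_len} "
                f"k={self.k}"
            )
        if self.k > 32:
            raise ValueError("k > 32 does not fit a 64-bit 2-bit encoding")

    @property
    def shard_count(self) -> int:
        return 4**self.prefix_len

    @property
    def suffix_len(self) -> int:
        return self.k - self.prefix_len


@dataclass(frozen=True)
class KmerRecord:
    """One tiled k-mer and the species whose reference produced it."""

    kmer: str
    species_id: str


def encode_prefix(prefix: str, prefix_len: int = 4) -> int:
    """Shard address of a prefix string; bijective onto [0, 4^prefix_len).

    A=0, C=1, G=2, T=3, first base most significant ("ACGT" -> 27).
    """
    if len(prefix) != prefix_len:
        raise EncodingError(
            f"prefix {prefix!r} has length {len(prefix)}, expected {prefix_len}"
        )
    code = 0
    for base in prefix:
        try:
            code = code * 4 + _BASE_CODE[base]
        except KeyError:
            raise EncodingError(
                f"non-ACGT character {base!r} in prefix {prefix!r}"
            ) from None
    return code


def decode_prefix(index: int, prefix_len: int = 4) -> str:
    """Inverse of :func:`encode_prefix`."""
    if not 0 <= index < 4**prefix_len:
        raise EncodingError(f"shard index {index} out of range")
    out = []
    for shift in range(prefix_len - 1, -1, -1):
        out.append(_BASES[(index >> (2 * shift)) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    """2-bit pack a k-mer string (k <= 32) into an integer."""
    code = 0
    for base in kmer:
        try:
            code = (code << 2) | _BASE_CODE[base]
        except KeyError:
            raise EncodingError(f"non-ACGT character {base!r} in k-mer") from None
    return code


def sequence_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes of a sequence; non-ACGT bases become 255.

    Case-insensitive (soft-masked lowercase is accepted).
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _LUT[raw]


def tile_reference(
    sequence: str, params: IndexParams = IndexParams()
) -> list[tuple[int, str]]:
    """Non-overlapping tiling of a reference sequence.

    Returns ``(offset, kmer)`` pairs at offsets 0, k, 2k, ... (0-based,
    forward strand only).  The trailing remainder shorter than k is
    discarded, and any tile containing a non-ACGT character after
    uppercasing is skipped.
    """
    k = params.k
    seq = sequence.upper()
    tiles: list[tuple[int, str]] = []
    for off in range(0, len(seq) - k + 1, k):
        tile = seq[off : off + k]
        if all(b in _BASE_CODE for b in tile):
            tiles.append((off, tile))
    return tiles


class Shard:
    """One prefix's hashtable: 26-base suffix -> sorted species tuple."""

    __slots__ = ("prefix", "table", "_suffix_codes", "_species_rows")

    def __init__(self, prefix: str, table: Mapping[str, Sequence[str]]):
        self.prefix = prefix
        self.table: dict[str, tuple[str, ...]] = {
            suffix: tuple(sorted(set(species)))
            for suffix, species in table.items()
        }
        self._suffix_codes: np.ndarray | None = None
        self._species_rows: list[tuple[str, ...]] | None = None

    def __len__(self) -> int:
        return len(self.table)

    def lookup_suffix(self, suffix: str) -> frozenset[str]:
        return frozenset(self.table.get(suffix, ()))

    def encoded(self) -> tuple[np.ndarray, list[tuple[str, ...]]]:
        """Sorted suffix codes + aligned species rows (built lazily).

        Lexicographic suffix order equals numeric order, so sorting the
        string keys and encoding them yields a sorted uint64 array suitable
        for vectorized binary search.
        """
        if self._suffix_codes is None:
            suffixes = sorted(self.table)
            self._suffix_codes = np.array(
                [encode_kmer(s) for s in suffixes], dtype=np.uint64
            )
            self._species_rows = [self.table[s] for s in suffixes]
        assert self._species_rows is not None
        return self._suffix_codes, self._species_rows

    def to_text(self) -> str:
        """Canonical serialization: one sorted suffix per line, species
        tab-separated after it."""
        lines = []
        for suffix in sorted(self.table):
            lines.append("\t".join((suffix, *self.table[suffix])))
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_text(cls, prefix: str, text: str) -> "Shard":
        table: dict[str, tuple[str, ...]] = {}
        for line in text.splitlines():
            if not line:
                continue
            suffix, *species = line.split("\t")
            table[suffix] = tuple(species)
        return cls(prefix, table)


class ShardedIndex:
    """The full database: 4^prefix_len shards plus the taxonomy."""

    def __init__(
        self,
        params: IndexParams,
        shards: Sequence[Shard],
        taxonomy: TaxonomyTable,
    ):
        if len(shards) != params.shard_count:
            raise IndexBuildError(
                f"expected {params.shard_count} shards, got {len(shards)}"
            )
        self.params = params
        self.shards = list(shards)
        self.taxonomy = taxonomy

    def shard_for(self, kmer_or_prefix: str) -> Shard:
        prefix = kmer_or_prefix[: self.params.prefix_len]
        return self.shards[encode_prefix(prefix, self.params.prefix_len)]

    def lookup(self, kmer: str) -> frozenset[str]:
        """Species set stored under an exact k-mer (empty set if absent)."""
        return lookup(self, kmer)

    def n_kmers(self) -> int:
        """Number of distinct stored k-mers."""
        return sum(len(s) for s in self.shards)

    def n_entries(self) -> int:
        """Number of stored (k-mer, species) pairs."""
        return sum(
            len(species) for s in self.shards for species in s.table.values()
        )

    def iter_kmers(self) -> Iterable[tuple[str, tuple[str, ...]]]:
        for shard in self.shards:
            for suffix in sorted(shard.table):
                yield shard.prefix + suffix, shard.table[suffix]


def lookup(index: ShardedIndex, kmer: str) -> frozenset[str]:
    """Exact-match query: species whose references contain ``kmer``.

    Raises :class:`QueryError` on wrong length or non-ACGT characters.
    """
    params = index.params
    if len(kmer) != params.k:
        raise QueryError(
            f"query length {len(kmer)} != k={params.k}"
        )
    if any(b not in _BASE_CODE for b in kmer):
        raise QueryError(f"non-ACGT character in query {kmer!r}")
    shard = index.shard_for(kmer)
    return shard.lookup_suffix(kmer[params.prefix_len :])


def _iter_references(
    references: str | Path | Iterable[tuple[str, str]],
) -> Iterable[tuple[str, str]]:
    if isinstance(references, (str, Path)):
        from .io import read_sequences

        yield from read_sequences(references)
    else:
        yield from references


def build_index(
    references: str | Path | Iterable[tuple[str, str]],
    taxonomy: TaxonomyTable,
    params: IndexParams = IndexParams(),
) -> ShardedIndex:
    """Tile references and route every (k-mer, species) pair to its shard.

    ``references`` is a FASTA path or an iterable of ``(record_id, sequence)``
    pairs.  Every record id must be present in the taxonomy.  Species sets
    are deduplicated and sorted, so the result (and its serialization) is
    independent of the input record order.
    """
    tables: list[dict[str, set[str]]] = [
        {} for _ in range(params.shard_count)
    ]
    n_records = 0
    n_pairs = 0
    for record_id, sequence in _iter_references(references):
        n_records += 1
        if record_id not in taxonomy:
            raise IndexBuildError(
                f"reference record {record_id!r} is absent from the taxonomy"
            )
        species = taxonomy.lineage_of(record_id).species_id
        for _, kmer in tile_reference(sequence, params):
            sid = encode_prefix(kmer[: params.prefix_len], params.prefix_len)
            tables[sid].setdefault(kmer[params.prefix_len :], set()).add(
                species
            )
            n_pairs += 1
    if n_records == 0:
        raise IndexBuildError("no reference records to index")
    if n_pairs == 0:
        raise IndexBuildError(
            "references contain no indexable k-length ACGT tiles"
        )
    shards = [
        Shard(decode_prefix(i, params.prefix_len), tables[i])
        for i in range(params.shard_count)
    ]
    return ShardedIndex(params, shards, taxonomy)


# ---------------------------------------------------------------------------
# serialization: manifest.json + taxonomy.tsv + one file per shard
# ---------------------------------------------------------------------------


def _shard_filename(prefix: str) -> str:
    return f"shard_{prefix}"


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def save_index(index: ShardedIndex, directory: str | Path) -> dict:
    """Write the index as a manifest plus one independent file per shard.

    The serialization is canonical (sorted suffixes, sorted species), so two
    indexes built from the same references in any order produce byte-identical
    directories.  Returns the manifest dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shard_meta: dict[str, dict] = {}
    for shard in index.shards:
        text = shard.to_text()
        (directory / _shard_filename(shard.prefix)).write_text(text)
        shard_meta[shard.prefix] = {
            "entries": len(shard),
            "sha256": _sha256_text(text),
        }
    tax_text = index.taxonomy.to_tsv()
    (directory / TAXONOMY_NAME).write_text(tax_text)
    manifest = {
        "format_version": FORMAT_VERSION,
        "k": index.params.k,
        "prefix_len": index.params.prefix_len,
        "mammalian_class": index.params.mammalian_class,
        "taxonomy_sha256": _sha256_text(tax_text),
        "shards": shard_meta,
    }
    (directory / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def _read_manifest(directory: Path) -> dict:
    path = directory / MANIFEST_NAME
    if not path.is_file():
        raise IndexIOError(f"no manifest at {path}")
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise IndexIOError(f"malformed manifest {path}: {exc}") from exc
    return manifest


def _check_params(manifest: dict, expected: IndexParams | None) -> IndexParams:
    params = IndexParams(
        k=manifest["k"],
        prefix_len=manifest["prefix_len"],
        mammalian_class=manifest["mammalian_class"],
    )
    if expected is not None and expected != params:
        raise IndexCompatibilityError(
            f"index was built with {params}, requested {expected}"
        )
    return params


def _load_shard_file(directory: Path, prefix: str, meta: dict) -> Shard:
    path = directory / _shard_filename(prefix)
    if not path.is_file():
        raise IndexIOError(f"missing shard file for prefix {prefix!r}")
    text = path.read_text()
    if _sha256_text(text) != meta["sha256"]:
        raise IndexIOError(f"checksum mismatch for shard {prefix!r}")
    return Shard.from_text(prefix, text)


def load_index(
    directory: str | Path, params: IndexParams | None = None
) -> ShardedIndex:
    """Load a saved index, verifying per-shard checksums.

    ``params`` is an optional compatibility assertion: loading fails if the
    manifest's parameters differ.
    """
    from .taxonomy import load_taxonomy

    directory = Path(directory)
    manifest = _read_manifest(directory)
    got = _check_params(manifest, params)
    taxonomy = load_taxonomy(
        directory / TAXONOMY_NAME, mammalian_class=got.mammalian_class
    )
    shards = []
    for i in range(got.shard_count):
        prefix = decode_prefix(i, got.prefix_len)
        meta = manifest["shards"].get(prefix)
        if meta is None:
            raise IndexIOError(f"manifest lacks shard {prefix!r}")
        shards.append(_load_shard_file(directory, prefix, meta))
    return ShardedIndex(got, shards, taxonomy)


def load_shard(
    directory: str | Path, prefix: str, params: IndexParams | None = None
) -> Shard:
    """Load a single shard without touching the other files.

    Supports memory-bounded search: one worker needs only its own shard.
    """
    directory = Path(directory)
    manifest = _read_manifest(directory)
    got = _check_params(manifest, params)
    encode_prefix(prefix, got.prefix_len)  # validates the prefix string
    meta = manifest["shards"].get(prefix)
    if meta is None:
        raise IndexIOError(f"manifest lacks shard {prefix!r}")
    return _load_shard_file(directory, prefix, meta)
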