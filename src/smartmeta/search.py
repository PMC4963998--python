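"""Sliding-window search of reads against the sharded k-mer database.

Every read is scanned on both strands (the read as given and its reverse
complement, each left-to-right with its own 0-based offsets) with a step-1
window of k bases.  A window containing any non-ACGT base is skipped.  In
``exact`` mode a window matches when its k-mer is literally stored in the
database; in ``permuted`` mode every one of the 3k single-base substitution
variants (90 at k=30) is additionally queried, which tolerates one SNP or
sequencing error per window but no indels.

The map step assigns each shard its own search program: a shard answers all
queries — exact windows or substitution variants — whose (possibly mutated)
first ``prefix_len`` bases equal its prefix.  Routing variants to the shard
that owns the *mutated* prefix keeps the sharded search exactly equivalent
to a global 1-edit search; fixing the prefix instead would silently drop the
variants whose substitution falls in the first four bases.  The reduce step
merges per-shard match lists into per-read match sets, deduplicating per
(window, strand, species) with exact evidence taking precedence over
permuted evidence.

Two execution paths produce identical results: :func:`search_shard` is the
literal one-shard program, and :func:`search_reads` runs the whole map-reduce
with numpy-vectorized lookups (windows are 2-bit packed into uint64, variants
generated by XOR, shards answered via binary search over their sorted keys).
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EncodingError,
    IndexCompatibilityError,
    QueryError,
    SearchInputError,
)
from .kmer_index import (
    IndexParams,
    Shard,
    ShardedIndex,
    encode_prefix,
    sequence_codes,
)

__all__ = [
    "SearchConfig",
    "WindowMatch",
    "ReadMatchSet",
    "reverse_complement",
    "sliding_windows",
    "permute_1bp",
    "search_shard",
    "reduce_matches",
    "search_reads",
]

FORWARD = "forward"
REVERSE = "reverse"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGTN = frozenset("ACGTN")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SearchConfig:
    """Search options.

    mode : "exact" or "permuted" (permuted additionally queries all
        Hamming-1 substitution variants of every window).
    workers : number of concurrently processed shard groups; results are
        invariant to this by contract.
    params : must equal the index's :class:`IndexParams`.
    """

    mode: str = "exact"
    workers: int = 1
    params: IndexParams = field(default_factory=IndexParams)

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "permuted"):
            raise SearchInputError(
                f"mode must be 'exact' or 'permuted', got {self.mode!r}"
            )
        if self.workers < 1:
            raise SearchInputError("workers must be a positive integer")


@dataclass(frozen=True)
class WindowMatch:
    """One successful lookup event.

    ``offset`` is the 0-based window start on the scanned strand (the read
    as given for ``forward``, its reverse complement for ``reverse``).
    ``permuted`` is False when the exact window k-mer is in the database and
    True when only a Hamming-1 variant is.
    """

    read_id: str
    offset: int
    strand: str
    permuted: bool
    species_ids: frozenset[str]


@dataclass
class ReadMatchSet:
    """All of one read's match events, merged across shards."""

    read_id: str
    matches: list[WindowMatch]
    windows_scanned: int = 0

    def species_events(self) -> set[tuple[int, str, str]]:
        """Deduplicated (offset, strand, species) vote events."""
        return {
            (m.offset, m.strand, sp)
            for m in self.matches
            for sp in m.species_ids
        }

    def matched_species(self) -> set[str]:
        return {sp for m in self.matches for sp in m.species_ids}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N; involution."""
    seq = seq.upper()
    bad = set(seq) - _ACGTN
    if bad:
        raise EncodingError(
            f"cannot reverse-complement characters {sorted(bad)!r}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


def sliding_windows(
    read: str, params: IndexParams = IndexParams()
) -> list[tuple[int, str]]:
    """Step-1 windows of a single strand: ``(offset, kmer)`` pairs.

    Windows containing non-ACGT characters (after uppercasing) are omitted;
    reads shorter than k yield no windows.
    """
    k = params.k
    seq = read.upper()
    out = []
    for off in range(len(seq) - k + 1):
        window = seq[off : off + k]
        if all(b in _ACGT for b in window):
            out.append((off, window))
    return out


def permute_1bp(kmer: str) -> set[str]:
    """All 3k strings at Hamming distance exactly 1 (input excluded)."""
    if not kmer or set(kmer) - _ACGT:
        raise QueryError(f"permute_1bp requires a non-empty ACGT string")
    out: set[str] = set()
    for i, base in enumerate(kmer):
        for alt in "ACGT":
            if alt != base:
                out.add(kmer[:i] + alt + kmer[i + 1 :])
    return out


# ---------------------------------------------------------------------------
# vectorized read encoding
# ---------------------------------------------------------------------------


class EncodedReads:
    """2-bit packed windows of a read batch, both strands.

    Windows from all reads and both strands are concatenated into flat
    arrays; ``win_read``/``win_off``/``win_strand`` recover the provenance
    of each window.  Built once and shared by all shard programs.
    """

    __slots__ = (
        "read_ids",
        "params",
        "win_vals",
        "win_read",
        "win_off",
        "win_strand",
        "windows_scanned",
    )

    def __init__(self, reads: Sequence[tuple[str, str]], params: IndexParams):
        self.params = params
        self.read_ids = [rid for rid, _ in reads]
        if len(set(self.read_ids)) != len(self.read_ids):
            from collections import Counter

            counts = Counter(self.read_ids)
            dupes = sorted(r for r, c in counts.items() if c > 1)
            raise SearchInputError(f"duplicate read ids: {dupes[:5]}")
        k = params.k
        seqs = [seq.upper() for _, seq in reads]
        vals_parts, read_parts, off_parts, strand_parts = [], [], [], []
        for strand_code, strand_seqs in enumerate(
            (seqs, [_revcomp_lenient(s) for s in seqs])
        ):
            pos, vals, starts = _concat_windows(strand_seqs, k)
            if len(pos):
                ridx = np.searchsorted(starts, pos, side="right") - 1
                vals_parts.append(vals)
                read_parts.append(ridx.astype(np.int64))
                off_parts.append((pos - starts[ridx]).astype(np.int64))
                strand_parts.append(
                    np.full(len(pos), strand_code, dtype=np.uint8)
                )
        if vals_parts:
            self.win_vals = np.concatenate(vals_parts)
            self.win_read = np.concatenate(read_parts)
            self.win_off = np.concatenate(off_parts)
            self.win_strand = np.concatenate(strand_parts)
        else:
            self.win_vals = np.empty(0, dtype=np.uint64)
            self.win_read = np.empty(0, dtype=np.int64)
            self.win_off = np.empty(0, dtype=np.int64)
            self.win_strand = np.empty(0, dtype=np.uint8)
        self.windows_scanned = np.bincount(
            self.win_read, minlength=len(reads)
        ).astype(np.int64)


def _revcomp_lenient(seq: str) -> str:
    # non-ACGTN characters stay invalid after complementing; windows
    # containing them are dropped at encoding time anyway
    return seq.translate(_COMPLEMENT)[::-1]


def _concat_windows(
    seqs: Sequence[str], k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Valid window positions and packed values over concatenated sequences.

    Sequences are joined with k sentinel (invalid) bases so no window spans
    two reads.  Returns (global positions, uint64 values, read start
    offsets in the concatenation).
    """
    sep = np.full(k, 255, dtype=np.uint8)
    chunks: list[np.ndarray] = []
    starts = np.empty(len(seqs), dtype=np.int64)
    cursor = 0
    for i, seq in enumerate(seqs):
        starts[i] = cursor
        codes = sequence_codes(seq)
        chunks.append(codes)
        cursor += len(codes)
        chunks.append(sep)
        cursor += k
    digits = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    )
    n = len(digits)
    if n < k:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.uint64),
            starts,
        )
    bad = digits > 3
    csum = np.concatenate(([0], np.cumsum(bad)))
    ok = (csum[k:] - csum[: n - k + 1]) == 0
    clean = np.where(bad, 0, digits).astype(np.uint64)
    nw = n - k + 1
    vals = np.zeros(nw, dtype=np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | clean[j : j + nw]
    positions = np.nonzero(ok)[0].astype(np.int64)
    return positions, vals[positions], starts


def _as_encoded(
    reads: "EncodedReads | Iterable[tuple[str, str]]", params: IndexParams
) -> EncodedReads:
    if isinstance(reads, EncodedReads):
        if reads.params != params:
            raise IndexCompatibilityError(
                "encoded reads were built with different index parameters"
            )
        return reads
    return EncodedReads(list(reads), params)


def _substitution_deltas(k: int) -> np.ndarray:
    """The 3k XOR masks generating all Hamming-1 variants of a packed k-mer.

    Position order matches string order (position 0 = most significant).
    """
    deltas = [
        np.uint64(d) << np.uint64(2 * (k - 1 - p))
        for p in range(k)
        for d in (1, 2, 3)
    ]
    return np.array(deltas, dtype=np.uint64)


# ---------------------------------------------------------------------------
# per-shard map step
# ---------------------------------------------------------------------------


def _shard_hits(
    keys: np.ndarray, suffixes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of queries found in sorted ``keys`` and their key rows."""
    if len(keys) == 0 or len(suffixes) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    pos = np.searchsorted(keys, suffixes)
    pos_clipped = np.minimum(pos, len(keys) - 1)
    hit = keys[pos_clipped] == suffixes
    return np.nonzero(hit)[0].astype(np.int64), pos_clipped[hit].astype(
        np.int64
    )


def _check_shard_geometry(shard: Shard, params: IndexParams) -> None:
    if len(shard.prefix) != params.prefix_len:
        raise IndexCompatibilityError(
            f"shard prefix {shard.prefix!r} incompatible with "
            f"prefix_len={params.prefix_len}"
        )
    for suffix in shard.table:
        if len(suffix) != params.suffix_len:
            raise IndexCompatibilityError(
                f"shard suffix length {len(suffix)} != {params.suffix_len}"
            )
        break


def search_shard(
    reads: "EncodedReads | Iterable[tuple[str, str]]",
    shard: Shard,
    config: SearchConfig,
) -> list[WindowMatch]:
    """One shard's search program over a batch of reads.

    The shard answers every query whose first ``prefix_len`` bases equal its
    prefix: in exact mode the read windows themselves, in permuted mode also
    every substitution variant whose (possibly mutated) prefix equals the
    shard prefix — including variants of windows that originally belonged to
    other shards.  Species matched by both the exact window and a variant
    are reported once, with ``permuted=False``.
    """
    params = config.params
    _check_shard_geometry(shard, params)
    enc = _as_encoded(reads, params)
    sid = np.uint64(encode_prefix(shard.prefix, params.prefix_len))
    shift = np.uint64(2 * params.suffix_len)
    mask = np.uint64((1 << (2 * params.suffix_len)) - 1)
    keys, rows = shard.encoded()

    # win index -> {species: permuted flag}; False (exact) takes precedence
    events: dict[int, dict[str, bool]] = {}

    def record(win_indices: np.ndarray, row_indices: np.ndarray, permuted: bool):
        for w, r in zip(win_indices.tolist(), row_indices.tolist()):
            bucket = events.setdefault(w, {})
            for sp in rows[r]:
                if permuted:
                    bucket.setdefault(sp, True)
                else:
                    bucket[sp] = False

    vals = enc.win_vals
    own = np.nonzero((vals >> shift) == sid)[0]
    qi, rowi = _shard_hits(keys, vals[own] & mask)
    record(own[qi], rowi, permuted=False)

    if config.mode == "permuted" and len(vals):
        deltas = _substitution_deltas(params.k)
        chunk = 65536
        for start in range(0, len(vals), chunk):
            block = vals[start : start + chunk]
            variants = block[:, None] ^ deltas[None, :]
            sel = np.nonzero((variants >> shift) == sid)
            qsuffix = variants[sel] & mask
            qi, rowi = _shard_hits(keys, qsuffix)
            record(start + sel[0][qi], rowi, permuted=True)

    return _events_to_matches(enc, events)


def _events_to_matches(
    enc: EncodedReads, events: dict[int, dict[str, bool]]
) -> list[WindowMatch]:
    matches: list[WindowMatch] = []
    for w in sorted(events):
        read_id = enc.read_ids[enc.win_read[w]]
        offset = int(enc.win_off[w])
        strand = FORWARD if enc.win_strand[w] == 0 else REVERSE
        by_flag: dict[bool, set[str]] = {}
        for sp, permuted in events[w].items():
            by_flag.setdefault(permuted, set()).add(sp)
        for permuted in (False, True):
            if permuted in by_flag:
                matches.append(
                    WindowMatch(
                        read_id=read_id,
                        offset=offset,
                        strand=strand,
                        permuted=permuted,
                        species_ids=frozenset(by_flag[permuted]),
                    )
                )
    return matches


# ---------------------------------------------------------------------------
# reduce step
# ---------------------------------------------------------------------------


def reduce_matches(
    partials: Iterable[Sequence[WindowMatch]],
    read_ids: Sequence[str] | None = None,
    windows_scanned: Mapping[str, int] | None = None,
) -> dict[str, ReadMatchSet]:
    """Merge per-shard match lists into per-read match sets.

    Deduplicates per (offset, strand, species) with exact evidence beating
    permuted; the result is independent of shard order.  When ``read_ids``
    is given every listed read appears in the output (possibly with no
    matches); duplicate ids are rejected.
    """
    if read_ids is not None and len(set(read_ids)) != len(read_ids):
        raise SearchInputError("duplicate read ids in reduce input")
    # read -> (offset, strand) -> species -> permuted flag
    acc: dict[str, dict[tuple[int, str], dict[str, bool]]] = {}
    order: list[str] = list(read_ids) if read_ids is not None else []
    seen = set(order)
    for partial in partials:
        for m in partial:
            if m.read_id not in seen:
                seen.add(m.read_id)
                order.append(m.read_id)
            window = acc.setdefault(m.read_id, {}).setdefault(
                (m.offset, m.strand), {}
            )
            for sp in m.species_ids:
                if m.permuted:
                    window.setdefault(sp, True)
                else:
                    window[sp] = False
    out: dict[str, ReadMatchSet] = {}
    for read_id in order:
        matches: list[WindowMatch] = []
        for (offset, strand) in sorted(acc.get(read_id, {})):
            flags = acc[read_id][(offset, strand)]
            for permuted in (False, True):
                species = {sp for sp, f in flags.items() if f == permuted}
                if species:
                    matches.append(
                        WindowMatch(
                            read_id, offset, strand, permuted,
                            frozenset(species),
                        )
                    )
        scanned = windows_scanned.get(read_id, 0) if windows_scanned else 0
        out[read_id] = ReadMatchSet(read_id, matches, scanned)
    return out


# ---------------------------------------------------------------------------
# full map-reduce driver
# ---------------------------------------------------------------------------


def _routed_pass(
    vals: np.ndarray,
    win_idx: np.ndarray,
    shard_arrays: list[tuple[np.ndarray, list[tuple[str, ...]]]],
    shard_order: Sequence[int],
    shift: np.uint64,
    mask: np.uint64,
    workers: int,
) -> list[tuple[int, int, tuple[str, ...]]]:
    """Answer packed queries shard by shard.

    Queries are sorted by owning prefix once, then each shard in
    ``shard_order`` resolves its contiguous slice with a binary search over
    its own keys — the same lookups the per-shard programs would perform.
    Returns (window index, order rank, species tuple) hit triples; the rank
    is only used to keep downstream assembly deterministic.
    """
    if len(vals) == 0:
        return []
    prefixes = vals >> shift
    order = np.argsort(prefixes, kind="stable")
    sorted_prefix = prefixes[order]
    sorted_vals = vals[order]
    sorted_win = win_idx[order]

    def do_shard(sid: int) -> list[tuple[int, int, tuple[str, ...]]]:
        lo = np.searchsorted(sorted_prefix, np.uint64(sid), side="left")
        hi = np.searchsorted(sorted_prefix, np.uint64(sid), side="right")
        if lo == hi:
            return []
        keys, rows = shard_arrays[sid]
        qi, rowi = _shard_hits(keys, sorted_vals[lo:hi] & mask)
        out = []
        for q, r in zip(qi.tolist(), rowi.tolist()):
            out.append((int(sorted_win[lo + q]), int(lo + q), rows[r]))
        return out

    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            chunks = list(pool.map(do_shard, shard_order))
    else:
        chunks = [do_shard(sid) for sid in shard_order]
    hits: list[tuple[int, int, tuple[str, ...]]] = []
    for chunk in chunks:
        hits.extend(chunk)
    return hits


def search_reads(
    index: ShardedIndex,
    reads: "EncodedReads | Iterable[tuple[str, str]]",
    config: SearchConfig | None = None,
    shard_order: Sequence[int] | None = None,
) -> dict[str, ReadMatchSet]:
    """Map-reduce search of a read batch against the full index.

    Equivalent to running :func:`search_shard` for every shard and reducing,
    but with the queries routed to shards in vectorized batches.  Results
    are invariant to ``workers`` and to ``shard_order`` (exposed for
    testing that invariance).
    """
    config = config or SearchConfig(params=index.params)
    if config.params != index.params:
        raise IndexCompatibilityError(
            f"search config params {config.params} != index params "
            f"{index.params}"
        )
    params = index.params
    enc = _as_encoded(reads, params)
    shift = np.uint64(2 * params.suffix_len)
    mask = np.uint64((1 << (2 * params.suffix_len)) - 1)
    shard_arrays = [shard.encoded() for shard in index.shards]
    if shard_order is None:
        shard_order = range(params.shard_count)

    events: dict[int, dict[str, bool]] = {}

    def record(hits: list[tuple[int, int, tuple[str, ...]]], permuted: bool):
        for w, _, species in sorted(hits, key=lambda h: (h[0], h[1])):
            bucket = events.setdefault(w, {})
            for sp in species:
                if permuted:
                    bucket.setdefault(sp, True)
                else:
                    bucket[sp] = False

    all_idx = np.arange(len(enc.win_vals), dtype=np.int64)
    record(
        _routed_pass(
            enc.win_vals, all_idx, shard_arrays, shard_order, shift, mask,
            config.workers,
        ),
        permuted=False,
    )

    if config.mode == "permuted" and len(enc.win_vals):
        deltas = _substitution_deltas(params.k)
        chunk = 65536
        for start in range(0, len(enc.win_vals), chunk):
            block = enc.win_vals[start : start + chunk]
            variants = (block[:, None] ^ deltas[None, :]).ravel()
            vwin = np.repeat(
                np.arange(start, start + len(block), dtype=np.int64),
                len(deltas),
            )
            record(
                _routed_pass(
                    variants, vwin, shard_arrays, shard_order, shift, mask,
                    config.workers,
                ),
                permuted=True,
            )

    matches = _events_to_matches(enc, events)
    scanned = {
        rid: int(n) for rid, n in zip(enc.read_ids, enc.windows_scanned)
    }
    return reduce_matches([matches], enc.read_ids, scanned)
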