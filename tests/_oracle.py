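"""Independent brute-force reference implementations for the test suite.

These deliberately avoid the package's sharded engine: the database is a
single flat dict built by a character-level scan, and search walks every
window of every read against it.  Two permuted-mode oracles exist — a
triple-loop scan of all 3k variants per window (used at tiny scale) and a
precomputed Hamming-1 neighborhood dictionary (used at 10k-read scale);
both are independent of the prefix-sharded map-reduce path they check.
"""

from __future__ import annotations

from smartmeta.search import ReadMatchSet

KMER = 30
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def naive_db(records, taxonomy, k: int = KMER) -> dict[str, set[str]]:
    """Flat dict of non-overlapping tiles -> species set."""
    db: dict[str, set[str]] = {}
    for rid, seq in records:
        species = taxonomy.lineage_of(rid).species_id
        seq = seq.upper()
        for off in range(0, len(seq) - k + 1, k):
            tile = seq[off : off + k]
            if set(tile) <= set("ACGT"):
                db.setdefault(tile, set()).add(species)
    return db


def variants_1bp(kmer: str) -> set[str]:
    out = set()
    for i, b in enumerate(kmer):
        for alt in "ACGT":
            if alt != b:
                out.add(kmer[:i] + alt + kmer[i + 1 :])
    return out


def neighbor_db(db: dict[str, set[str]]) -> dict[str, set[str]]:
    """Hamming-1 neighborhood of the stored k-mers."""
    nb: dict[str, set[str]] = {}
    for kmer, species in db.items():
        for v in variants_1bp(kmer):
            nb.setdefault(v, set()).update(species)
    return nb


def _scan_strands(seq: str, k: int):
    seq = seq.upper()
    for strand, s in (("forward", seq), ("reverse", revcomp(seq))):
        for off in range(len(s) - k + 1):
            window = s[off : off + k]
            if set(window) <= set("ACGT"):
                yield strand, off, window


def oracle_events(
    reads,
    db: dict[str, set[str]],
    mode: str = "exact",
    k: int = KMER,
    nb: dict[str, set[str]] | None = None,
    triple_loop: bool = False,
) -> dict[str, dict[tuple[int, str, str], bool]]:
    """read_id -> {(offset, strand, species): permuted flag}.

    Exact evidence wins over permuted per (window, strand, species).
    """
    if mode == "permuted" and nb is None and not triple_loop:
        nb = neighbor_db(db)
    out: dict[str, dict[tuple[int, str, str], bool]] = {}
    for read_id, seq in reads:
        events: dict[tuple[int, str, str], bool] = {}
        for strand, off, window in _scan_strands(seq, k):
            exact = db.get(window, set())
            for sp in exact:
                events[(off, strand, sp)] = False
            if mode == "permuted":
                if triple_loop:
                    near: set[str] = set()
                    for v in variants_1bp(window):
                        near |= db.get(v, set())
                else:
                    near = nb.get(window, set())
                for sp in near - exact:
                    events.setdefault((off, strand, sp), True)
        out[read_id] = events
    return out


def matchset_events(ms: ReadMatchSet) -> dict[tuple[int, str, str], bool]:
    """Canonical event dict of a package ReadMatchSet, for comparison."""
    events: dict[tuple[int, str, str], bool] = {}
    for m in ms.matches:
        for sp in m.species_ids:
            key = (m.offset, m.strand, sp)
            if m.permuted:
                events.setdefault(key, True)
            else:
                events[key] = False
    return events
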