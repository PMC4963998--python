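"""Vote tallying, per-read verdicts, and sample-level reports.

Each deduplicated (window, strand, species) match event contributes one
species-level vote; genus and class tallies are derived by summing species
votes through the taxonomy (with a single-lineage taxonomy this is
equivalent to tallying genus/class matches directly).  Per level, the
verdict is the unique argmax taxon, AMBIGUOUS on a tie, or UNMATCHED when
the read produced no events at all.

The host-override rule is conservative: a read with even one mammalian
match event is categorized MAMMALIAN regardless of the tallies — designed
for host-rich samples where partial homology would otherwise inflate the
microbial fraction.  Sample reports partition reads into
MAMMALIAN > UNMATCHED > AMBIGUOUS (species-level tie) > NON_MAMMALIAN, and
per-genus read counts can be normalized by host genome depth of coverage to
compare samples of different sequencing depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ClassificationError
from .search import ReadMatchSet
from .taxonomy import TaxonomyTable

__all__ = [
    "AMBIGUOUS",
    "UNMATCHED",
    "CATEGORIES",
    "VoteTally",
    "ReadClassification",
    "SampleReport",
    "GenusNormalization",
    "tally_votes",
    "classify_read",
    "classify_sample",
    "summarize_sample",
    "normalize_by_host_coverage",
]

AMBIGUOUS = "AMBIGUOUS"
UNMATCHED = "UNMATCHED"

MAMMALIAN = "mammalian"
NON_MAMMALIAN = "non_mammalian"
CAT_AMBIGUOUS = "ambiguous"
CAT_UNMATCHED = "unmatched"
CATEGORIES = (MAMMALIAN, NON_MAMMALIAN, CAT_AMBIGUOUS, CAT_UNMATCHED)

LEVELS = ("species", "genus", "class")


@dataclass
class VoteTally:
    """Per-level vote counts for one read."""

    species: Counter = field(default_factory=Counter)
    genus: Counter = field(default_factory=Counter)
    class_: Counter = field(default_factory=Counter)

    def at(self, level: str) -> Counter:
        return {
            "species": self.species,
            "genus": self.genus,
            "class": self.class_,
        }[level]

    def total_votes(self) -> int:
        return sum(self.species.values())


@dataclass
class ReadClassification:
    """Final per-read verdicts plus the tallies that produced them."""

    read_id: str
    verdict_per_level: dict[str, str]
    mammalian_override: bool
    tally: VoteTally
    category: str

    @property
    def species_verdict(self) -> str:
        return self.verdict_per_level["species"]


def tally_votes(
    match_set: ReadMatchSet, taxonomy: TaxonomyTable
) -> VoteTally:
    """One vote per deduplicated (window, strand, species) event.

    Exact and permuted matches weigh equally; genus/class counts are the
    lineage sums of the species counts.
    """
    species_index = taxonomy.species_index()
    tally = VoteTally()
    for _, _, species in match_set.species_events():
        lineage = species_index.get(species)
        if lineage is None:
            raise ClassificationError(
                f"matched species {species!r} has no lineage in the taxonomy"
            )
        tally.species[species] += 1
        tally.genus[lineage.genus_id] += 1
        tally.class_[lineage.class_id] += 1
    return tally


def _level_verdict(counts: Counter) -> str:
    if not counts:
        return UNMATCHED
    top = max(counts.values())
    leaders = [t for t, c in counts.items() if c == top]
    return leaders[0] if len(leaders) == 1 else AMBIGUOUS


def classify_read(
    tally: VoteTally,
    match_set: ReadMatchSet,
    taxonomy: TaxonomyTable,
) -> ReadClassification:
    """Per-level verdicts with the mammalian override.

    Verdict precedence per level: UNMATCHED when there are no votes, the
    unique argmax taxon otherwise, AMBIGUOUS on a tie.  The override is
    recorded independently of the verdicts, and the read's final category
    applies the precedence MAMMALIAN > UNMATCHED > AMBIGUOUS (species tie) >
    NON_MAMMALIAN.
    """
    if tally.total_votes() != len(match_set.species_events()):
        raise ClassificationError(
            f"tally for {match_set.read_id!r} does not derive from its "
            f"match set"
        )
    species_index = taxonomy.species_index()
    verdicts = {level: _level_verdict(tally.at(level)) for level in LEVELS}
    override = any(
        species_index[sp].is_mammalian
        for sp in match_set.matched_species()
        if sp in species_index
    )
    if override:
        category = MAMMALIAN
    elif verdicts["species"] == UNMATCHED:
        category = CAT_UNMATCHED
    elif verdicts["species"] == AMBIGUOUS:
        category = CAT_AMBIGUOUS
    else:
        category = NON_MAMMALIAN
    return ReadClassification(
        read_id=match_set.read_id,
        verdict_per_level=verdicts,
        mammalian_override=override,
        tally=tally,
        category=category,
    )


def classify_sample(
    match_sets: Mapping[str, ReadMatchSet], taxonomy: TaxonomyTable
) -> list[ReadClassification]:
    """Tally and classify every read of a sample."""
    out = []
    for read_id in match_sets:
        ms = match_sets[read_id]
        out.append(classify_read(tally_votes(ms, taxonomy), ms, taxonomy))
    return out


@dataclass
class SampleReport:
    """Table-style aggregate of one sample's classifications."""

    total_reads: int
    counts: dict[str, int]
    fractions: dict[str, float]
    genus_counts: dict[str, int]
    normalized_genus: dict[str, float] | None = None
    host_depth: float | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "total_reads": self.total_reads,
            "counts": dict(self.counts),
            "fractions": dict(self.fractions),
            "genus_counts": dict(self.genus_counts),
        }
        if self.normalized_genus is not None:
            out["normalized_genus"] = dict(self.normalized_genus)
            out["host_depth"] = self.host_depth
        return out


def summarize_sample(
    classifications: Sequence[ReadClassification],
) -> SampleReport:
    """Category counts/fractions plus per-genus read counts.

    Each read lands in exactly one category; genus counts run over reads
    with a unique genus verdict (whatever their category).
    """
    counts = {c: 0 for c in CATEGORIES}
    genus_counts: Counter = Counter()
    for rc in classifications:
        counts[rc.category] += 1
        gv = rc.verdict_per_level["genus"]
        if gv not in (AMBIGUOUS, UNMATCHED):
            genus_counts[gv] += 1
    total = len(classifications)
    fractions = {
        c: (counts[c] / total if total else 0.0) for c in CATEGORIES
    }
    return SampleReport(
        total_reads=total,
        counts=counts,
        fractions=fractions,
        genus_counts=dict(sorted(genus_counts.items())),
    )


@dataclass
class GenusNormalization:
    """Per-genus counts divided by host depth of coverage.

    ``normalized`` is False (and values are the raw counts) when the depth
    is zero — normalization is refused rather than dividing by zero.
    """

    values: dict[str, float]
    depth: float
    normalized: bool


def normalize_by_host_coverage(
    genus_counts: Mapping[str, int | float],
    host_read_count: int,
    host_genome_length: int,
    read_length: int,
) -> GenusNormalization:
    """Divide genus read counts by host mean depth of coverage.

    depth = host_read_count * read_length / host_genome_length.  A depth of
    zero returns the counts unnormalized with a warning flag.
    """
    if host_genome_length <= 0 or read_length <= 0:
        raise ClassificationError(
            "host_genome_length and read_length must be positive"
        )
    if host_read_count < 0:
        raise ClassificationError("host_read_count must be non-negative")
    depth = host_read_count * read_length / host_genome_length
    if depth == 0:
        return GenusNormalization(
            values={g: float(c) for g, c in genus_counts.items()},
            depth=0.0,
            normalized=False,
        )
    return GenusNormalization(
        values={g: c / depth for g, c in genus_counts.items()},
        depth=depth,
        normalized=True,
    )
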