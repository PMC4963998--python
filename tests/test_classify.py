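"""Vote tallying, verdicts, the mammalian override, and sample reports."""

import pytest

from smartmeta import (
    AMBIGUOUS,
    UNMATCHED,
    TaxonAssignment,
    TaxonomyTable,
    classify_read,
    normalize_by_host_coverage,
    summarize_sample,
    tally_votes,
)
from smartmeta.classify import (
    CAT_AMBIGUOUS,
    CAT_UNMATCHED,
    MAMMALIAN,
    NON_MAMMALIAN,
    ReadClassification,
    VoteTally,
)
from smartmeta.errors import ClassificationError
from smartmeta.search import ReadMatchSet, WindowMatch


@pytest.fixture()
def taxonomy():
    return TaxonomyTable(
        {
            "rX": TaxonAssignment.from_lineage("spX", "genG", "clsM"),
            "rY": TaxonAssignment.from_lineage("spY", "genG", "clsM"),
            "rZ": TaxonAssignment.from_lineage("spZ", "genZ", "clsZ"),
            "rH": TaxonAssignment.from_lineage("H. sapiens", "Homo", "Mammalia"),
        }
    )


def match_set(read_id, events):
    """events: list of (offset, strand, permuted, species set)."""
    return ReadMatchSet(
        read_id,
        [
            WindowMatch(read_id, off, strand, permuted, frozenset(species))
            for off, strand, permuted, species in events
        ],
        windows_scanned=100,
    )


def test_tally_sums_species_into_genus_and_class(taxonomy):
    ms = match_set(
        "r",
        [
            (0, "forward", False, {"spX"}),
            (10, "forward", False, {"spX"}),
            (20, "forward", True, {"spX"}),
            (30, "forward", False, {"spY"}),
        ],
    )
    tally = tally_votes(ms, taxonomy)
    assert tally.species == {"spX": 3, "spY": 1}
    assert tally.genus == {"genG": 4}
    assert tally.class_ == {"clsM": 4}


def test_tally_deduplicates_same_window_species(taxonomy):
    # the same (offset, strand, species) reported exact and permuted is one vote
    ms = match_set(
        "r",
        [
            (0, "forward", False, {"spX"}),
            (0, "forward", True, {"spX"}),
        ],
    )
    assert tally_votes(ms, taxonomy).species == {"spX": 1}


def test_tally_empty_and_unknown_species(taxonomy):
    assert tally_votes(match_set("r", []), taxonomy).total_votes() == 0
    with pytest.raises(ClassificationError):
        tally_votes(
            match_set("r", [(0, "forward", False, {"mystery"})]), taxonomy
        )


def classify(ms, taxonomy):
    return classify_read(tally_votes(ms, taxonomy), ms, taxonomy)


def test_unique_argmax_wins_at_each_level(taxonomy):
    ms = match_set(
        "r",
        [
            (0, "forward", False, {"spX"}),
            (10, "forward", False, {"spX"}),
            (20, "forward", False, {"spX"}),
            (30, "forward", False, {"spY"}),
        ],
    )
    rc = classify(ms, taxonomy)
    assert rc.verdict_per_level == {
        "species": "spX", "genus": "genG", "class": "clsM",
    }
    assert rc.category == NON_MAMMALIAN and not rc.mammalian_override


def test_species_tie_resolves_at_genus_level(taxonomy):
    ms = match_set(
        "r",
        [
            (0, "forward", False, {"spX"}),
            (5, "forward", False, {"spX"}),
            (10, "forward", False, {"spY"}),
            (15, "forward", False, {"spY"}),
        ],
    )
    rc = classify(ms, taxonomy)
    assert rc.verdict_per_level["species"] == AMBIGUOUS
    assert rc.verdict_per_level["genus"] == "genG"
    assert rc.category == CAT_AMBIGUOUS


def test_unmatched_read_is_unmatched_at_every_level(taxonomy):
    rc = classify(match_set("r", []), taxonomy)
    assert set(rc.verdict_per_level.values()) == {UNMATCHED}
    assert rc.category == CAT_UNMATCHED


def test_single_mammalian_match_overrides_higher_tally(taxonomy):
    events = [(o, "forward", False, {"spZ"}) for o in range(0, 70, 10)]
    events.append((5, "reverse", False, {"H. sapiens"}))
    rc = classify(match_set("r", events), taxonomy)
    assert rc.tally.species["spZ"] == 7
    assert rc.tally.species["H. sapiens"] == 1
    assert rc.verdict_per_level["species"] == "spZ"  # verdicts untouched
    assert rc.mammalian_override and rc.category == MAMMALIAN


def test_override_dominates_ambiguity(taxonomy):
    # mammalian-tied read is MAMMALIAN, not ambiguous
    ms = match_set(
        "r",
        [
            (0, "forward", False, {"spZ"}),
            (10, "forward", False, {"H. sapiens"}),
        ],
    )
    rc = classify(ms, taxonomy)
    assert rc.verdict_per_level["species"] == AMBIGUOUS
    assert rc.category == MAMMALIAN


def test_adding_a_mammalian_event_always_yields_mammalian(taxonomy):
    base_sets = [
        match_set("r", []),
        match_set("r", [(0, "forward", False, {"spZ"})]),
        match_set(
            "r",
            [
                (0, "forward", False, {"spX"}),
                (10, "forward", False, {"spY"}),
            ],
        ),
    ]
    for ms in base_sets:
        augmented = ReadMatchSet(
            "r",
            ms.matches
            + [WindowMatch("r", 60, "forward", True, frozenset({"H. sapiens"}))],
            ms.windows_scanned,
        )
        rc = classify(augmented, taxonomy)
        assert rc.category == MAMMALIAN


def test_unique_species_verdict_implies_consistent_coarser_verdicts(taxonomy):
    ms = match_set("r", [(0, "forward", False, {"spZ"})])
    rc = classify(ms, taxonomy)
    assert rc.verdict_per_level == {
        "species": "spZ", "genus": "genZ", "class": "clsZ",
    }


def test_inconsistent_tally_rejected(taxonomy):
    ms = match_set("r", [(0, "forward", False, {"spZ"})])
    wrong = VoteTally()
    wrong.species["spZ"] = 5
    with pytest.raises(ClassificationError):
        classify_read(wrong, ms, taxonomy)


# -- sample summaries --------------------------------------------------------


def make_rc(read_id, category, genus="genG"):
    verdicts = {"species": "spX", "genus": genus, "class": "clsM"}
    if category == CAT_UNMATCHED:
        verdicts = {lvl: UNMATCHED for lvl in verdicts}
    if category == CAT_AMBIGUOUS:
        verdicts["species"] = AMBIGUOUS
    return ReadClassification(
        read_id=read_id,
        verdict_per_level=verdicts,
        mammalian_override=category == MAMMALIAN,
        tally=VoteTally(),
        category=category,
    )


def test_summarize_counts_and_fractions_partition_reads():
    rcs = (
        [make_rc(f"m{i}", MAMMALIAN) for i in range(4)]
        + [make_rc(f"b{i}", NON_MAMMALIAN) for i in range(3)]
        + [make_rc(f"a{i}", CAT_AMBIGUOUS) for i in range(2)]
        + [make_rc("u0", CAT_UNMATCHED)]
    )
    report = summarize_sample(rcs)
    assert report.total_reads == 10
    assert report.counts == {
        "mammalian": 4, "non_mammalian": 3, "ambiguous": 2, "unmatched": 1,
    }
    assert report.fractions == {
        "mammalian": 0.4, "non_mammalian": 0.3, "ambiguous": 0.2,
        "unmatched": 0.1,
    }
    assert sum(report.counts.values()) == report.total_reads
    # genus counts run over reads with a unique genus verdict
    assert report.genus_counts == {"genG": 9}


def test_summarize_empty_sample():
    report = summarize_sample([])
    assert report.total_reads == 0
    assert all(v == 0 for v in report.counts.values())


# -- host-coverage normalization --------------------------------------------


def test_normalization_divides_by_depth():
    norm = normalize_by_host_coverage(
        {"genA": 100}, host_read_count=1000,
        host_genome_length=50000, read_length=100,
    )
    assert norm.depth == pytest.approx(2.0)
    assert norm.values == {"genA": pytest.approx(50.0)}
    assert norm.normalized


def test_normalization_refused_at_zero_depth():
    norm = normalize_by_host_coverage(
        {"genA": 100}, host_read_count=0,
        host_genome_length=50000, read_length=100,
    )
    assert not norm.normalized
    assert norm.values == {"genA": 100.0}


def test_normalization_rejects_nonpositive_lengths():
    with pytest.raises(ClassificationError):
        normalize_by_host_coverage({}, 1, 0, 100)
    with pytest.raises(ClassificationError):
        normalize_by_host_coverage({}, 1, 100, 0)
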