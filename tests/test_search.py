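"""Window scanning, 1-bp permutation matching, and map-reduce equivalence."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smartmeta import (
    EncodedReads,
    IndexParams,
    SearchConfig,
    TaxonAssignment,
    TaxonomyTable,
    build_index,
    permute_1bp,
    reduce_matches,
    reverse_complement,
    search_reads,
    search_shard,
    sliding_windows,
)
from smartmeta.errors import (
    EncodingError,
    IndexCompatibilityError,
    QueryError,
    SearchInputError,
)
from smartmeta.search import WindowMatch

from _oracle import matchset_events, naive_db, oracle_events

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


# -- primitives --------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGT", "ACGT"), ("AAAC", "GTTT"), ("ANGT", "ACNT")],
)
def test_reverse_complement_examples(seq, expected):
    assert reverse_complement(seq) == expected


def test_reverse_complement_rejects_other_characters():
    with pytest.raises(EncodingError):
        reverse_complement("ACGU")


@settings(deadline=None)
@given(dna)
def test_reverse_complement_is_an_involution(seq):
    assert reverse_complement(reverse_complement(seq)) == seq


def test_sliding_windows_counts():
    rng = random.Random(0)
    read31 = "".join(rng.choices("ACGT", k=31))
    assert [off for off, _ in sliding_windows(read31)] == [0, 1]
    read30 = read31[:30]
    assert len(sliding_windows(read30)) == 1
    assert sliding_windows("A" * 29) == []


def test_sliding_windows_skip_windows_containing_n():
    rng = random.Random(1)
    read = list("".join(rng.choices("ACGT", k=35)))
    read[32] = "N"
    offs = [off for off, _ in sliding_windows("".join(read))]
    assert offs == [0, 1, 2]


def test_permute_1bp_tiny_and_full_size():
    assert permute_1bp("AA") == {"CA", "GA", "TA", "AC", "AG", "AT"}
    kmer = "".join(random.Random(2).choices("ACGT", k=30))
    variants = permute_1bp(kmer)
    assert len(variants) == 90
    assert kmer not in variants
    for v in variants:
        assert sum(a != b for a, b in zip(v, kmer)) == 1


def test_permute_1bp_rejects_bad_alphabet():
    with pytest.raises(QueryError):
        permute_1bp("ACGN")


# -- search_shard ------------------------------------------------------------


def one_species_index(seq, species="spX"):
    tax = TaxonomyTable(
        {"r1": TaxonAssignment.from_lineage(species, "genX", "clsX")}
    )
    return build_index([("r1", seq)], tax)


def test_search_shard_exact_forward_match():
    kmer = "".join(random.Random(3).choices("ACGT", k=30))
    index = one_species_index(kmer)
    shard = index.shard_for(kmer)
    config = SearchConfig(mode="exact", params=index.params)
    matches = search_shard([("read1", kmer)], shard, config)
    fwd = [m for m in matches if m.strand == "forward"]
    assert fwd == [
        WindowMatch("read1", 0, "forward", False, frozenset({"spX"}))
    ]


def test_search_shard_reverse_complement_match():
    kmer = "".join(random.Random(4).choices("ACGT", k=30))
    index = one_species_index(kmer)
    config = SearchConfig(mode="exact", params=index.params)
    read = reverse_complement(kmer)
    all_matches = [
        m
        for shard in index.shards
        for m in search_shard([("read1", read)], shard, config)
    ]
    assert (
        WindowMatch("read1", 0, "reverse", False, frozenset({"spX"}))
        in all_matches
    )


def test_search_shard_one_substitution_needs_permuted_mode():
    rng = random.Random(5)
    kmer = "".join(rng.choices("ACGT", k=30))
    mutated = list(kmer)
    mutated[10] = next(b for b in "ACGT" if b != kmer[10])
    read = "".join(mutated)
    index = one_species_index(kmer)
    exact_cfg = SearchConfig(mode="exact", params=index.params)
    perm_cfg = SearchConfig(mode="permuted", params=index.params)
    exact = [
        m
        for shard in index.shards
        for m in search_shard([("read1", read)], shard, exact_cfg)
    ]
    # forward strand yields nothing exact; reverse strand can't match either
    assert not [m for m in exact if not m.permuted]
    permuted = [
        m
        for shard in index.shards
        for m in search_shard([("read1", read)], shard, perm_cfg)
    ]
    fwd = [m for m in permuted if m.strand == "forward"]
    assert fwd == [
        WindowMatch("read1", 0, "forward", True, frozenset({"spX"}))
    ]


def test_variant_mutated_in_prefix_is_answered_by_owning_shard():
    """A substitution inside the 4-bp prefix moves the query to another
    shard; that shard must answer it."""
    kmer = "A" + "".join(random.Random(6).choices("ACGT", k=29))
    read = "C" + kmer[1:]  # differs from stored kmer at position 0
    index = one_species_index(kmer)
    perm_cfg = SearchConfig(mode="permuted", params=index.params)
    owner = index.shard_for(kmer)  # shard of the STORED kmer's prefix
    matches = search_shard([("read1", read)], owner, perm_cfg)
    assert any(
        m.strand == "forward" and m.permuted and m.species_ids == {"spX"}
        for m in matches
    )
    # the shard of the read window's own prefix has nothing stored there
    reader_shard = index.shard_for(read)
    assert reader_shard is not owner


def test_exact_beats_permuted_within_a_window():
    """A window matching species X exactly and species Y at distance 1
    reports X unpermuted and Y permuted."""
    rng = random.Random(7)
    kmer = "".join(rng.choices("ACGT", k=30))
    variant = list(kmer)
    variant[15] = next(b for b in "ACGT" if b != kmer[15])
    tax = TaxonomyTable(
        {
            "rX": TaxonAssignment.from_lineage("spX", "gX", "c"),
            "rY": TaxonAssignment.from_lineage("spY", "gY", "c"),
        }
    )
    index = build_index(
        [("rX", kmer), ("rY", "".join(variant))], tax
    )
    result = search_reads(
        index, [("read1", kmer)],
        SearchConfig(mode="permuted", params=index.params),
    )
    events = matchset_events(result["read1"])
    assert events[(0, "forward", "spX")] is False
    assert events[(0, "forward", "spY")] is True


def test_search_shard_rejects_incompatible_geometry(index5):
    config = SearchConfig(params=IndexParams(k=20, prefix_len=4))
    populated = next(s for s in index5.shards if len(s))
    with pytest.raises(IndexCompatibilityError):
        search_shard([("r", "A" * 30)], populated, config)


# -- reduce ------------------------------------------------------------------


def test_reduce_concatenates_and_is_order_independent():
    m1 = [WindowMatch("r", 0, "forward", False, frozenset({"spA"}))]
    m2 = [WindowMatch("r", 30, "forward", False, frozenset({"spB"}))]
    ab = reduce_matches([m1, m2], ["r"])
    ba = reduce_matches([m2, m1], ["r"])
    assert ab == ba
    assert len(ab["r"].matches) == 2


def test_reduce_deduplicates_and_prefers_exact():
    exact = [WindowMatch("r", 0, "forward", False, frozenset({"spA"}))]
    perm = [WindowMatch("r", 0, "forward", True, frozenset({"spA", "spB"}))]
    merged = reduce_matches([exact, perm], ["r"])["r"]
    events = matchset_events(merged)
    assert events == {
        (0, "forward", "spA"): False,
        (0, "forward", "spB"): True,
    }


def test_reduce_keeps_matchless_reads_and_rejects_duplicates():
    out = reduce_matches([[]], ["r1", "r2"])
    assert set(out) == {"r1", "r2"}
    assert out["r1"].matches == []
    with pytest.raises(SearchInputError):
        reduce_matches([[]], ["r1", "r1"])


# -- map-reduce vs oracle ----------------------------------------------------


@pytest.mark.parametrize("mode", ["exact", "permuted"])
def test_full_map_reduce_equals_shard_loop_and_oracle(
    community5, index5, reads_noisy, mode
):
    reads = reads_noisy.as_pairs()[:120]
    config = SearchConfig(mode=mode, params=index5.params)
    driver = search_reads(index5, reads, config)

    enc = EncodedReads(reads, index5.params)
    partials = [
        search_shard(enc, shard, config) for shard in index5.shards
    ]
    scanned = {rid: int(n) for rid, n in zip(enc.read_ids, enc.windows_scanned)}
    looped = reduce_matches(partials, enc.read_ids, scanned)
    assert looped == driver

    db = naive_db(community5.records, community5.taxonomy)
    expected = oracle_events(reads, db, mode=mode, triple_loop=True)
    got = {rid: matchset_events(ms) for rid, ms in driver.items()}
    assert got == expected


def test_shard_order_and_workers_do_not_change_results(index5, reads_noisy):
    reads = reads_noisy.as_pairs()[:100]
    config1 = SearchConfig(mode="permuted", workers=1, params=index5.params)
    base = search_reads(index5, reads, config1)
    order = list(range(256))
    random.Random(13).shuffle(order)
    for workers in (4, 16):
        cfg = SearchConfig(
            mode="permuted", workers=workers, params=index5.params
        )
        assert search_reads(index5, reads, cfg, shard_order=order) == base


def test_permuted_matches_are_superset_of_exact(index5, reads_noisy):
    reads = reads_noisy.as_pairs()[:200]
    exact = search_reads(
        index5, reads, SearchConfig(mode="exact", params=index5.params)
    )
    permuted = search_reads(
        index5, reads, SearchConfig(mode="permuted", params=index5.params)
    )
    for rid in exact:
        exact_ev = set(matchset_events(exact[rid]))
        perm_ev = set(matchset_events(permuted[rid]))
        assert exact_ev <= perm_ev


def test_strand_symmetry_of_matched_species(index5, reads_clean):
    """Reverse-complementing every read leaves its matched species
    multiset unchanged (offsets and strands flip)."""
    reads = reads_clean.as_pairs()[:60]
    flipped = [(rid, reverse_complement(seq)) for rid, seq in reads]
    config = SearchConfig(mode="exact", params=index5.params)
    fwd = search_reads(index5, reads, config)
    rev = search_reads(index5, flipped, config)
    for rid in fwd:
        assert sorted(
            sp for _, _, sp in fwd[rid].species_events()
        ) == sorted(sp for _, _, sp in rev[rid].species_events())


def test_windows_with_n_never_match(index5, community5):
    genome = community5.records[0][1]
    read = genome[:50] + "N" + genome[51:100]
    result = search_reads(
        index5, [("readN", read)],
        SearchConfig(mode="permuted", params=index5.params),
    )
    for offset, strand, _ in result["readN"].species_events():
        # windows overlapping position 50 (forward) / 49 (reverse) are gone
        n_pos = 50 if strand == "forward" else 49
        assert not (offset <= n_pos <= offset + 29)


def test_config_index_params_mismatch_raises(index5):
    with pytest.raises(IndexCompatibilityError):
        search_reads(
            index5, [("r", "A" * 40)],
            SearchConfig(params=IndexParams(k=20)),
        )


def test_duplicate_read_ids_rejected(index5):
    with pytest.raises(SearchInputError):
        search_reads(index5, [("r", "A" * 40), ("r", "C" * 40)])
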