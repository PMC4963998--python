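# Methods

## The classification model

`smartmeta` performs taxonomic classification by *complete* exact k-mer
matching: every 30-mer of every reference is kept, mapped to the full set of
species containing it.  Nothing is collapsed to a lowest common ancestor and
no discriminative-k-mer filtering is applied; ambiguity is resolved at read
level by voting rather than at database level by pruning.  The trade-off is
a much larger database, which the prefix sharding makes tractable: the
database partitions into 4^4 = 256 independent hashtables, any subset of
which can be loaded and searched in parallel.

### Database construction

References are tiled **non-overlapping** (step = k = 30, offsets 0, 30, 60,
...; the trailing remainder is discarded).  Each FASTA record is tiled
independently from offset 0, forward strand only.  Tiles containing a
non-ACGT character after uppercasing are skipped — skipping is the
conservative choice that keeps the 2-bit base encoding total; lowercase
soft-masking is uppercased rather than discarded.  Every (30-mer, species)
pair is routed to the shard addressed by the integer encoding of its first
4 bases and stored under its 26-base suffix; species sets are deduplicated
and sorted.  Construction is an in-memory sort with sorted-merge semantics,
so the result — and its serialization — is independent of reference input
order (the order-independence is asserted byte-for-byte in the tests).
An out-of-core merge for larger-than-memory reference sets is out of scope.

The on-disk format is one JSON manifest (parameters, per-shard entry counts
and sha256 checksums, taxonomy digest), the taxonomy TSV, and one text file
per shard holding sorted `suffix<TAB>species...` lines.  Each shard file is
self-contained, so a single shard can be loaded and verified alone.

### Search

Each read is scanned on two strands: the read as given, and its reverse
complement, each left-to-right with its own 0-based window offsets.  This
is equivalent to querying each window's reverse complement and keeps the
strand-symmetry property exact: reverse-complementing every input read
permutes offsets/strands but leaves each read's matched species multiset
unchanged (a tested invariant).  Windows step by 1; windows containing a
non-ACGT base are skipped and can never match.

In permuted mode every window additionally queries its 3k = 90 Hamming-1
substitution variants.  Variants are routed to the shard owning the
*mutated* prefix: a shard answers every query whose (possibly mutated)
first 4 bases equal its own, including variants of windows that originally
belonged elsewhere.  Fixing the prefix instead would silently drop
3·4/90 ≈ 13% of the variant space.  Permuted mode always performs the
exact query as well; within a window, matches are deduplicated per species
and exact evidence beats permuted evidence, so a species hit by many
variants still contributes a single vote per window.  Insertions and
deletions are deliberately outside the error model.

Two execution paths exist and are tested for equality: `search_shard`, the
literal per-shard program, and the `search_reads` driver, which 2-bit packs
all windows into uint64s (a substitution is an XOR with a 2-bit mask),
sorts queries by owning prefix, and resolves each shard's contiguous slice
with a vectorized binary search over that shard's sorted keys.  Worker
count and shard processing order cannot affect results; both invariances
are asserted, as is event-level equality with a brute-force flat-dictionary
scanner on 10,000-read fixtures.

### Classification

One vote per deduplicated (window, strand, species) event at species level;
genus and class tallies are derived by lineage summation through the
taxonomy table rather than tallied from separately stored genus/class
links — with a single-lineage taxonomy the two are equivalent, and the
derivation avoids a redundant store.  Exact and permuted matches carry
equal weight.  Per level the verdict is the unique argmax, `AMBIGUOUS` on a
tie (evaluated independently per level: a species-level tie between two
congeneric species still yields a unique genus), and `UNMATCHED` with no
events.

The mammalian override is unconditional: any matched species whose class is
the configured mammalian label (default `"Mammalia"`) makes the read's
final category MAMMALIAN, even when non-mammalian species out-vote it and
even when the species tally is tied.  Sample reports partition reads by the
precedence MAMMALIAN > UNMATCHED > AMBIGUOUS (species-level tie) >
NON_MAMMALIAN; per-level verdict columns are exposed in the per-read TSV so
other conventions can be recomputed.  Per-genus read counts run over reads
with a unique genus verdict; optional normalization divides them by host
mean depth of coverage, depth = host reads × read length / host genome
length (summed bases would replace the product for variable-length reads).
Zero depth refuses normalization explicitly instead of dividing by zero.

### Evaluation

Sensitivity = correct classifications / total reads; precision = correct
classifications / reads attempted, where *attempted* means a unique taxon
verdict at the level scored (ambiguous and unmatched reads stay in the
sensitivity denominator only — the reading under which precision can exceed
sensitivity; the alternative, counting ambiguous reads as attempted and
incorrect, is available behind a flag).  Correctness is exact-at-level
against the truth lineage.  Confidence intervals are Wilson score at 95%.
Host (truth-mammalian) and microbial reads are also scored separately so
host reads do not dilute microbial metrics.

## The simulator and what it does (not) emulate

Genomes are i.i.d. uniform ACGT.  At k = 30 the chance that two random
multi-kilobase genomes share any 30-mer is ~L²/4^30 ≈ 10⁻¹¹, so
unique/shared k-mer structure is entirely by construction:
`shared_fraction` copies an identical tile-aligned block between designated
species pairs (creating genuinely multi-species k-mers), and
`host_fraction` adds a genome carrying a `Homo / Mammalia` lineage and
draws that fraction of reads from it.  Reads take uniform start offsets, a
random strand, and i.i.d. substitutions (each error flips to one of the
three other bases); truth (source species, offset, strand, substitution
count) is encoded in the read name and, authoritatively, in a sidecar TSV.

What this does **not** emulate: real genome composition and repeat
structure, shared ancestry between related taxa, platform error profiles,
indels, chimeras, and non-uniform abundance.  Passing tests therefore
demonstrate the correctness of the machinery — tiling, sharding, 1-edit
search, voting, override, metric arithmetic — not classification accuracy
on real communities, which is dominated by reference completeness and
database representation bias.

## Default study conditions and problem sizes

The standard fixture is 5 species × 3,000 bp (seed 1) with 10,000 reads of
100 bp — small enough that an independent brute-force scanner can
re-derive every match event for comparison, large enough that every code
path (multi-tile reads, both strands, prefix-crossing variants, ties) is
exercised; the host fixture uses `host_fraction = 0.5` and a 1%
substitution rate, at which most reads carry 1–3 errors so the permutation
benefit is visible (≈5% additional reads classified) without swamping the
exact path.  Defaults of k = 30 and prefix_len = 4 give 256 shards; k ≤ 32
is required by the 64-bit packing.

## Numerical and degenerate-input choices

* Base encoding A=0, C=1, G=2, T=3, most-significant first; lexicographic
  string order equals numeric order, which makes serialized shards
  canonical and diffable.
* Ties report `AMBIGUOUS` rather than breaking by label order; no
  tie-break is ever silent.
* Empty reference sets, references absent from the taxonomy, wrong-length
  or non-ACGT queries, conflicting duplicate taxonomy rows, and
  truth/classification universe mismatches all raise typed errors rather
  than degrading.
* Reads shorter than k yield zero windows and classify as UNMATCHED.
* Precision with zero attempted reads is reported as null, not 0.

## Known limitations

Single-lineage three-rank taxonomy only (no tree, no LCA); edit distance
is capped at 1 substitution; paired ends are treated as independent reads;
the in-memory builder bounds reference size by available RAM; quality
values are ignored (trim upstream).
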