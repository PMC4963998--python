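# smartmeta

A sharded exact-match 30-mer classifier for shotgun metagenomic reads.

Shotgun sequencing of host-derived samples (gut, ocular surface, skin, ...)
yields millions of short reads from an unknown mixture of microbes and host.
`smartmeta` assigns each read a species, genus and class by exact k-mer
matching against a taxonomically labeled reference set, with two ideas doing
the heavy lifting:

* **A 256-way prefix-sharded database.** References are cut into
  *non-overlapping* 30-mers; each 30-mer is routed to the shard addressed by
  its first 4 bases (A=0, C=1, G=2, T=3, most-significant first) and stored
  in that shard's hashtable under its remaining 26 bases, mapped to the set
  of species containing it.  Because a 30-mer's shard is deterministic, the
  search runs as 256 independent programs (map) whose results are merged per
  read (reduce), and a single shard can be loaded without the other 255 —
  memory is bounded by one shard plus one read batch.
* **Vote tallying with a conservative host override.** Each read is scanned
  on both strands with a step-1 sliding 30-mer window; every successful
  lookup contributes one vote per (window, strand, species).  Genus and
  class votes are the lineage sums of species votes.  Per level the verdict
  is the unique argmax, `AMBIGUOUS` on a tie, `UNMATCHED` with no votes at
  all — and a read with even **one** mammalian match is categorized as host,
  regardless of the tallies, which suppresses false microbial calls from
  host-rich samples.

In *permuted* mode the search additionally queries all 3·k = 90 single-base
substitution variants of every window (no indels), absorbing one SNP or
sequencing error per window; variants whose substitution falls inside the
4-bp prefix are answered by the shard owning the *mutated* prefix, so the
sharded search is exactly equivalent to a global 1-edit search.

A bundled simulator generates random reference communities, an optional
mammalian host genome, and substitution-bearing reads with known truth
labels, so the whole pipeline is testable with no downloads.

## Worked example

Simulate a 5-species community plus a mammalian host contributing 30% of
reads, build the index, search with 1-bp permutations, and score against
the truth labels:

```sh
smart simulate --n-species 5 --genome-length 3000 --n-reads 2000 \
    --read-length 100 --sub-rate 0.01 --host-fraction 0.3 --seed 1 --out sim
smart build --refs sim/refs.fa --tax sim/tax.tsv --out index
smart search --index index --reads sim/reads.fq --mode permuted \
    --workers 4 --out matches.tsv
smart report --matches matches.tsv --tax sim/tax.tsv --out report \
    --normalize-host-genus Homo --host-genome-length 3000 --read-length 100
smart eval --per-read report/per_read.tsv --truth sim/truth.tsv \
    --tax sim/tax.tsv --out metrics.json
```

which prints:

```
wrote 6 genomes and 2000 reads to sim
indexed 600 distinct 30-mers (600 k-mer/species pairs) into 256 shards at index
1999/2000 reads matched (permuted mode); matches written to matches.tsv
reads: mammalian=580, non_mammalian=1419, ambiguous=0, unmatched=1; reports written to report
species-level sensitivity=0.9995 precision=1.0000; metrics written to metrics.json
```

Reading the numbers: the six 3 kb genomes tile into 600 distinct 30-mers
(none shared, so 600 k-mer/species pairs).  Of 2,000 reads, 580 carried at
least one match to the host genome and were categorized mammalian by the
override rule; 1,419 received a unique non-mammalian species verdict; one
read's errors broke every window beyond one substitution, leaving it
unmatched.  Sensitivity (correct / all reads) is 1999/2000 and precision
(correct / reads given a unique verdict) is 1.0.  `report/report.json` also
holds per-genus read counts normalized by host depth of coverage
(host reads x read length / host genome length), the standard way to compare
samples of different sequencing depth.

The same pipeline is available as library calls (`simulate_community`,
`build_index`, `search_reads`, `classify_sample`, `evaluate`, ...); see the
module docstrings and `docs/methods.md`.

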