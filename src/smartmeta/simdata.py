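"""Synthetic communities and reads with known truth labels.

The simulator makes the whole pipeline testable offline.  Genomes are
i.i.d. uniform ACGT: at 30-mer scale two random multi-kilobase genomes
share a k-mer with probability ~ L^2 / 4^30, i.e. essentially never, so
unique/shared k-mer structure is controlled entirely by construction —
``shared_fraction`` copies an identical tile-aligned block between
designated species pairs to create genuinely ambiguous k-mers, and
``host_fraction`` adds one genome labeled with the mammalian class and
draws that fraction of reads from it.

Reads carry i.i.d. substitution errors only (no indels), matching what the
1-bp permutation search is designed to absorb.  Truth (source species,
offset, strand, number of substitutions) is encoded in each read name and,
authoritatively, in a sidecar TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SimulationError
from .io import write_fasta, write_fastq
from .taxonomy import (
    DEFAULT_MAMMALIAN_CLASS,
    TaxonAssignment,
    TaxonomyTable,
)

__all__ = [
    "CommunityParams",
    "Community",
    "SimulatedRead",
    "SimulatedReadSet",
    "simulate_community",
    "simulate_reads",
    "simulate_to_dir",
    "write_truth_tsv",
    "load_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MICROBIAL_CLASS = "Microbia"
HOST_RECORD_ID = "host_ref"
HOST_SPECIES = "Homo sapiens"
HOST_GENUS = "Homo"


@dataclass(frozen=True)
class CommunityParams:
    """Study conditions for one synthetic community.

    n_species : number of microbial genomes (each its own species/genus).
    genome_length : bases per genome.
    shared_fraction : fraction of each genome copied identically between
        consecutive species pairs (1&2, 3&4, ...) to create non-unique
        k-mers; blocks are tile-aligned so shared 30-mers are exact.
    host_fraction : fraction of reads drawn from an extra mammalian-class
        host genome (the genome exists iff this is > 0).
    seed : RNG seed; same seed -> byte-identical outputs.
    """

    n_species: int = 5
    genome_length: int = 3000
    shared_fraction: float = 0.0
    host_fraction: float = 0.0
    seed: int = 0
    k: int = 30
    mammalian_class: str = DEFAULT_MAMMALIAN_CLASS

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise SimulationError("n_species must be >= 1")
        if self.genome_length < self.k:
            raise SimulationError("genome_length must be >= k")
        if not 0 <= self.shared_fraction < 1:
            raise SimulationError("shared_fraction must be in [0, 1)")
        if not 0 <= self.host_fraction <= 1:
            raise SimulationError("host_fraction must be in [0, 1]")


@dataclass
class Community:
    """Reference records plus their taxonomy."""

    params: CommunityParams
    records: list[tuple[str, str]]
    taxonomy: TaxonomyTable

    @property
    def has_host(self) -> bool:
        return any(rid == HOST_RECORD_ID for rid, _ in self.records)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    species: str
    record_id: str
    offset: int
    strand: str
    n_substitutions: int


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead] = field(default_factory=list)

    def as_pairs(self) -> list[tuple[str, str]]:
        return [(r.read_id, r.sequence) for r in self.reads]

    def truth_rows(self) -> list[tuple[str, str, int, str, int]]:
        return [
            (r.read_id, r.species, r.offset, r.strand, r.n_substitutions)
            for r in self.reads
        ]


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate_community(params: CommunityParams) -> Community:
    """Generate genomes and the matching taxonomy table.

    Microbial species are named sp01, sp02, ... each in its own genus
    (gen01, ...) under a common microbial class; the optional host genome
    carries a Homo/Mammalia lineage so the override rule is exercised.
    """
    rng = np.random.default_rng(params.seed)
    records: list[tuple[str, str]] = []
    entries: dict[str, TaxonAssignment] = {}
    genomes = [
        _random_genome(rng, params.genome_length)
        for _ in range(params.n_species)
    ]
    if params.shared_fraction > 0:
        k = params.k
        block = (
            int(params.shared_fraction * params.genome_length) // k
        ) * k
        if block >= k:
            # copy a tile-aligned block from each odd genome into its pair
            for a in range(0, params.n_species - 1, 2):
                b = a + 1
                start = 0
                genomes[b] = (
                    genomes[b][:start]
                    + genomes[a][start : start + block]
                    + genomes[b][start + block :]
                )
    for i, genome in enumerate(genomes, start=1):
        rid = f"ref{i:02d}"
        records.append((rid, genome))
        entries[rid] = TaxonAssignment.from_lineage(
            f"sp{i:02d}",
            f"gen{i:02d}",
            MICROBIAL_CLASS,
            params.mammalian_class,
        )
    if params.host_fraction > 0:
        records.append(
            (HOST_RECORD_ID, _random_genome(rng, params.genome_length))
        )
        entries[HOST_RECORD_ID] = TaxonAssignment.from_lineage(
            HOST_SPECIES,
            HOST_GENUS,
            params.mammalian_class,
            params.mammalian_class,
        )
    return Community(params, records, TaxonomyTable(entries))


def simulate_reads(
    community: Community,
    n_reads: int,
    read_length: int = 100,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> SimulatedReadSet:
    """Draw reads with i.i.d. substitution errors and record the truth.

    Reads come uniformly from the microbial genomes, except that with
    probability ``host_fraction`` a read comes from the host genome; each
    read takes a uniform start offset and a random strand.  Substitutions
    flip a base to one of the three alternatives, independently per base.
    """
    params = community.params
    if read_length < params.k:
        raise SimulationError("read_length must be >= k")
    if any(len(seq) < read_length for _, seq in community.records):
        raise SimulationError("read_length exceeds a genome length")
    if not 0 <= substitution_rate <= 1:
        raise SimulationError("substitution_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    microbial = [
        (rid, seq) for rid, seq in community.records if rid != HOST_RECORD_ID
    ]
    host = [
        (rid, seq) for rid, seq in community.records if rid == HOST_RECORD_ID
    ]
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        if host and rng.random() < params.host_fraction:
            rid, genome = host[0]
        else:
            rid, genome = microbial[rng.integers(0, len(microbial))]
        species = community.taxonomy.lineage_of(rid).species_id
        offset = int(rng.integers(0, len(genome) - read_length + 1))
        fragment = genome[offset : offset + read_length]
        strand = "forward" if rng.random() < 0.5 else "reverse"
        if strand == "reverse":
            from .search import reverse_complement

            fragment = reverse_complement(fragment)
        codes = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
        hit = np.nonzero(rng.random(read_length) < substitution_rate)[0]
        for pos in hit:
            current = codes[pos]
            alternatives = _BASES[_BASES != current]
            codes[pos] = alternatives[rng.integers(0, 3)]
        sequence = codes.tobytes().decode()
        n_subs = int(len(hit))
        # ids must survive FASTQ round trips, so no whitespace
        safe_species = species.replace(" ", "_")
        read_id = f"r{i:06d}:{safe_species}:{offset}:{strand}:{n_subs}"
        reads.append(
            SimulatedRead(
                read_id=read_id,
                sequence=sequence,
                species=species,
                record_id=rid,
                offset=offset,
                strand=strand,
                n_substitutions=n_subs,
            )
        )
    return SimulatedReadSet(reads)


def write_truth_tsv(read_set: SimulatedReadSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#read_id\tspecies\toffset\tstrand\tn_substitutions\n")
        for row in read_set.truth_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")


def load_truth_tsv(path: str | Path) -> dict[str, dict]:
    """read_id -> {species, offset, strand, n_substitutions}."""
    out: dict[str, dict] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, species, offset, strand, nsub = line.split("\t")
            out[read_id] = {
                "species": species,
                "offset": int(offset),
                "strand": strand,
                "n_substitutions": int(nsub),
            }
    return out


def simulate_to_dir(
    outdir: str | Path,
    params: CommunityParams,
    n_reads: int,
    read_length: int = 100,
    substitution_rate: float = 0.0,
    read_seed: int | None = None,
) -> tuple[Community, SimulatedReadSet]:
    """Write refs.fa, tax.tsv, reads.fq and truth.tsv into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = simulate_community(params)
    read_set = simulate_reads(
        community,
        n_reads,
        read_length=read_length,
        substitution_rate=substitution_rate,
        seed=params.seed if read_seed is None else read_seed,
    )
    write_fasta(community.records, outdir / "refs.fa")
    (outdir / "tax.tsv").write_text(community.taxonomy.to_tsv())
    write_fastq(read_set.as_pairs(), outdir / "reads.fq")
    write_truth_tsv(read_set, outdir / "truth.tsv")
    return community, read_set
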