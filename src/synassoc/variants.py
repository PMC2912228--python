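"""SNP tables, genotype simulation, and spectrum-preserving mutagenesis.

A genome is held as a mapping of contig id to an upper-case nucleotide
string; all coordinates are 0-based half-open internally and converted to
1-based inclusive only at file boundaries.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"

#: The 12 ordered substitution types, lexicographic by (ref, alt).
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in NUCLEOTIDES for b in NUCLEOTIDES if a != b
)


@dataclass(frozen=True, order=True)
class SnpRecord:
    """One biallelic substitution between the reference and alternate strain.

    ``pos`` is a 0-based offset into ``contig``; the TSV dialect on disk is
    1-based and converted at I/O time.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"non-ACGT allele at {self.contig}:{self.pos + 1}: "
                f"{self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError(
                f"ref equals alt at {self.contig}:{self.pos + 1}: {self.ref}"
            )


@dataclass
class GenotypeMatrix:
    """Binary genotypes for a simulated population plus the two endpoints.

    Row ``i`` of ``matrix`` is the genotype vector of ``genome_ids[i]`` over
    the SNP index: 0 = reference allele, 1 = alternate allele.  The first two
    rows are always the endpoints: the all-0 reference genome and the all-1
    all-alternate genome; the remaining rows are the N intermediates.
    """

    genome_ids: list[str]
    matrix: np.ndarray  # shape (N + 2, n_snps), dtype uint8
    seed: int | None = None

    REFERENCE_ID = "reference"
    ALL_ALT_ID = "all_alt"

    @property
    def n_intermediates(self) -> int:
        return len(self.genome_ids) - 2

    @property
    def intermediate_ids(self) -> list[str]:
        return self.genome_ids[2:]

    def vector(self, genome_id: str) -> np.ndarray:
        return self.matrix[self.genome_ids.index(genome_id)]


@dataclass
class MutationSpectrum:
    """Counts of each substitution type plus eligible-base counts.

    ``substitutions`` maps each of the 12 ordered (ref, alt) pairs to a
    count; ``eligible`` maps each nucleotide to the number of genome
    positions of that base available for mutation (positions passing the
    coverage mask).
    """

    substitutions: dict[tuple[str, str], int] = field(default_factory=dict)
    eligible: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in SUBSTITUTION_TYPES:
            self.substitutions.setdefault(key, 0)
        for base in NUCLEOTIDES:
            self.eligible.setdefault(base, 0)

    @property
    def total(self) -> int:
        return sum(self.substitutions.values())

    def source_totals(self) -> dict[str, int]:
        out = {b: 0 for b in NUCLEOTIDES}
        for (ref, _), n in self.substitutions.items():
            out[ref] += n
        return out


# ---------------------------------------------------------------------------
# FASTA helpers

def read_fasta(path) -> dict[str, str]:
    """Load a multi-contig FASTA as an ordered {contig: sequence} dict."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path, line_width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=line_width)
    writer.write_file(records)


# ---------------------------------------------------------------------------
# SNP table I/O

def read_snp_table(path, genome: Mapping[str, str]) -> list[SnpRecord]:
    """Read a SNP TSV (contig, pos 1-based, ref, alt) validated against *genome*.

    Returns records sorted by (contig, pos).  Any reference-allele mismatch,
    duplicate position, unknown contig, out-of-range position or non-ACGT
    allele is a hard error naming the offending site.
    """
    records: list[SnpRecord] = []
    seen: set[tuple[str, int]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"contig", "pos", "ref", "alt"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: SNP table must have header columns {sorted(required)}"
            )
        for row in reader:
            contig = row["contig"]
            pos = int(row["pos"]) - 1
            rec = SnpRecord(contig, pos, row["ref"].upper(), row["alt"].upper())
            if contig not in genome:
                raise ValueError(f"{path}: unknown contig {contig!r}")
            if not 0 <= pos < len(genome[contig]):
                raise ValueError(
                    f"{path}: position {pos + 1} outside contig {contig} "
                    f"(length {len(genome[contig])})"
                )
            if genome[contig][pos] != rec.ref:
                raise ValueError(
                    f"{path}: reference allele mismatch at {contig}:{pos + 1}: "
                    f"table says {rec.ref}, genome has {genome[contig][pos]}"
                )
            if (contig, pos) in seen:
                raise ValueError(f"{path}: duplicate SNP at {contig}:{pos + 1}")
            seen.add((contig, pos))
            records.append(rec)
    records.sort()
    return records


def write_snp_table(snps: Sequence[SnpRecord], path) -> None:
    """Write SNPs in the 1-based TSV dialect read by :func:`read_snp_table`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["contig", "pos", "ref", "alt"])
        for s in sorted(snps):
            writer.writerow([s.contig, s.pos + 1, s.ref, s.alt])


# ---------------------------------------------------------------------------
# Genotype realization and simulation

def apply_genotype(
    genome: Mapping[str, str],
    snps: Sequence[SnpRecord],
    genotype_vector: Sequence[int] | np.ndarray,
) -> dict[str, str]:
    """Realize one artificial genome from a genotype vector.

    Positions where the vector is 1 carry the alternate allele, all other
    positions the reference.  Contig names, order and lengths are preserved.
    """
    vec = np.asarray(genotype_vector)
    if vec.shape != (len(snps),):
        raise ValueError(
            f"genotype vector length {vec.shape} does not match SNP count {len(snps)}"
        )
    out = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    for snp, allele in zip(snps, vec):
        if allele:
            out[snp.contig][snp.pos] = ord(snp.alt)
    return {name: buf.decode("ascii") for name, buf in out.items()}


def sample_genotypes(n_genomes: int, n_snps: int, seed: int) -> GenotypeMatrix:
    """Simulate *n_genomes* intermediates with independent fair-coin alleles.

    Each SNP allele is drawn independently with probability 1/2, so there is
    no linkage between sites.  The two endpoint genomes (all-reference,
    all-alternate) are prepended so downstream code always sees N + 2 rows.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    inter = rng.integers(0, 2, size=(n_genomes, n_snps), dtype=np.uint8)
    endpoints = np.vstack(
        [np.zeros(n_snps, dtype=np.uint8), np.ones(n_snps, dtype=np.uint8)]
    )
    ids = [GenotypeMatrix.REFERENCE_ID, GenotypeMatrix.ALL_ALT_ID] + [
        f"intermediate_{i:04d}" for i in range(n_genomes)
    ]
    return GenotypeMatrix(ids, np.vstack([endpoints, inter]), seed=seed)


# ---------------------------------------------------------------------------
# Mutation spectrum and randomized mutagenesis

def compute_mutation_spectrum(
    snps: Sequence[SnpRecord],
    genome: Mapping[str, str],
    coverage_mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> MutationSpectrum:
    """Tally the 12 substitution types and the eligible-base composition.

    *coverage_mask* maps contig to 0-based half-open intervals of positions
    eligible for mutation (e.g. adequately covered by reads); by default the
    whole genome is eligible.
    """
    spectrum = MutationSpectrum()
    for snp in snps:
        spectrum.substitutions[(snp.ref, snp.alt)] += 1
    for contig, seq in genome.items():
        if coverage_mask is None:
            regions = [(0, len(seq))]
        else:
            regions = list(coverage_mask.get(contig, []))
        for start, stop in regions:
            for base in NUCLEOTIDES:
                spectrum.eligible[base] += seq.count(base, start, stop)
    return spectrum


def randomize_mutations(
    genome: Mapping[str, str],
    spectrum: MutationSpectrum,
    seed: int,
    coverage_mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> tuple[dict[str, str], list[SnpRecord]]:
    """Place the spectrum's substitutions at random genome positions.

    A single left-to-right pass over the eligible bases: at each base of
    nucleotide X the probability of mutating to Y is the number of X->Y
    substitutions still to place divided by the number of eligible X bases
    not yet passed.  This sequential scheme places exactly the spectrum's
    counts (the probability reaches 1 when the remaining bases are exactly
    the remaining mutations) and every eligible X position is equally likely
    to receive any given X->Y mutation.  A base is mutated at most once.
    """
    remaining_eligible = dict(spectrum.eligible)
    needed = spectrum.source_totals()
    for base in NUCLEOTIDES:
        if needed[base] > remaining_eligible[base]:
            raise ValueError(
                f"infeasible spectrum: {needed[base]} mutations from {base} "
                f"but only {remaining_eligible[base]} eligible {base} bases"
            )
    remaining = {k: v for k, v in spectrum.substitutions.items()}
    rng = np.random.default_rng(seed)

    mutated: dict[str, str] = {}
    placed: list[SnpRecord] = []
    targets = {b: [t for (s, t) in SUBSTITUTION_TYPES if s == b] for b in NUCLEOTIDES}
    for contig, seq in genome.items():
        if coverage_mask is None:
            regions = [(0, len(seq))]
        else:
            regions = list(coverage_mask.get(contig, []))
        buf = bytearray(seq, "ascii")
        for start, stop in regions:
            for pos in range(start, stop):
                base = seq[pos]
                if base not in NUCLEOTIDES:
                    continue
                total_needed = sum(remaining[(base, t)] for t in targets[base])
                if total_needed:
                    u = rng.random() * remaining_eligible[base]
                    acc = 0
                    for t in targets[base]:
                        acc += remaining[(base, t)]
                        if u < acc:
                            buf[pos] = ord(t)
                            remaining[(base, t)] -= 1
                            placed.append(SnpRecord(contig, pos, base, t))
                            break
                remaining_eligible[base] -= 1
        mutated[contig] = buf.decode("ascii")
    assert all(v == 0 for v in remaining.values()), "spectrum under-placed"
    placed.sort()
    return mutated, placed


# ---------------------------------------------------------------------------
# BED mask I/O (0-based half-open)

def read_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file of eligible intervals into {contig: [(start, stop)]}."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, stop = fields[0], int(fields[1]), int(fields[2])
            mask.setdefault(contig, []).append((start, stop))
    for intervals in mask.values():
        intervals.sort()
    return mask
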