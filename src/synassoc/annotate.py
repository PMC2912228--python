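"""Gene prediction: exon models, ZFF/GFF3 I/O, and a built-in toy annotator.

The analysis treats a gene predictor as a black box mapping genome sequence
to a set of typed exons.  An exon's identity is exactly the 5-tuple
(contig, exon type, start, stop, strand); two exons are the same model iff
all five fields match.  Scores are carried through for reporting but never
consulted by any downstream logic.

The toy annotator is a deterministic, purely local gene caller — greedy
GT..AG intron selection followed by longest-ORF calling on the spliced
sequence — designed to react to point changes in start, stop and splice
motifs the same qualitative ways an HMM gene finder does, while remaining
trivially auditable.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

EXON_TYPES = ("initial", "internal", "terminal", "single")

_ZFF_LABELS = {
    "Einit": "initial",
    "Exon": "internal",
    "Eterm": "terminal",
    "Esngl": "single",
}
_ZFF_LABELS_INV = {v: k for k, v in _ZFF_LABELS.items()}

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class ExonModel:
    """A predictor's atomic output; equality is on the five identity fields."""

    contig: str
    exon_type: str
    start: int  # 0-based
    stop: int   # half-open
    strand: str
    score: float | None = field(default=None, compare=False)
    gene_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.exon_type not in EXON_TYPES:
            raise ValueError(f"unknown exon type {self.exon_type!r}")
        if not self.start < self.stop:
            raise ValueError(f"empty exon interval [{self.start}, {self.stop})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, str, int, int, str]:
        return (self.contig, self.exon_type, self.start, self.stop, self.strand)


@dataclass
class GeneModel:
    """Ordered exons of one gene on one contig and strand."""

    gene_id: str
    contig: str
    strand: str
    exons: list[ExonModel]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.stop:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or touch at {a.stop}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0].start, self.exons[-1].stop)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a.stop, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


def group_genes(exons: Iterable[ExonModel]) -> list[GeneModel]:
    """Assemble GeneModels from exons sharing a gene_id (orphans get their own)."""
    by_gene: dict[str, list[ExonModel]] = {}
    orphans: list[ExonModel] = []
    for e in exons:
        if e.gene_id is None:
            orphans.append(e)
        else:
            by_gene.setdefault(e.gene_id, []).append(e)
    genes = [
        GeneModel(gid, members[0].contig, members[0].strand, members)
        for gid, members in by_gene.items()
    ]
    for i, e in enumerate(orphans):
        genes.append(GeneModel(f"orphan_{i}", e.contig, e.strand, [e]))
    genes.sort(key=lambda g: (g.contig, g.span))
    return genes


# ---------------------------------------------------------------------------
# ZFF (SNAP dialect)

def parse_zff(path) -> list[ExonModel]:
    """Parse SNAP-style ZFF: '>contig' headers then typed exon rows.

    Row layout: label, begin, end, then optionally a score and/or a group
    label.  begin > end encodes the minus strand; coordinates are 1-based
    inclusive and normalized to 0-based half-open with start < stop.
    """
    exons: list[ExonModel] = []
    contig: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                contig = line[1:].split()[0]
                continue
            if contig is None:
                raise ValueError(f"{path}:{lineno}: exon row before any '>contig'")
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}")
            label = fields[0]
            if label not in _ZFF_LABELS:
                warnings.warn(f"{path}:{lineno}: unknown ZFF label {label!r}, skipped")
                continue
            try:
                begin, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            score: float | None = None
            gene_id: str | None = None
            for extra in fields[3:]:
                try:
                    score = float(extra)
                except ValueError:
                    gene_id = extra
            if begin <= end:
                start, stop, strand = begin - 1, end, "+"
            else:
                start, stop, strand = end - 1, begin, "-"
            exons.append(
                ExonModel(contig, _ZFF_LABELS[label], start, stop, strand,
                          score=score, gene_id=gene_id)
            )
    return exons


def write_zff(exons: Sequence[ExonModel], path) -> None:
    with open(path, "w") as fh:
        by_contig: dict[str, list[ExonModel]] = {}
        for e in exons:
            by_contig.setdefault(e.contig, []).append(e)
        for contig, members in by_contig.items():
            fh.write(f">{contig}\n")
            for e in sorted(members, key=lambda x: x.start):
                if e.strand == "+":
                    begin, end = e.start + 1, e.stop
                else:
                    begin, end = e.stop, e.start + 1
                row = [_ZFF_LABELS_INV[e.exon_type], str(begin), str(end)]
                if e.score is not None:
                    row.append(f"{e.score:g}")
                if e.gene_id is not None:
                    row.append(e.gene_id)
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# GFF3

def parse_gff3(path) -> list[ExonModel]:
    """Parse GFF3 CDS/exon features grouped by Parent into typed exons.

    Exon types are inferred from position within the parent gene,
    strand-aware: the 5'-most exon of a multi-exon gene is "initial", the
    3'-most "terminal", and a lone exon "single".  CDS features are
    preferred when both CDS and exon rows are present.  An exon without a
    Parent is treated as a single-exon gene with a warning.
    """
    rows: list[tuple[str, str, int, int, str, float | None, str | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            contig, _src, ftype, start1, end1, score_s, strand, _phase, attrs = fields
            if ftype not in ("CDS", "exon"):
                continue
            score = None if score_s == "." else float(score_s)
            parent = None
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    if k == "Parent":
                        parent = v
            rows.append(
                (ftype, contig, int(start1) - 1, int(end1), strand, score, parent)
            )
    types_present = {r[0] for r in rows}
    wanted = "CDS" if "CDS" in types_present else "exon"
    groups: dict[str | None, list] = {}
    orphan_count = 0
    exons: list[ExonModel] = []
    for r in rows:
        if r[0] != wanted:
            continue
        if r[6] is None:
            warnings.warn(f"{path}: {wanted} without Parent treated as single-exon gene")
            groups[f"__orphan_{orphan_count}"] = [r]
            orphan_count += 1
        else:
            groups.setdefault(r[6], []).append(r)
    for parent, members in groups.items():
        members.sort(key=lambda r: r[2])
        n = len(members)
        strand = members[0][4]
        for i, (_t, contig, start, stop, strand_i, score, _p) in enumerate(members):
            if n == 1:
                etype = "single"
            else:
                five_prime_first = i == 0 if strand == "+" else i == n - 1
                three_prime_last = i == n - 1 if strand == "+" else i == 0
                if five_prime_first:
                    etype = "initial"
                elif three_prime_last:
                    etype = "terminal"
                else:
                    etype = "internal"
            gid = None if str(parent).startswith("__orphan_") else str(parent)
            exons.append(
                ExonModel(contig, etype, start, stop, strand_i, score=score, gene_id=gid)
            )
    return exons


def write_gff3(exons: Sequence[ExonModel], path, source: str = "synassoc") -> None:
    """Write exons as CDS features grouped by gene_id (Parent attribute).

    Exons lacking a gene_id are written under a generated singleton parent;
    exon types round-trip through :func:`parse_gff3` as long as they are
    positionally consistent within each gene.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        anon = 0
        by_gene: dict[str, list[ExonModel]] = {}
        for e in exons:
            gid = e.gene_id
            if gid is None:
                gid = f"anon_{anon}"
                anon += 1
            by_gene.setdefault(gid, []).append(e)
        for gid in sorted(by_gene, key=lambda g: (by_gene[g][0].contig,
                                                  min(e.start for e in by_gene[g]))):
            members = sorted(by_gene[gid], key=lambda e: e.start)
            for e in members:
                score = "." if e.score is None else f"{e.score:g}"
                fh.write(
                    f"{e.contig}\t{source}\tCDS\t{e.start + 1}\t{e.stop}\t"
                    f"{score}\t{e.strand}\t.\tParent={gid}\n"
                )


# ---------------------------------------------------------------------------
# Toy annotator

@dataclass(frozen=True)
class ToyParams:
    """Tunables of the toy gene caller.

    min_orf_nt: minimum spliced ORF length (start through stop codon, nt).
    min_intron / max_intron: accepted GT..AG intron length bounds, inclusive.
    """

    min_orf_nt: int = 120
    min_intron: int = 30
    max_intron: int = 200


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _find_introns(seq: str, params: ToyParams) -> list[tuple[int, int]]:
    # Greedy left-to-right: each GT pairs with the nearest downstream AG
    # giving an in-range intron; a candidate overlapping an accepted intron
    # is discarded.
    introns: list[tuple[int, int]] = []
    last_end = 0
    i = seq.find("GT")
    n = len(seq)
    while i != -1:
        if i >= last_end:
            j_lo = i + params.min_intron - 2
            j_hi = min(i + params.max_intron - 2, n - 2)
            j = seq.find("AG", j_lo, j_hi + 2) if j_lo <= j_hi else -1
            if j != -1:
                introns.append((i, j + 2))
                last_end = j + 2
        i = seq.find("GT", i + 1)
    return introns


def _splice(seq: str, introns: list[tuple[int, int]]) -> tuple[str, list[tuple[int, int, int]]]:
    # Returns spliced sequence and exonic segments as (spliced_offset,
    # oriented_start, oriented_stop).
    segments: list[tuple[int, int, int]] = []
    parts: list[str] = []
    cursor = 0
    spliced_len = 0
    for a, b in introns:
        if a > cursor:
            segments.append((spliced_len, cursor, a))
            parts.append(seq[cursor:a])
            spliced_len += a - cursor
        cursor = b
    if cursor < len(seq):
        segments.append((spliced_len, cursor, len(seq)))
        parts.append(seq[cursor:])
    return "".join(parts), segments


def _orfs(spliced: str, min_orf_nt: int) -> list[tuple[int, int]]:
    # Maximal ATG..stop ORFs per frame: the earliest ATG since the last stop
    # through the stop codon inclusive.
    found: list[tuple[int, int]] = []
    n = len(spliced)
    for frame in range(3):
        start: int | None = None
        for p in range(frame, n - 2, 3):
            codon = spliced[p:p + 3]
            if codon in _STOPS:
                if start is not None and p + 3 - start >= min_orf_nt:
                    found.append((start, p + 3))
                start = None
            elif codon == "ATG" and start is None:
                start = p
    return found


def _map_back(orf: tuple[int, int], segments: list[tuple[int, int, int]]) -> list[tuple[int, int]]:
    s, e = orf
    out: list[tuple[int, int]] = []
    for offset, g_start, g_stop in segments:
        seg_len = g_stop - g_start
        lo = max(s, offset)
        hi = min(e, offset + seg_len)
        if lo < hi:
            out.append((g_start + (lo - offset), g_start + (hi - offset)))
    return out


def toy_annotate(
    genome: Mapping[str, str], params: ToyParams | None = None
) -> list[ExonModel]:
    """Predict typed exons on both strands of every contig.

    Per strand, 5'->3': GT..AG introns are selected greedily (nearest
    in-range AG, no overlap with an accepted intron), spliced out, and
    maximal ATG..stop ORFs of at least ``min_orf_nt`` are called on the
    spliced sequence and mapped back to genomic exons.  Candidate genes from
    both strands are then accepted greedily by descending spliced ORF
    length — ties broken by lower genomic start, then + strand — discarding
    any candidate whose genomic span overlaps an accepted gene on either
    strand.  The output is a pure function of sequence content.
    """
    if params is None:
        params = ToyParams()
    exons: list[ExonModel] = []
    for contig in genome:
        seq = genome[contig].upper()
        n = len(seq)
        candidates: list[tuple[int, int, str, list[tuple[int, int]]]] = []
        for strand in "+-":
            oriented = seq if strand == "+" else _revcomp(seq)
            introns = _find_introns(oriented, params)
            spliced, segments = _splice(oriented, introns)
            for orf in _orfs(spliced, params.min_orf_nt):
                oriented_exons = _map_back(orf, segments)
                if strand == "+":
                    genomic = oriented_exons
                else:
                    genomic = sorted((n - b, n - a) for a, b in oriented_exons)
                span_start = genomic[0][0]
                candidates.append((orf[1] - orf[0], span_start, strand, genomic))
        candidates.sort(key=lambda c: (-c[0], c[1], 0 if c[2] == "+" else 1))
        accepted: list[tuple[int, int, str, list[tuple[int, int]]]] = []
        spans: list[tuple[int, int]] = []
        for cand in candidates:
            lo, hi = cand[3][0][0], cand[3][-1][1]
            if all(hi <= a or lo >= b for a, b in spans):
                accepted.append(cand)
                spans.append((lo, hi))
        accepted.sort(key=lambda c: c[1])
        for gi, (_length, _start, strand, genomic) in enumerate(accepted, 1):
            gid = f"{contig}.g{gi}"
            m = len(genomic)
            five = 0 if strand == "+" else m - 1
            three = m - 1 if strand == "+" else 0
            for i, (a, b) in enumerate(genomic):
                if m == 1:
                    etype = "single"
                elif i == five:
                    etype = "initial"
                elif i == three:
                    etype = "terminal"
                else:
                    etype = "internal"
                exons.append(ExonModel(contig, etype, a, b, strand, gene_id=gid))
    return exons


# ---------------------------------------------------------------------------
# External predictor adapter

def run_external_predictor(
    genome_paths: Mapping[str, str | Path],
    command_template: str,
    cache_dir: str | Path,
    dialect: str = "zff",
) -> dict[str, list[ExonModel]]:
    """Run an external gene predictor once per genome, with on-disk caching.

    *command_template* contains ``{input}`` and ``{output}`` placeholders and
    is run through the shell with identical parameters for every genome.
    Predictions are cached as ``<cache_dir>/<genome_id>.<dialect>``; a cache
    hit spawns no subprocess.  A nonzero exit is a hard error carrying the
    predictor's stderr; empty output yields an empty exon set with a warning.
    """
    if dialect not in ("zff", "gff3"):
        raise ValueError(f"unknown prediction dialect {dialect!r}")
    parser = parse_zff if dialect == "zff" else parse_gff3
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    out: dict[str, list[ExonModel]] = {}
    for genome_id, fasta in genome_paths.items():
        target = cache / f"{genome_id}.{dialect}"
        if not target.exists():
            cmd = command_template.format(input=str(fasta), output=str(target))
            proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
            if proc.returncode != 0:
                raise RuntimeError(
                    f"predictor failed for {genome_id} (exit {proc.returncode}): "
                    f"{proc.stderr.strip()}"
                )
        predictions = parser(target) if target.stat().st_size else []
        if not predictions:
            warnings.warn(f"empty prediction set for genome {genome_id}")
        out[genome_id] = predictions
    return out
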