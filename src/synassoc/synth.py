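"""Self-validating synthetic fixtures for the full association pipeline.

The generator emits a toy multi-gene genome, a SNP table whose entries
belong to known mechanistic classes (stop/start/splice disruption,
epistatic donor+acceptor pairs, neutral), and a machine-readable truth
record.  Every fixture is verified at generation time by running the toy
annotator on the reference, the all-alternate genome, and each single-SNP
(and epistatic-pair) genome, asserting exactly the planted consequences;
a fixture whose truth cannot be confirmed is never emitted.

Provability rests on strict motif control rather than chance:

* background and filler sequence is drawn from {A, C, T}, so the only G
  bases in the genome are the planted ATG starts, GT donors and AG
  acceptors — the toy annotator can find no other starts or splice sites
  on the plus strand;
* the trinucleotide CAT is scrubbed everywhere, so the minus strand
  contains no ATG and therefore no gene on the minus strand, anywhere;
* the dinucleotides CT and AC (a splice acceptor and donor as read on the
  minus strand) are scrubbed from all filler, so minus-strand introns can
  arise only at the audited planted literals — the single such intron (the
  latent epistatic site, reference state) splices two G-against-G
  junctions that cannot assemble an ATG;
* TAA is scrubbed from the reading frame of every coding and potential
  read-through span, so the only in-frame stops are the planted primary
  and backup stop codons.

Each gene is a two-exon template on the plus strand::

    ATG + 45 nt ... GT + 38 nt + AG ... 120 nt + TAA   (+ backup TAA, 33 nt
    exon1 (48)      intron (42)         exon2 (123)     downstream in frame)

The intron length (42) is a multiple of 3, so a disrupted splice site reads
through in frame to the primary stop (a single merged exon: intron
gain/loss); a disrupted stop reads on in frame to the backup stop (a longer
terminal exon: shift); a disrupted start removes the gene (exon gain/loss).
Epistatic genes carry a latent CT/AC pair in the second exon whose two C->G
SNPs jointly — and only jointly — create a new in-range GT..AG intron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from synassoc.annotate import ExonModel, ToyParams, toy_annotate
from synassoc.variants import SnpRecord, apply_genotype, write_fasta, write_snp_table

MECHANISMS = (
    "stop_disrupt", "start_disrupt", "donor_disrupt", "acceptor_disrupt",
    "epistatic_donor", "epistatic_acceptor",
    "neutral_exonic", "neutral_intronic", "neutral_intergenic",
)

# gene template geometry (offsets relative to the gene's ATG)
_EXON1_LEN = 48
_INTRON_LEN = 42
_EXON2_LEN = 123          # 120 coding + TAA
_EXON2_START = _EXON1_LEN + _INTRON_LEN           # 90
_GENE_LEN = _EXON2_START + _EXON2_LEN             # 213
_BACKUP_STOP = _GENE_LEN + 30                     # 243, in frame (+33 nt)
_SLOT_LEN = _BACKUP_STOP + 3 + 12                 # 258
_GAP = 450
_EPI_DONOR = 45           # exon2 offset of the latent CT donor (codon start)
_EPI_INTRON = 36          # length of the SNP-created intron, multiple of 3


@dataclass
class PlantedSnp:
    """Truth for one fixture SNP."""

    mechanism: str
    gene_span: tuple[int, int] | None   # genomic span of the affected gene
    expected_category: str | None       # event category once triggered
    expected_site_class: str
    partner_index: int | None = None    # index of the epistatic partner SNP


@dataclass
class FixtureTruth:
    """Machine-readable truth paired index-by-index with the sorted SNP table."""

    seed: int
    n_genes: int
    n_snps_per_class: int
    params: ToyParams
    entries: list[PlantedSnp] = field(default_factory=list)

    def to_json(self, snps: Sequence[SnpRecord], path) -> None:
        payload = {
            "seed": self.seed,
            "n_genes": self.n_genes,
            "n_snps_per_class": self.n_snps_per_class,
            "params": asdict(self.params),
            "snps": [
                {
                    "contig": s.contig,
                    "pos": s.pos + 1,
                    "ref": s.ref,
                    "alt": s.alt,
                    "mechanism": e.mechanism,
                    "gene_span": list(e.gene_span) if e.gene_span else None,
                    "expected_category": e.expected_category,
                    "expected_site_class": e.expected_site_class,
                    "partner_index": e.partner_index,
                }
                for s, e in zip(snps, self.entries)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


class _ContigBuilder:
    """Accumulates sequence from {A,C,T} fillers and planted literals.

    The filler refuses any character completing CAT (a minus-strand ATG),
    the dinucleotides CT or AC (minus-strand splice motifs), or TAA at a
    codon start of the active reading frame.  Some character is always
    admissible, so filling cannot deadlock; ``forbid_last`` additionally
    constrains the final filler base (used before literals starting with
    C) and is satisfied by brute-forcing the last two bases.
    """

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.chars: list[str] = []

    @property
    def pos(self) -> int:
        return len(self.chars)

    def literal(self, s: str) -> None:
        self.chars.extend(s)

    def filler(
        self,
        length: int,
        frame_anchor: int | None = None,
        forbid_last: frozenset[str] = frozenset(),
    ) -> None:
        if length < 2 and forbid_last:
            raise ValueError("forbid_last needs a filler of length >= 2")
        bulk = length - 2 if forbid_last else length
        for _ in range(bulk):
            p = len(self.chars)
            for c in self.rng.permutation(["A", "C", "T"]):
                if self._ok(p, str(c), frame_anchor):
                    self.chars.append(str(c))
                    break
            else:  # pragma: no cover - some base is always admissible
                raise AssertionError("filler deadlock")
        if forbid_last:
            p = len(self.chars)
            for x in self.rng.permutation(["A", "C", "T"]):
                x = str(x)
                if not self._ok(p, x, frame_anchor):
                    continue
                self.chars.append(x)
                for y in self.rng.permutation(["A", "C", "T"]):
                    y = str(y)
                    if y not in forbid_last and self._ok(p + 1, y, frame_anchor):
                        self.chars.append(y)
                        return
                self.chars.pop()
            raise AssertionError("filler deadlock at constrained tail")

    def _ok(self, p: int, c: str, frame_anchor: int | None) -> bool:
        tri = "".join(self.chars[max(0, p - 2):p]) + c
        if tri.endswith("CAT") or tri.endswith("CT") or tri.endswith("AC"):
            return False
        if (
            frame_anchor is not None
            and tri.endswith("TAA")
            and (p - 2 - frame_anchor) % 3 == 0
        ):
            return False
        return True

    def sequence(self) -> str:
        return "".join(self.chars)


def _expected_gene_exons(contig: str, start: int, variant: str) -> set[tuple]:
    """Exon identity keys of one template gene under a named realization."""
    e1 = (contig, "initial", start, start + _EXON1_LEN, "+")
    e2 = (contig, "terminal", start + _EXON2_START, start + _GENE_LEN, "+")
    if variant == "reference":
        return {e1, e2}
    if variant == "stop_lost":
        return {e1, (contig, "terminal", start + _EXON2_START,
                     start + _BACKUP_STOP + 3, "+")}
    if variant == "start_lost":
        return set()
    if variant == "merged":  # splice site lost, read-through in frame
        return {(contig, "single", start, start + _GENE_LEN, "+")}
    if variant == "split":   # epistatic intron created inside exon 2
        d = start + _EXON2_START + _EPI_DONOR
        return {
            e1,
            (contig, "internal", start + _EXON2_START, d, "+"),
            (contig, "terminal", d + _EPI_INTRON, start + _GENE_LEN, "+"),
        }
    raise ValueError(variant)


_ALT_VARIANT = {
    "stop_disrupt": "stop_lost",
    "start_disrupt": "start_lost",
    "donor_disrupt": "merged",
    "acceptor_disrupt": "merged",
    "epistatic": "split",
}

_CATEGORY = {
    "stop_disrupt": "shift",
    "start_disrupt": "exon_gain_loss",
    "donor_disrupt": "intron_gain_loss",
    "acceptor_disrupt": "intron_gain_loss",
    "epistatic_donor": "intron_gain_loss",
    "epistatic_acceptor": "intron_gain_loss",
}

_SITE_CLASS = {
    "stop_disrupt": "stop",
    "start_disrupt": "start",
    "donor_disrupt": "splice_donor",
    "acceptor_disrupt": "splice_acceptor",
    "epistatic_donor": "splice_donor",
    "epistatic_acceptor": "splice_acceptor",
    "neutral_exonic": "exon",
    "neutral_intronic": "intron",
    "neutral_intergenic": "intergenic",
}


def _build_gene(b: _ContigBuilder, epistatic: bool) -> int:
    """Append one gene template plus its post-stop tail; returns gene start."""
    start = b.pos
    no_a = frozenset("A")  # a C-initial literal follows: avoid creating AC
    # exon 1: ATG, forced C (no GT after the start's G), coding filler,
    # forced CC (no ATG across the exon/intron junction)
    b.literal("ATG")
    b.literal("C")
    b.filler(_EXON1_LEN - 6, frame_anchor=start, forbid_last=no_a)
    b.literal("CC")
    # intron: GT ... AG with a forced C before the acceptor so the
    # read-through frame sees CAG, never TAG
    b.literal("GT")
    b.filler(_INTRON_LEN - 5, frame_anchor=start, forbid_last=no_a)
    b.literal("C")
    b.literal("AG")
    # exon 2 coding (120 nt), ending in CCCCCCCCC so the primary stop's
    # codon neighborhood is inert
    b.literal("C")
    if epistatic:
        b.filler(_EPI_DONOR - 2, frame_anchor=start, forbid_last=no_a)
        b.literal("CCT")                          # latent donor (CT -> GT)
        b.filler(31, frame_anchor=start, forbid_last=no_a)
        b.literal("CAC")                          # latent acceptor (AC -> AG)
        b.literal("C")                            # after-acceptor guard, != T
        b.filler(29, frame_anchor=start, forbid_last=no_a)
        b.literal("C" * 9)
    else:
        b.filler(_EXON2_LEN - 3 - 10, frame_anchor=start, forbid_last=no_a)
        b.literal("C" * 9)
    b.literal("TAA")
    # post-stop tail: in-frame filler, then the backup stop for stop-loss
    b.filler(27, frame_anchor=start, forbid_last=no_a)
    b.literal("CCC")
    b.literal("TAA")
    b.filler(12)
    assert b.pos - start == _SLOT_LEN
    return start


def _neutral_alt(seq: str, pos: int, rng: np.random.Generator,
                 frame_anchor: int | None) -> str | None:
    """A substitute base at *pos* provably invisible to the toy annotator.

    The alternate must introduce no G, create no CAT (minus-strand start)
    and no TAA at a codon start of the active frame.  Returns None if no
    such base exists at this position.
    """
    ref = seq[pos]
    window_lo = max(0, pos - 2)
    for alt in rng.permutation(["A", "C", "T"]):
        alt = str(alt)
        if alt == ref:
            continue
        window = seq[window_lo:pos] + alt + seq[pos + 1:pos + 3]
        if "CAT" in window or "CT" in window or "AC" in window:
            continue
        if frame_anchor is not None:
            bad = False
            for off in range(len(window) - 2):
                p0 = window_lo + off
                if window[off:off + 3] == "TAA" and (p0 - frame_anchor) % 3 == 0:
                    bad = True
            if bad:
                continue
        return alt
    return None


def generate_fixture(
    n_genes: int = 20,
    n_snps_per_class: int = 2,
    seed: int = 1,
    params: ToyParams | None = None,
    n_contigs: int = 2,
    out_dir: str | Path | None = None,
    max_retries: int = 5,
) -> tuple[dict[str, str], list[SnpRecord], FixtureTruth]:
    """Generate a (genome, SNP table, truth) triple with planted mechanisms.

    ``n_snps_per_class`` SNPs are planted for each of the five causal
    classes (stop, start, donor, acceptor, epistatic donor+acceptor pair —
    one dedicated gene each) and for each of the three neutral classes
    (exonic, intronic, intergenic).  The fixture is reproducible
    bit-for-bit for a given (seed, parameters) and is self-checked by
    running the toy annotator on the reference, all-alternate, every
    single-SNP genome and every epistatic pair genome.
    """
    if params is None:
        params = ToyParams()
    if params.min_intron > _INTRON_LEN or params.max_intron < _INTRON_LEN:
        raise ValueError("fixture gene template needs min_intron<=42<=max_intron")
    npc = n_snps_per_class
    if 7 * npc > n_genes:
        raise ValueError(
            f"need at least {7 * npc} genes for {npc} SNPs per class, "
            f"got {n_genes}"
        )
    last_error: Exception | None = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(attempt,))
        )
        try:
            return _generate_once(n_genes, npc, seed, params, n_contigs,
                                  out_dir, rng)
        except _FixtureInvalid as exc:  # pragma: no cover - defensive retry
            last_error = exc
    raise RuntimeError(
        f"fixture generation failed after {max_retries} attempts: {last_error}"
    )


class _FixtureInvalid(RuntimeError):
    pass


def _generate_once(n_genes, npc, seed, params, n_contigs, out_dir, rng):
    mech_order = ["stop_disrupt", "start_disrupt", "donor_disrupt",
                  "acceptor_disrupt", "epistatic", "neutral_exonic",
                  "neutral_intronic"]
    mech_of_gene: dict[int, str] = {}
    g = 0
    for mech in mech_order:
        for _ in range(npc):
            mech_of_gene[g] = mech
            g += 1

    per_contig = -(-n_genes // n_contigs)
    genome: dict[str, str] = {}
    gene_pos: list[tuple[str, int]] = []  # (contig, abs start) per gene index
    gap_pos: list[tuple[str, int]] = []   # midpoint of the gap after gene i
    for ci in range(n_contigs):
        contig = f"ctg{ci + 1}"
        b = _ContigBuilder(rng)
        b.filler(_GAP - 1)
        b.literal("A")  # guard: gene ATG preceded by A never completes CAT
        lo = ci * per_contig
        hi = min(n_genes, (ci + 1) * per_contig)
        for gi in range(lo, hi):
            start = _build_gene(b, mech_of_gene.get(gi) == "epistatic")
            gene_pos.append((contig, start))
            gap_pos.append((contig, b.pos + _GAP // 2))
            b.filler(_GAP - 1)
            b.literal("A")
        genome[contig] = b.sequence()

    snps: list[SnpRecord] = []
    entries: list[PlantedSnp] = []

    def plant(contig: str, pos: int, alt: str, mech: str,
              span: tuple[int, int] | None, partner: int | None = None) -> int:
        ref = genome[contig][pos]
        snps.append(SnpRecord(contig, pos, ref, alt))
        entries.append(PlantedSnp(
            mechanism=mech,
            gene_span=span,
            expected_category=_CATEGORY.get(mech),
            expected_site_class=_SITE_CLASS[mech],
            partner_index=partner,
        ))
        return len(snps) - 1

    neutral_genes = {"neutral_exonic": [], "neutral_intronic": []}
    for gi in range(n_genes):
        mech = mech_of_gene.get(gi)
        if mech is None:
            continue
        contig, s = gene_pos[gi]
        span = (s, s + _GENE_LEN)
        if mech == "stop_disrupt":
            plant(contig, s + _GENE_LEN - 3, "C", mech, span)  # TAA -> CAA
        elif mech == "start_disrupt":
            plant(contig, s + 2, "C", mech, span)              # ATG -> ATC
        elif mech == "donor_disrupt":
            plant(contig, s + _EXON1_LEN, "C", mech, span)     # GT -> CT
        elif mech == "acceptor_disrupt":
            plant(contig, s + _EXON2_START - 1, "C", mech, span)  # AG -> AC
        elif mech == "epistatic":
            d = s + _EXON2_START + _EPI_DONOR
            i1 = plant(contig, d, "G", "epistatic_donor", span)
            i2 = plant(contig, d + _EPI_INTRON - 1, "G", "epistatic_acceptor",
                       span, partner=i1)
            entries[i1].partner_index = i2
        else:
            neutral_genes[mech].append(gi)

    # neutral SNPs: provably invisible substitutions
    for gi in neutral_genes["neutral_exonic"]:
        contig, s = gene_pos[gi]
        _plant_neutral(genome, rng, snps, entries, contig,
                       candidates=range(s + _EXON2_START + 6, s + _GENE_LEN - 15),
                       mech="neutral_exonic", span=(s, s + _GENE_LEN),
                       frame_anchor=s)
    for gi in neutral_genes["neutral_intronic"]:
        contig, s = gene_pos[gi]
        _plant_neutral(genome, rng, snps, entries, contig,
                       candidates=range(s + _EXON1_LEN + 7, s + _EXON2_START - 7),
                       mech="neutral_intronic", span=(s, s + _GENE_LEN),
                       frame_anchor=s)
    for i in range(npc):
        contig, mid = gap_pos[i]
        _plant_neutral(genome, rng, snps, entries, contig,
                       candidates=range(mid - 20, mid + 20),
                       mech="neutral_intergenic", span=None, frame_anchor=None)

    order = sorted(range(len(snps)), key=lambda i: snps[i])
    rank = {old: new for new, old in enumerate(order)}
    snps = [snps[i] for i in order]
    entries = [entries[i] for i in order]
    for e in entries:
        if e.partner_index is not None:
            e.partner_index = rank[e.partner_index]

    _validate(genome, snps, entries, mech_of_gene, gene_pos, params, n_genes)

    truth = FixtureTruth(seed=seed, n_genes=n_genes, n_snps_per_class=npc,
                         params=params, entries=entries)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fasta")
        write_snp_table(snps, out / "snps.tsv")
        truth.to_json(snps, out / "truth.json")
    return genome, snps, truth


def _plant_neutral(genome, rng, snps, entries, contig, candidates, mech,
                   span, frame_anchor):
    seq = genome[contig]
    taken = {(s.contig, s.pos) for s in snps}
    for pos in rng.permutation(list(candidates)):
        pos = int(pos)
        if (contig, pos) in taken or seq[pos] == "G":
            continue
        alt = _neutral_alt(seq, pos, rng, frame_anchor)
        if alt is not None:
            snps.append(SnpRecord(contig, pos, seq[pos], alt))
            entries.append(PlantedSnp(
                mechanism=mech, gene_span=span, expected_category=None,
                expected_site_class=_SITE_CLASS[mech],
            ))
            return
    raise _FixtureInvalid(f"no neutral {mech} position available on {contig}")


def _validate(genome, snps, entries, mech_of_gene, gene_pos, params, n_genes):
    """Confirm every planted consequence with the toy annotator."""
    def keys(ann):
        return {e.key for e in ann}

    ref_keys = keys(toy_annotate(genome, params))
    expected_ref = set()
    for gi in range(n_genes):
        contig, s = gene_pos[gi]
        expected_ref |= _expected_gene_exons(contig, s, "reference")
    if ref_keys != expected_ref:
        raise _FixtureInvalid(
            f"reference annotation mismatch: unexpected "
            f"{sorted(ref_keys ^ expected_ref)[:4]}"
        )

    def expect_with(gi: int, variant: str) -> set:
        contig, s = gene_pos[gi]
        return (expected_ref - _expected_gene_exons(contig, s, "reference")) \
            | _expected_gene_exons(contig, s, variant)

    gene_of_span = {}
    for gi in range(n_genes):
        contig, s = gene_pos[gi]
        gene_of_span[(contig, s)] = gi

    vec = np.zeros(len(snps), dtype=np.uint8)
    done_pairs = set()
    for i, (snp, entry) in enumerate(zip(snps, entries)):
        vec[:] = 0
        vec[i] = 1
        single = keys(toy_annotate(apply_genotype(genome, snps, vec), params))
        mech = entry.mechanism
        if mech.startswith("neutral") or mech.startswith("epistatic"):
            if single != ref_keys:
                raise _FixtureInvalid(
                    f"SNP {i} ({mech}) alone must be silent but changed "
                    f"{sorted(single ^ ref_keys)[:4]}"
                )
        else:
            gi = gene_of_span[(snp.contig, entry.gene_span[0])]
            want = expect_with(gi, _ALT_VARIANT[mech])
            if single != want:
                raise _FixtureInvalid(
                    f"SNP {i} ({mech}) produced {sorted(single ^ want)[:4]}"
                )
        if mech == "epistatic_donor":
            j = entry.partner_index
            vec[j] = 1
            both = keys(toy_annotate(apply_genotype(genome, snps, vec), params))
            gi = gene_of_span[(snp.contig, entry.gene_span[0])]
            want = expect_with(gi, "split")
            if both != want:
                raise _FixtureInvalid(
                    f"epistatic pair ({i},{j}) produced {sorted(both ^ want)[:4]}"
                )
            done_pairs.add((i, j))

    all_alt = keys(toy_annotate(apply_genotype(genome, snps,
                                               np.ones(len(snps), np.uint8)),
                                params))
    want_alt = set(expected_ref)
    for gi in range(n_genes):
        mech = mech_of_gene.get(gi)
        if mech in _ALT_VARIANT:
            contig, s = gene_pos[gi]
            want_alt -= _expected_gene_exons(contig, s, "reference")
            want_alt |= _expected_gene_exons(contig, s, _ALT_VARIANT[mech])
    if all_alt != want_alt:
        raise _FixtureInvalid(
            f"all-alternate annotation mismatch: {sorted(all_alt ^ want_alt)[:4]}"
        )
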