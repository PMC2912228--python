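# Methods

## The synthetic association study

The study treats a gene predictor as a deterministic genotype→phenotype
map and borrows the machinery of association mapping to invert it. Two
strains differ at a set of biallelic SNPs. An artificial population of N
intermediate genomes is simulated on the reference backbone: at every SNP
position each genome independently carries the reference or the alternate
allele with probability ½. Alleles are therefore independent across sites
— there is no linkage — which is what makes the downstream association
search clean: any SNP–phenotype correlation reflects causation by that SNP
(or chance), never hitchhiking. The two endpoint genomes (all-reference
and all-alternate) are carried alongside the N intermediates.

Every genome is annotated with the same predictor and parameters. The
phenotype space is the union of all exon models predicted in *any* genome;
an exon model is identified by the exact 5-tuple (contig, exon type,
start, stop, strand), so a one-base boundary shift or a type change
produces a distinct model. This admits exons seen only in intermediate
genomes and in neither endpoint.

### Events

Exons whose presence/absence vectors across all genomes are identical or
exactly complementary are grouped into an *event*; the event's canonical
phenotype vector is oriented so the all-alternate endpoint reads 1, and
each member exon carries a sign (+ correlated, − anti-correlated).
Events whose endpoints agree are discarded (the study concerns variation
between the two strains), as are events grouping exons from more than one
contig (counted and logged — such groupings are coincidences of identical
patterns, not biology). Every polymorphic exon belongs to exactly one
event; this partition equals a quadratic pairwise-comparison oracle on all
small instances, which the test suite checks exhaustively.

The *phenotype frequency* of an event is min(k, N−k)/N, the fraction of
intermediates carrying the rarer version (k counts the canonical
phenotype). It ranges from 0 (monomorphic intermediates) to 0.5 and
is the study's analogue of minor-allele frequency: rare-phenotype events
are intrinsically hard to associate.

### Event categories

Member exons as realized in the two endpoints are overlapped (≥1 shared
base, same strand). Members on opposite strands make the event a `flip`,
which pre-empts everything else. Otherwise each connected overlap
component contributes: no partner → `exon_gain_loss`; a 1:1 pair with a
moved boundary → `shift`; one exon against ≥2 → `intron_gain_loss` (the
more extreme change wins within a component). An event may carry several
categories. A 1:1 component with identical coordinates (an identity
difference in type or score only) matches no category and contributes
none. For the randomized-mutation assay the same overlap logic runs
directly on two full prediction sets without event grouping, with
direction resolved by treating the first genome as ancestral (`exon_loss`
vs `exon_gain`, `intron_gain` when the derived genome splits an exon);
balanced m:n components with m = n ≥ 2 have no defensible direction and
are tallied separately as `complex`.

### Association statistic and null

For each event × SNP pair, m counts intermediates where the SNP allele
co-occurs with the event phenotype. Because allele labelling is arbitrary,
the agreement folds: agreement = max(m, N−m), and

    correlation = (agreement − N/2) / (N/2)

is 1 at perfect association and 0 at chance. Under independence the raw
count is Binomial(N, ½), so the correlation null is the folded binomial,
computed by exact summation (`null_tail`). The significance cutoff is the
smallest achievable correlation value c = (2k − N)/N at which the
empirical false discovery rate — expected null tail count at c divided by
the observed count of correlations ≥ c — drops to α (default 0.05). The
cutoff is therefore data-dependent by construction. Events with no
variation among intermediates are reported but excluded from cutoff
estimation, since their associations are vacuous. Endpoint genomes define
event polarity but are excluded from N.

### Complete explanations (epistasis)

An event is *completely explained* by a SNP subset if every allele
combination observed over the intermediates co-occurs with a single
phenotype. Subsets of size 1..5 over the event's significant SNPs are
tested exhaustively; the first size with an explanation wins, ties broken
by higher summed correlation, then genomic order. A perfectly correlated
SNP always explains alone at k = 1. The candidate list is capped at 20
SNPs (top correlations, logged) because the subset count grows as C(n, 5).

### SNP site classification

Within one genome's gene models: the first/last 3 bp of a gene span are
start/stop sites (5′/3′ on the gene's strand); intronic positions within
5 bp of an intron's 5′/3′ end are splice donor/acceptor; otherwise exon,
intron or intergenic. Across the two endpoint genomes the more functional
class wins: start > stop > splice donor > splice acceptor > exon > intron
> intergenic (a SNP in a start codon in one genome and an intron in the
other is a start-codon SNP). SNP-to-event distance is 0 inside any member
exon, else the gap to the nearest member exon boundary; a SNP on another
contig is reported as unlinked.

### Randomized-mutation assay

The mutation spectrum tallies the 12 ordered substitution types among the
SNPs and the eligible A/C/G/T counts of the genome (optionally restricted
by a BED coverage mask — coverage itself is an input property, not
recomputed). Mutations are re-placed in a single left-to-right pass: at
each eligible base of nucleotide X the probability of mutating to Y is
(remaining X→Y count) / (remaining eligible X bases). This sequential
scheme is exact by construction — when the remaining eligible bases equal
the remaining mutations the probability reaches 1 — so every run places
precisely the input spectrum, each eligible position equally likely
(verified by a χ² uniformity test over 10⁴ seeded replicates). A base is
mutated at most once.

## The toy annotator

A deterministic stand-in for an HMM gene finder, pinned so fixture truth
is provable. Per strand, scanning 5′→3′: every GT is paired greedily with
the nearest downstream AG giving an intron length within
[min_intron, max_intron] (defaults 30 and 200 nt); a candidate overlapping
an accepted intron is discarded. Accepted introns are spliced out and
maximal ATG→{TAA, TAG, TGA} open reading frames of at least `min_orf_nt`
(default 120 nt, start through stop inclusive) are called on the spliced
sequence — earliest ATG since the previous stop, per frame — and mapped
back to genomic exons. Candidate genes from both strands are accepted
greedily by descending spliced ORF length (ties: lower genomic start, then
plus strand), discarding candidates whose genomic span overlaps an
accepted gene on either strand. The output is a pure function of sequence
content, so it reacts to point mutations exactly the way the association
machinery assumes: stop loss extends an exon, start loss deletes a gene,
splice-site loss merges exons, and a created donor+acceptor pair splits
one. The defaults reflect a compact fungal-like genome: short introns,
modest minimum ORF.

## The fixture generator

`synth.generate_fixture` emits a toy genome, SNP table and truth file
whose planted effects are provable, not probable. Each gene is a
two-exon plus-strand template: 48 nt initial exon, 42 nt intron, 123 nt
terminal exon, with a backup in-frame stop 33 nt past the primary one.
The intron length is a multiple of 3 so splice-site loss reads through in
frame to the primary stop (one merged exon); stop loss reads through to
the backup stop (a boundary shift); start loss removes the gene.
Epistatic genes carry a latent CT/AC pair inside the terminal exon whose
two C→G SNPs jointly create a new in-frame, in-range intron — each alone
is inert. Provability rests on motif scrubbing: filler sequence is drawn
from {A, C, T} (so G exists only in planted motifs), the trinucleotide
CAT is excluded everywhere (no minus-strand ATG, hence no minus-strand
gene), the dinucleotides CT and AC are excluded from filler (no
minus-strand splice sites beyond audited literals), and TAA is excluded
from the reading frame of every coding or potential read-through span.
Neutral SNPs are substitutions proven to create none of these motifs,
placed in an exon, an intron (outside splice windows) or mid-gap
(≥200 bp from any gene). Genes sit in 450 bp gaps so no intron can span
slots and SNP effects are provably local to their own gene; with at most
two SNPs per gene, validating the reference, the all-alternate genome,
every single-SNP genome and every epistatic pair covers all realizable
local genotype neighborhoods. The generator runs this validation at build
time and refuses to emit a fixture whose truth does not hold; output is
bit-reproducible for a given seed.

The standard fixture (20 genes split over 2 contigs, 2 SNPs per causal
class, 6 neutral SNPs, N = 500 intermediates, seed 1) is what the
acceptance suite runs end-to-end; the full study (502 annotated genomes of
about 15 kb) completes in a couple of seconds. What passing shows: the
pipeline recovers planted single-SNP causes, epistatic pairs and neutral
SNPs exactly under a predictor whose rules it controls. What it does not
show: behaviour under realistic genome composition (repeats, codon bias,
overlapping genes), predictor stochasticity, indels or multi-allelic
sites, all of which are out of scope by design.

## Numerical and design choices

- Coordinates are 0-based half-open internally; all file formats use their
  native conventions (1-based inclusive for SNP TSV/GFF3/ZFF, 0-based
  half-open for BED).
- Folded (unsigned) agreement is used because a single-number correlation
  with a null peaking at zero implies the allele labelling is arbitrary;
  the allele achieving the agreement is recorded for reporting.
- The FDR cutoff search runs over the exact achievable correlation grid,
  never interpolated values, and returns an infinite sentinel when no
  grid value qualifies (e.g. tiny populations) — then nothing is
  significant.
- Exon type is part of exon identity but ignored by interval-overlap
  logic, so a pure type change still registers as a polymorphic pair.
- Every stochastic operation takes an explicit seed; the pipeline derives
  per-stage seeds from the master seed via `numpy` seed sequences and logs
  them, so reruns are byte-identical and cached annotation stages are
  skipped without changing output.
- Scores parsed from prediction files are carried through untouched; no
  logic consults them.

## Known limitations

- Only biallelic substitutions are modelled; indels and multi-allelic
  sites are out of scope.
- The simulated population is linkage-free by construction, so no
  population-structure or linkage-aware corrections are provided.
- Events grouping exons across contigs are dropped rather than resolved.
- The toy annotator has no UTRs, no alternative splicing and no scoring;
  it is a testing instrument, not a gene finder.
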