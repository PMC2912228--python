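"""SNP-event association: correlation statistic, binomial null, FDR cutoff,
epistasis search, and SNP site classification.

The association statistic is a linear rescaling of the SNP-event agreement
frequency over the N intermediate genomes:

    correlation = (agreement - N/2) / (N/2)

where agreement = max(m, N - m) folds over the arbitrary allele labelling
(m is the raw number of intermediates at which the SNP allele and the event
phenotype co-occur).  Full agreement (N of N) maps to 1, chance (N/2) to 0.
Under independence the correlation inherits a folded Binomial(N, 1/2)
distribution, which serves as the null for an empirical false-discovery-rate
cutoff.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import binom

from synassoc.annotate import ExonModel, GeneModel, group_genes
from synassoc.events import Event
from synassoc.variants import SnpRecord

logger = logging.getLogger(__name__)

SITE_CLASSES = (
    "start", "stop", "splice_donor", "splice_acceptor",
    "exon", "intron", "intergenic",
)
_SITE_RANK = {name: i for i, name in enumerate(SITE_CLASSES)}

#: Sentinel for a SNP on a different contig from every member exon.
UNLINKED = "unlinked"


@dataclass
class AssociationResult:
    """One scored SNP-event pair."""

    event_id: str
    snp_index: int
    agreement: int
    correlation: float
    perfect: bool
    significant: bool
    distance_bp: int | None = None  # None = unlinked (different contig)
    site_class: str | None = None
    matched_allele: str | None = None  # allele co-occurring with the phenotype


def correlation(
    event_vector: Sequence[int] | np.ndarray,
    snp_vector: Sequence[int] | np.ndarray,
) -> tuple[int, float]:
    """Agreement count and folded correlation over the intermediates.

    Both vectors are binary and cover the N intermediate genomes only.
    Returns (agreement, correlation) with agreement = max(m, N - m).
    """
    e = np.asarray(event_vector, dtype=bool)
    s = np.asarray(snp_vector, dtype=bool)
    if e.shape != s.shape:
        raise ValueError(f"vector length mismatch: {e.shape} vs {s.shape}")
    n = e.size
    m = int((e == s).sum())
    agreement = max(m, n - m)
    return agreement, (agreement - n / 2) / (n / 2)


def null_tail(n_intermediates: int, n_pairs: int, c: float) -> float:
    """Expected number of null correlations >= c among *n_pairs* tests.

    Under independence the raw match count X ~ Binomial(N, 1/2) and the
    folded correlation is (max(X, N-X) - N/2)/(N/2); the tail is computed by
    exact binomial summation.
    """
    n = n_intermediates
    threshold = n * (1 + c) / 2  # agreement >= threshold
    k0 = math.ceil(threshold)
    if 2 * k0 <= n:
        return float(n_pairs)
    p = binom.sf(k0 - 1, n, 0.5) + binom.cdf(n - k0, n, 0.5)
    return n_pairs * float(p)


def fdr_cutoff(
    correlations: Sequence[float] | np.ndarray,
    n_intermediates: int,
    alpha: float = 0.05,
) -> float:
    """Smallest achievable correlation controlling the empirical FDR at *alpha*.

    FDR(c) is the expected null tail count at c (binomial null over the same
    number of pairs) divided by the observed count of correlations >= c.
    The cutoff is searched over the exact achievable grid
    (2k - N)/N for k = ceil(N/2)..N; returns ``math.inf`` when no grid value
    qualifies.
    """
    obs = np.asarray(correlations, dtype=float)
    if obs.size == 0:
        raise ValueError("no correlations supplied")
    n = n_intermediates
    n_pairs = obs.size
    sorted_obs = np.sort(obs)
    for k in range(math.ceil(n / 2), n + 1):
        c = (2 * k - n) / n
        observed = n_pairs - np.searchsorted(sorted_obs, c - 1e-12, side="left")
        if observed == 0:
            continue
        if null_tail(n, n_pairs, c) / observed <= alpha:
            return c
    return math.inf


def associate_all(
    events: Sequence[Event],
    genotype_matrix: np.ndarray,
    snps: Sequence[SnpRecord],
    alpha: float = 0.05,
) -> tuple[list[AssociationResult], float]:
    """Score every event x SNP pair and calibrate the significance cutoff.

    *genotype_matrix* holds the intermediate genomes only, one row per
    genome, aligned with each event's intermediate phenotype vector.
    Events with no variation among the intermediates are scored but
    excluded from cutoff estimation (their associations are vacuous).
    Returns the result list and the FDR cutoff.
    """
    geno = np.asarray(genotype_matrix, dtype=np.int8)
    n_inter = geno.shape[0]
    results: list[AssociationResult] = []
    informative: list[float] = []
    all_pairs: list[tuple[int, int, int, float]] = []
    for ei, event in enumerate(events):
        phen = event.intermediate_vector().astype(np.int8)
        degenerate = phen.min() == phen.max()
        if degenerate:
            logger.warning(
                "event %s has no variation among intermediates; "
                "excluded from cutoff estimation", event.event_id,
            )
        matches = (geno == phen[:, None]).sum(axis=0)
        agreements = np.maximum(matches, n_inter - matches)
        corrs = (agreements - n_inter / 2) / (n_inter / 2)
        for si in range(geno.shape[1]):
            all_pairs.append((ei, si, int(agreements[si]), float(corrs[si])))
            if not degenerate:
                informative.append(float(corrs[si]))
    cutoff = fdr_cutoff(informative, n_inter, alpha) if informative else math.inf
    for ei, si, agreement, corr in all_pairs:
        event = events[ei]
        perfect = agreement == n_inter
        phen = event.intermediate_vector().astype(np.int8)
        m = int((geno[:, si] == phen).sum())
        allele = snps[si].alt if m >= n_inter - m else snps[si].ref
        results.append(
            AssociationResult(
                event_id=event.event_id,
                snp_index=si,
                agreement=agreement,
                correlation=corr,
                perfect=perfect,
                significant=corr > cutoff,
                matched_allele=allele,
            )
        )
    return results, cutoff


# ---------------------------------------------------------------------------
# Epistasis: complete explanations by SNP subsets

def _single_valued(
    geno: np.ndarray, phen: np.ndarray, subset: tuple[int, ...]
) -> bool:
    mapping: dict[bytes, int] = {}
    sub = geno[:, list(subset)]
    for row, p in zip(sub, phen):
        sig = row.tobytes()
        prev = mapping.setdefault(sig, int(p))
        if prev != int(p):
            return False
    return True


def explain_event(
    event: Event,
    genotype_matrix: np.ndarray,
    candidate_indices: Sequence[int],
    correlations: Mapping[int, float] | None = None,
    max_k: int = 5,
    candidate_cap: int = 20,
) -> tuple[int, ...] | None:
    """Find a minimal SNP subset that completely explains the event.

    A subset explains the event iff every genotype combination observed
    over the intermediates always co-occurs with a single event phenotype.
    Subsets of size k = 1..max_k are tested exhaustively over the candidate
    SNPs (the significantly correlated ones); among equally small
    explanations the one with the higher summed correlation wins, then
    genomic order.  Candidates beyond *candidate_cap* are truncated to the
    top correlations with a warning.
    """
    geno = np.asarray(genotype_matrix, dtype=np.int8)
    phen = event.intermediate_vector().astype(np.int8)
    candidates = list(candidate_indices)
    if correlations is None:
        correlations = {i: 0.0 for i in candidates}
    if len(candidates) > candidate_cap:
        logger.warning(
            "event %s: %d candidate SNPs truncated to top %d by correlation",
            event.event_id, len(candidates), candidate_cap,
        )
        candidates = sorted(
            candidates, key=lambda i: (-correlations.get(i, 0.0), i)
        )[:candidate_cap]
        candidates.sort()
    for k in range(1, max_k + 1):
        best: tuple[float, tuple[int, ...]] | None = None
        for subset in itertools.combinations(candidates, k):
            if _single_valued(geno, phen, subset):
                score = -sum(correlations.get(i, 0.0) for i in subset)
                cand = (score, subset)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            return best[1]
    return None


def genotype_phenotype_map(
    event: Event,
    genotype_matrix: np.ndarray,
    snps: Sequence[SnpRecord],
    subset: Sequence[int],
) -> dict[str, set[int]]:
    """Observed allele-combination -> phenotype values, for reporting."""
    geno = np.asarray(genotype_matrix, dtype=np.int8)
    phen = event.intermediate_vector().astype(np.int8)
    out: dict[str, set[int]] = {}
    for row, p in zip(geno[:, list(subset)], phen):
        alleles = "".join(
            snps[i].alt if a else snps[i].ref for i, a in zip(subset, row)
        )
        out.setdefault(alleles, set()).add(int(p))
    return out


# ---------------------------------------------------------------------------
# SNP site classification and distances

def _classify_in_genes(
    snp: SnpRecord, genes: Iterable[GeneModel],
    start_stop_bp: int = 3, splice_bp: int = 5,
) -> str:
    best = "intergenic"
    for gene in genes:
        if gene.contig != snp.contig:
            continue
        lo, hi = gene.span
        if not lo <= snp.pos < hi:
            continue
        # gene-terminal windows are strand-aware: "start" is the 5'-most
        # start_stop_bp bases of the gene span on its strand.
        if gene.strand == "+":
            in_start = snp.pos < lo + start_stop_bp
            in_stop = snp.pos >= hi - start_stop_bp
        else:
            in_start = snp.pos >= hi - start_stop_bp
            in_stop = snp.pos < lo + start_stop_bp
        cls = "intron"
        for a, b in gene.introns:
            if a <= snp.pos < b:
                if gene.strand == "+":
                    donor = snp.pos < a + splice_bp
                    acceptor = snp.pos >= b - splice_bp
                else:
                    donor = snp.pos >= b - splice_bp
                    acceptor = snp.pos < a + splice_bp
                if donor:
                    cls = "splice_donor"
                elif acceptor:
                    cls = "splice_acceptor"
                break
        else:
            cls = "exon"
        if in_start:
            cls = "start"
        elif in_stop and _SITE_RANK["stop"] < _SITE_RANK[cls]:
            cls = "stop"
        if _SITE_RANK[cls] < _SITE_RANK[best]:
            best = cls
    return best


def classify_snp_site(
    snp: SnpRecord,
    exons_a: Iterable[ExonModel],
    exons_b: Iterable[ExonModel],
) -> str:
    """Functional site class of a SNP relative to two genomes' gene models.

    Within one genome: the first/last 3 bp of a gene span are start/stop
    sites (5'/3' on the gene's strand); intronic positions within 5 bp of
    the intron's 5' or 3' end are splice donor/acceptor; otherwise exon,
    intron, or intergenic.  The two per-genome classes are then resolved by
    the hierarchy start > stop > splice donor > splice acceptor > exon >
    intron > intergenic, the more functional location winning.
    """
    cls_a = _classify_in_genes(snp, group_genes(exons_a))
    cls_b = _classify_in_genes(snp, group_genes(exons_b))
    return cls_a if _SITE_RANK[cls_a] <= _SITE_RANK[cls_b] else cls_b


def snp_event_distance(snp: SnpRecord, event: Event) -> int | None:
    """Base pairs from the SNP to the nearest member exon of the event.

    0 when the SNP falls inside any member exon interval (as realized in
    either endpoint); otherwise the minimum gap to the nearest member exon
    boundary on the same contig.  Returns None (unlinked) when every member
    exon lies on a different contig.
    """
    best: int | None = None
    for (contig, _etype, start, stop, _strand) in event.member_keys:
        if contig != snp.contig:
            continue
        if start <= snp.pos < stop:
            return 0
        gap = start - snp.pos if snp.pos < start else snp.pos - stop + 1
        if best is None or gap < best:
            best = gap
    return best
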