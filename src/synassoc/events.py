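"""Exon presence/absence matrices, event grouping and categorization.

An *event* is the atomic phenotype of the association study: a maximal set
of exon models whose presence/absence patterns across every genome —
reference, all-alternate, and all intermediates — are identical or exactly
complementary.  Only events polymorphic between the two endpoint genomes
are analyzed, and an event grouping exons from more than one contig is
dropped (and counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from synassoc.annotate import ExonModel

logger = logging.getLogger(__name__)

CATEGORIES = ("shift", "exon_gain_loss", "intron_gain_loss", "flip")

ExonKey = tuple[str, str, int, int, str]


@dataclass
class PresenceMatrix:
    """Boolean exon-key x genome table over every exon predicted anywhere.

    Genome order is (reference, all_alt, intermediates...); an exon key is
    listed iff it was predicted in at least one genome, which admits exons
    seen only in intermediates and never in either endpoint.
    """

    exon_keys: list[ExonKey]
    genome_ids: list[str]
    table: np.ndarray  # bool, shape (n_exons, n_genomes)
    exemplars: dict[ExonKey, ExonModel] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        index = pd.Index([str(k) for k in self.exon_keys], name="exon_key")
        return pd.DataFrame(self.table, index=index, columns=self.genome_ids)


@dataclass
class Event:
    """A group of exons sharing one presence/absence pattern (or its complement).

    ``members`` pairs each exon key with a sign: +1 if its presence vector
    equals the canonical phenotype vector, -1 if it is the complement.  The
    canonical vector is oriented so the all-alternate endpoint shows 1.
    ``phenotype_vector`` covers all genomes in matrix order.
    """

    event_id: str
    contig: str
    members: list[tuple[ExonKey, int]]
    phenotype_vector: np.ndarray
    categories: set[str] = field(default_factory=set)
    phenotype_frequency: float | None = None

    @property
    def member_keys(self) -> list[ExonKey]:
        return [k for k, _ in self.members]

    def intermediate_vector(self) -> np.ndarray:
        """Canonical phenotype over the intermediates only (endpoints excluded)."""
        return self.phenotype_vector[2:]


def build_presence_matrix(
    predictions: Mapping[str, Sequence[ExonModel]],
    genome_order: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Union all predicted exon keys and mark presence per genome.

    *predictions* maps genome id to its exon list; *genome_order* fixes the
    column order (defaults to mapping order) and must contain unique ids
    with the two endpoints first.
    """
    ids = list(genome_order) if genome_order is not None else list(predictions)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome id in presence matrix")
    key_sets: dict[str, set[ExonKey]] = {}
    exemplars: dict[ExonKey, ExonModel] = {}
    for gid in ids:
        keys = set()
        for exon in predictions[gid]:
            keys.add(exon.key)
            exemplars.setdefault(exon.key, exon)
        key_sets[gid] = keys
    all_keys = sorted(exemplars)
    table = np.zeros((len(all_keys), len(ids)), dtype=bool)
    for j, gid in enumerate(ids):
        present = key_sets[gid]
        for i, key in enumerate(all_keys):
            if key in present:
                table[i, j] = True
    return PresenceMatrix(all_keys, ids, table, exemplars)


def group_events(matrix: PresenceMatrix) -> list[Event]:
    """Partition polymorphic exons into events by canonicalized presence vector.

    Exons whose vectors are identical or exactly complementary across ALL
    genomes share an event.  Events whose endpoints agree (non-polymorphic
    between reference and all-alternate) are dropped, as are events that mix
    contigs (counted in the log).
    """
    if matrix.table.shape[1] < 2:
        raise ValueError("presence matrix must include both endpoint genomes")
    groups: dict[bytes, list[tuple[ExonKey, int]]] = {}
    vectors: dict[bytes, np.ndarray] = {}
    for i, key in enumerate(matrix.exon_keys):
        vec = matrix.table[i]
        # canonical orientation: all-alt endpoint (column 1) shows True;
        # if endpoints agree the orientation is resolved by the first
        # differing genome so complements still collide in one bucket.
        if vec[1] != vec[0]:
            flip = not vec[1]
        else:
            flip = bool(vec[0])
        canon = ~vec if flip else vec
        sig = canon.tobytes()
        groups.setdefault(sig, []).append((key, -1 if flip else 1))
        vectors.setdefault(sig, canon)
    events: list[Event] = []
    dropped_multicontig = 0
    n = 0
    for sig, members in sorted(groups.items(), key=lambda kv: min(kv[1])):
        canon = vectors[sig]
        if canon[0] == canon[1]:
            continue  # not polymorphic between the endpoints
        contigs = {key[0] for key, _ in members}
        if len(contigs) > 1:
            dropped_multicontig += 1
            continue
        n += 1
        events.append(
            Event(
                event_id=f"event_{n:04d}",
                contig=contigs.pop(),
                members=sorted(members),
                phenotype_vector=canon.astype(np.uint8),
            )
        )
    if dropped_multicontig:
        logger.info("dropped %d multi-contig event(s)", dropped_multicontig)
    group_events.last_dropped_multicontig = dropped_multicontig  # type: ignore[attr-defined]
    return events


def phenotype_frequency(event: Event, n_intermediates: int) -> float:
    """Fraction of intermediate genomes carrying the rarer event version.

    min(k, N-k)/N where k counts intermediates showing the canonical
    phenotype; ranges from 0 (monomorphic intermediates) to 0.5.
    """
    if n_intermediates == 0:
        raise ValueError("no intermediate genomes")
    k = int(event.intermediate_vector().sum())
    return min(k, n_intermediates - k) / n_intermediates


# ---------------------------------------------------------------------------
# Overlap machinery

def _overlaps(a: ExonModel, b: ExonModel) -> bool:
    return a.contig == b.contig and a.start < b.stop and b.start < a.stop


def _components(
    side_a: Sequence[ExonModel], side_b: Sequence[ExonModel]
) -> list[tuple[list[ExonModel], list[ExonModel]]]:
    """Connected components of the strand-aware bipartite overlap graph."""
    same_strand = lambda a, b: a.strand == b.strand
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    items = [(e, 0) for e in side_a] + [(e, 1) for e in side_b]
    for i in range(len(items)):
        parent[i] = i
    for i, (ea, sa) in enumerate(items):
        for j in range(i + 1, len(items)):
            eb, sb = items[j]
            if sa != sb and same_strand(ea, eb) and _overlaps(ea, eb):
                union(i, j)
    comps: dict[int, tuple[list[ExonModel], list[ExonModel]]] = {}
    for i, (e, side) in enumerate(items):
        root = find(i)
        comps.setdefault(root, ([], []))[side].append(e)
    return list(comps.values())


def categorize_event(
    event: Event,
    reference_exons: Iterable[ExonModel],
    all_alt_exons: Iterable[ExonModel],
) -> set[str]:
    """Assign structural categories by overlapping the event's endpoint exons.

    The event's member exons as realized in the reference genome are
    compared against those realized in the all-alternate genome.  Members on
    opposite strands make the whole event a "flip" and nothing else.
    Otherwise each overlap component contributes: no partner -> exon
    gain/loss; 1:1 with moved boundary -> shift; any side with 2 or more
    overlapping exons -> intron gain/loss (the more extreme change wins
    within a component).  An event may carry several categories.
    """
    member_set = set(event.member_keys)
    side_ref = [e for e in reference_exons if e.key in member_set]
    side_alt = [e for e in all_alt_exons if e.key in member_set]
    strands = {k[4] for k in member_set}
    if len(strands) > 1:
        return {"flip"}
    categories: set[str] = set()
    for in_ref, in_alt in _components(side_ref, side_alt):
        m, n = len(in_ref), len(in_alt)
        if m + n == 0:
            continue
        if max(m, n) >= 2 and min(m, n) >= 1:
            categories.add("intron_gain_loss")
            if max(m, n) > 2:
                logger.info(
                    "event %s: complex %d:%d overlap component categorized "
                    "as intron_gain_loss", event.event_id, m, n,
                )
        elif m == 1 and n == 1:
            a, b = in_ref[0], in_alt[0]
            if (a.start, a.stop) != (b.start, b.stop):
                categories.add("shift")
        else:  # 1:0 or 0:1
            categories.add("exon_gain_loss")
    return categories


def classify_pairwise_changes(
    exons_a: Sequence[ExonModel], exons_b: Sequence[ExonModel]
) -> dict[str, int]:
    """Count structural differences between two full prediction sets.

    Genome A is taken as ancestral.  Only exons differing between the sets
    (by identity key) enter the overlap graph; components are counted as:
    1:0 exon_loss, 0:1 exon_gain, 1:1 with moved boundary shift, one A exon
    over >=2 B exons intron_gain (an intron appeared in B), >=2 A exons over
    one B exon intron_loss.  Balanced m:n components with m == n >= 2 match
    no single direction and are counted under "complex".  No event grouping
    is involved.
    """
    keys_a = {e.key for e in exons_a}
    keys_b = {e.key for e in exons_b}
    only_a = [e for e in exons_a if e.key not in keys_b]
    only_b = [e for e in exons_b if e.key not in keys_a]
    counts = {
        "exon_gain": 0, "exon_loss": 0, "shift": 0,
        "intron_gain": 0, "intron_loss": 0, "complex": 0,
    }
    for in_a, in_b in _components(only_a, only_b):
        m, n = len(in_a), len(in_b)
        if m + n == 0:
            continue
        if m == 1 and n == 0:
            counts["exon_loss"] += 1
        elif m == 0 and n == 1:
            counts["exon_gain"] += 1
        elif m == 1 and n == 1:
            a, b = in_a[0], in_b[0]
            if (a.start, a.stop) != (b.start, b.stop):
                counts["shift"] += 1
        elif m < n:
            counts["intron_gain"] += 1
        elif m > n:
            counts["intron_loss"] += 1
        else:
            counts["complex"] += 1
    return counts
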