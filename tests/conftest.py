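"""Shared fixtures: the standard synthetic study, run once per session."""

from dataclasses import dataclass

import numpy as np
import pytest

from synassoc.annotate import ExonModel
from synassoc.assoc import AssociationResult, associate_all, explain_event
from synassoc.cli import _stage_seed
from synassoc.events import (
    Event,
    PresenceMatrix,
    build_presence_matrix,
    categorize_event,
    group_events,
    phenotype_frequency,
)
from synassoc.synth import FixtureTruth, generate_fixture
from synassoc.variants import GenotypeMatrix, SnpRecord, apply_genotype, sample_genotypes
from synassoc.annotate import toy_annotate

N_INTERMEDIATES = 500
MASTER_SEED = 1


@dataclass
class Study:
    """The standard fixture pushed through the whole in-memory pipeline."""

    genome: dict
    snps: list
    truth: FixtureTruth
    gm: GenotypeMatrix
    predictions: dict
    matrix: PresenceMatrix
    events: list
    results: list
    cutoff: float
    explanations: dict

    def results_for(self, event_id):
        return [r for r in self.results if r.event_id == event_id]


@pytest.fixture(scope="session")
def standard_fixture():
    return generate_fixture(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def study(standard_fixture):
    genome, snps, truth = standard_fixture
    gm = sample_genotypes(N_INTERMEDIATES, len(snps),
                          seed=_stage_seed(MASTER_SEED, 1))
    predictions = {
        gid: toy_annotate(apply_genotype(genome, snps, gm.matrix[i]))
        for i, gid in enumerate(gm.genome_ids)
    }
    matrix = build_presence_matrix(predictions, gm.genome_ids)
    events = group_events(matrix)
    for ev in events:
        ev.phenotype_frequency = phenotype_frequency(ev, N_INTERMEDIATES)
        ev.categories = categorize_event(
            ev, predictions[gm.REFERENCE_ID], predictions[gm.ALL_ALT_ID]
        )
    results, cutoff = associate_all(events, gm.matrix[2:], snps)
    corr = {}
    sig = {}
    for r in results:
        corr.setdefault(r.event_id, {})[r.snp_index] = r.correlation
        if r.significant:
            sig.setdefault(r.event_id, []).append(r.snp_index)
    explanations = {
        ev.event_id: explain_event(ev, gm.matrix[2:],
                                   sorted(sig.get(ev.event_id, [])),
                                   correlations=corr[ev.event_id])
        for ev in events
    }
    return Study(genome, snps, truth, gm, predictions, matrix, events,
                 results, cutoff, explanations)


def make_exon(contig="c1", etype="single", start=0, stop=100, strand="+",
              gene_id=None):
    return ExonModel(contig, etype, start, stop, strand, gene_id=gene_id)
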