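"""Shared fixtures: a session-scoped noise-free simulated cross run end to
end through the pipeline, plus truth-scoring helpers."""

from __future__ import annotations

import collections

import numpy as np
import pytest
from hypothesis import settings

from polymaps.pipeline import PipelineResult, run_simulated_pipeline
from polymaps.simulate import SUBGENOME_ORDER, SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")

# The standard noise-free cross: same pedigree, depth and planted structure
# as the full-scale conditions but with zero sequencing error and a reduced
# target count per chromosome to keep the suite fast.
TESTBED_CONFIG = SimulationConfig(
    seed=20,
    n_chromosomes=7,
    chromosome_length=1_000_000,
    targets_per_chromosome=64,
    n_progeny=48,
    depth=80.0,
    error_rate=0.0,
    n_tracts=6,
    tract_length=60_000,
    n_transpositions=4,
)


@pytest.fixture(scope="session")
def testbed() -> PipelineResult:
    return run_simulated_pipeline(TESTBED_CONFIG)


def clean_planted_sites(result: PipelineResult) -> list:
    """Planted sites that remain heterozygous in exactly one parent in the
    realised truth haplotypes (collisions with interhomeolog differences are
    excluded: they are not single-subgenome het sites)."""
    cross = result.simulator.cross
    lin = result.simulator.lineages
    out = []
    for s in cross.planted:
        idx = int(np.searchsorted(lin.positions[s.chromosome], s.position))
        col = [
            cross.haplotypes[(par, sub, h)][s.chromosome][idx]
            for par in "mp"
            for sub in SUBGENOME_ORDER
            for h in (0, 1)
        ]
        m_het = len(set(col[:8])) > 1
        p_het = len(set(col[8:])) > 1
        if m_het != p_het:
            out.append(s)
    return out


def lg_snp_recall(result: PipelineResult) -> float:
    retained = {
        (s.coordinate.chromosome, s.coordinate.position,
         {"maternal": "m", "paternal": "p"}[s.parent_of_origin.value])
        for s in result.selection.lg_snps
    }
    clean = clean_planted_sites(result)
    hits = sum(
        1
        for s in clean
        if (f"chr{s.chromosome + 1}", s.position, s.parent) in retained
    )
    return hits / len(clean)


def true_group_labels(result: PipelineResult) -> dict[str, str]:
    """Majority planted subgenome of each major group's LG SNPs."""
    planted = {
        (s.chromosome, s.position, s.parent): s.subgenome
        for s in result.simulator.cross.planted
    }
    truth = {}
    for g in result.major_groups:
        tally: collections.Counter = collections.Counter()
        for snp in g.snps:
            ci = int(snp.coordinate.chromosome.replace("chr", "")) - 1
            key = (ci, snp.coordinate.position, g.parent)
            if key in planted:
                tally[planted[key]] += 1
        truth[g.group_id] = tally.most_common(1)[0][0] if tally else None
    return truth


def tract_cluster_recall(result: PipelineResult) -> tuple[int, int]:
    tracts = result.simulator.lineages.tracts
    hits = 0
    for t in tracts:
        chrom = f"chr{t.chromosome + 1}"
        hits += any(
            c.chromosome == chrom
            and c.subgenome == t.subgenome
            and c.first_site <= t.end
            and c.last_site >= t.start
            for c in result.scan.clusters
        )
    return hits, len(tracts)
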