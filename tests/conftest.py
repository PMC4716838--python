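"""Shared fixtures: a toy genome for unit tests and the default-scale
simulated study (four genotypes, 50k reads each) reused across tests."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from p4r2scan.align import build_index
from p4r2scan.biogenesis import SimParams, build_catalog, simulate_sample
from p4r2scan.genome import GenomeBundle, LocusPlan, simulate_genome
from p4r2scan.species import (
    SampleMeta,
    build_species_table,
    exclude_stage1,
    exclude_stage2,
    normalize,
)

STUDY_SEED = 7
GENOTYPE_SEEDS = {"Col-0": 11, "dcl2/3/4": 12, "nrpd1": 13, "rdr2": 14}


@pytest.fixture(scope="session")
def toy_genome() -> GenomeBundle:
    """Small featureless genome for mapper unit tests."""
    import numpy as np

    rng = np.random.default_rng(42)
    return GenomeBundle(
        chromosomes={
            "chrA": "".join(rng.choice(list("ACGT"), size=5000)),
            "chrB": "".join(rng.choice(list("ACGT"), size=3000)),
        }
    )


def _run_study(seed: int, params: SimParams):
    genome = simulate_genome(2, 80_000, LocusPlan(), seed=seed)
    catalog = build_catalog(genome, params)
    index = build_index(genome, k=7)
    sims, tables = {}, {}
    for genotype, gs in GENOTYPE_SEEDS.items():
        sim = simulate_sample(
            genotype, genome, params, seed=seed * 1000 + gs, catalog=catalog
        )
        sims[genotype] = sim
        table, _ = build_species_table(
            sim.reads, index, SampleMeta(genotype, genotype)
        )
        tables[genotype] = exclude_stage1(table, genome.features)
    normalize(list(tables.values()))
    tables = {g: exclude_stage2(t, genome.features) for g, t in tables.items()}
    return dict(genome=genome, params=params, catalog=catalog, index=index,
                sims=sims, tables=tables)


@pytest.fixture(scope="session")
def study():
    """Default simulation at study conditions (~200 loci, depth 50k)."""
    return _run_study(STUDY_SEED, SimParams(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def clean_study():
    """Same study with sequencing error and orphan siRNAs switched off
    (for exact truth-recovery and false-positive checks)."""
    params = SimParams(seed=STUDY_SEED, error_rate=0.0, orphan_sirna_rate=0.0)
    return _run_study(STUDY_SEED, params)
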