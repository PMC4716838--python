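"""End-to-end orchestration: simulate -> align -> tabulate -> analyses.

A single validated configuration drives every stage; all stage seeds are
derived deterministically from the global seed, so a (config, seed) pair
fully determines every output file and the summary JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from pydantic import BaseModel, Field, field_validator

from ._util import derive_seed
from .align import build_index
from .biogenesis import GENOTYPES, SimParams, build_catalog, canonical_genotype, simulate_sample
from .ends import end_offsets, overlap_fraction, terminal_freq
from .genome import GenomeBundle, LocusPlan, simulate_genome, write_sirna_loci
from .loci import CallThresholds, detect_intervals, write_bed6
from .mismatch import background_subtract, mismatch_matrix, terminal_mismatch_fraction
from .profiles import size_profile
from .species import (
    SampleMeta,
    SpeciesTable,
    build_species_table,
    exclude_stage1,
    exclude_stage2,
    normalize,
    threshold,
)

log = logging.getLogger(__name__)

HEADLINE_KEYS = (
    "p4r2_modal_length",
    "sirna_5p_A_freq",
    "offset5_zero_share",
    "offset3_zero_share",
    "overlap_fraction_pct",
    "terminal_mismatch_pct",
    "n_called_intervals",
)


class GenomeConfig(BaseModel):
    n_chrom: int = 2
    chrom_len: int = 80_000
    silent_locus_rate: float = 0.03
    locus_plan: dict = Field(default_factory=dict)


class SampleConfig(BaseModel):
    genotype: str
    replicates: int = 1

    @field_validator("genotype")
    @classmethod
    def _known_genotype(cls, v: str) -> str:
        return canonical_genotype(v)


class AlignConfig(BaseModel):
    k: int = 7
    max_mm: int = 1
    max_hits: int = 50


class RunConfig(BaseModel):
    """Schema for `run_pipeline`; unknown fields are rejected."""

    model_config = {"extra": "forbid"}

    seed: int = 0
    outdir: str = "results/run"
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    sim: dict = Field(default_factory=dict)  # SimParams field overrides
    samples: list[SampleConfig] = Field(
        default_factory=lambda: [SampleConfig(genotype=g, replicates=2) for g in GENOTYPES]
    )
    align: AlignConfig = Field(default_factory=AlignConfig)
    window: int = 100
    thresholds: dict = Field(default_factory=dict)
    min_norm: float = 5.0
    write_fastq: bool = True

    @field_validator("sim")
    @classmethod
    def _sim_fields(cls, v: dict) -> dict:
        known = set(SimParams.__dataclass_fields__)
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown sim parameter(s): {sorted(unknown)}")
        return v


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the headline summary dict.

    Writes genome FASTA/GFF3, per-sample FASTQ and truth tables, species
    tables, analysis TSVs, the interval BED and `summary.json` under
    `config.outdir`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    # --- simulate
    plan = LocusPlan(**config.genome.locus_plan)
    genome = simulate_genome(
        config.genome.n_chrom, config.genome.chrom_len, plan,
        seed=derive_seed(seed, "genome"),
        silent_locus_rate=config.genome.silent_locus_rate,
    )
    genome.write_fasta(outdir / "genome.fa")
    genome.write_gff3(outdir / "annotation.gff3")
    write_sirna_loci(genome.sirna_loci, outdir / "sirna_loci_truth.tsv")

    params = SimParams(**{**config.sim, "seed": derive_seed(seed, "catalog")})
    catalog = build_catalog(genome, params)
    with open(outdir / "config_echo.json", "w") as fh:
        fh.write(config.model_dump_json(indent=2))

    index = build_index(genome, k=config.align.k)

    tables: dict[tuple[str, int], SpeciesTable] = {}
    for sc in config.samples:
        for rep in range(1, sc.replicates + 1):
            sample_id = f"{sc.genotype.replace('/', '')}_rep{rep}"
            sim = simulate_sample(
                sc.genotype, genome, params,
                seed=derive_seed(seed, "sample", sample_id),
                catalog=catalog, replicate=rep,
            )
            if config.write_fastq:
                sim.write_fastq(outdir / f"{sample_id}.fastq")
                sim.write_truth(outdir / f"{sample_id}.truth.tsv")
            meta = SampleMeta(sample_id=sample_id, genotype=sc.genotype, replicate=rep)
            table, stats = build_species_table(
                sim.reads, index, meta,
                max_mm=config.align.max_mm, max_hits=config.align.max_hits,
            )
            log.info("%s: %d species, %d unmapped, %d skipped",
                     sample_id, len(table), stats.n_unmapped, stats.n_skipped)
            tables[(sc.genotype, rep)] = exclude_stage1(table, genome.features)

    normalize(list(tables.values()))
    tables = {k: exclude_stage2(t, genome.features) for k, t in tables.items()}

    # --- analyses (first replicate of each genotype as the focal sample)
    col0 = tables[("Col-0", 1)]
    dcl = tables[("dcl2/3/4", 1)]
    col0_thr = threshold(col0, config.min_norm)
    dcl_thr = threshold(dcl, config.min_norm)

    profile = size_profile(dcl_thr)
    profile.to_csv(outdir / "size_profile_dcl234.tsv", sep="\t")
    p4r2_rows = profile.loc[26:]
    modal_length = int(p4r2_rows["total"].idxmax()) if p4r2_rows["total"].sum() else 0

    sirna_freq = terminal_freq(col0_thr, "five_prime", size_filter=(20, 25))

    sirna_universe = col0.subset(
        col0.df.index[(col0.df["length"] == 24) & (col0.df["norm"] >= config.min_norm)]
    )
    p4r2_universe = dcl.subset(dcl.df.index[dcl.df["length"] >= 26])
    off5 = end_offsets(p4r2_universe, sirna_universe, "five_prime")
    off3 = end_offsets(p4r2_universe, sirna_universe, "three_prime")
    off5.write_tsv(outdir / "offsets_5p.tsv")
    off3.write_tsv(outdir / "offsets_3p.tsv")
    frac, breakdown = overlap_fraction(dcl, col0, min_sirna_reads=config.min_norm)

    mm_seed = derive_seed(seed, "mismatch")
    mat_dcl = mismatch_matrix(dcl, seed=mm_seed)
    mat_wt = mismatch_matrix(col0, seed=mm_seed)
    background_subtract(mat_dcl, mat_wt).write_tsv(outdir / "mismatch_matrix_sub.tsv")
    mat_dcl.write_tsv(outdir / "mismatch_matrix_dcl234.tsv")
    terminal_pct = terminal_mismatch_fraction(dcl, seed=mm_seed)

    chrom_lengths = {c: len(s) for c, s in genome.chromosomes.items()}
    calls = detect_intervals(
        tables, chrom_lengths, window=config.window,
        thresholds=CallThresholds(**config.thresholds),
    )
    calls.to_csv(outdir / "interval_calls.tsv", sep="\t", index=False)
    if len(calls):
        write_bed6(calls, outdir / "interval_calls.bed")

    summary = {
        "p4r2_modal_length": modal_length,
        "sirna_5p_A_freq": round(sirna_freq["A"], 4),
        "offset5_zero_share": round(off5.counts.get(0, 0.0) / off5.total, 4) if off5.total else 0.0,
        "offset3_zero_share": round(off3.counts.get(0, 0.0) / off3.total, 4) if off3.total else 0.0,
        "overlap_fraction_pct": round(100.0 * frac, 2),
        "terminal_mismatch_pct": round(terminal_pct, 2),
        "n_called_intervals": int(calls["called"].sum()) if len(calls) else 0,
        "overlap_breakdown": breakdown,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
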