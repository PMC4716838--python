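"""Simulate the study: genome, annotation, and eight small-RNA libraries.

Writes genome.fa / annotation.gff3 / siRNA-locus truth and one FASTQ +
truth table per (genotype, replicate) under scratch/analysis/sim.
The catalogue of precursor species is drawn once and shared by all
genotypes, so the same transcription units underlie every library.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from p4r2scan._util import derive_seed
from p4r2scan.biogenesis import SimParams, build_catalog, simulate_sample
from p4r2scan.genome import LocusPlan, simulate_genome, write_sirna_loci


def main() -> None:
    out = cfg.SCRATCH / "sim"
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(2, 80_000, LocusPlan(), seed=derive_seed(cfg.SEED, "genome"))
    genome.write_fasta(out / "genome.fa")
    genome.write_gff3(out / "annotation.gff3")
    write_sirna_loci(genome.sirna_loci, out / "sirna_loci_truth.tsv")
    print(f"genome: {sum(len(s) for s in genome.chromosomes.values()):,} bp, "
          f"{len(genome.features)} features, {len(genome.sirna_loci)} siRNA loci "
          f"({sum(not l.coupled for l in genome.sirna_loci)} silent in wild type)")

    params = SimParams(seed=derive_seed(cfg.SEED, "catalog"), depth=cfg.DEPTH)
    catalog = build_catalog(genome, params)
    print(f"catalogue: {len(catalog.duplexes)} precursor duplex species, "
          f"{len(catalog.orphans)} orphan siRNAs, {len(catalog.mirnas)} miRNAs")

    for genotype in cfg.GENOTYPES:
        for rep in range(1, cfg.REPLICATES + 1):
            sid = cfg.sample_id(genotype, rep)
            sim = simulate_sample(genotype, genome, params,
                                  seed=derive_seed(cfg.SEED, "sample", sid),
                                  catalog=catalog, replicate=rep)
            sim.write_fastq(out / f"{sid}.fastq")
            sim.write_truth(out / f"{sid}.truth.tsv")
            n_p4 = int((sim.truth["kind"] == "p4r2").sum())
            n_si = int((sim.truth["kind"] == "sirna").sum())
            print(f"  {sid}: {len(sim.reads):,} reads; "
                  f"{n_p4} precursor and {n_si} siRNA truth species")


if __name__ == "__main__":
    main()
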