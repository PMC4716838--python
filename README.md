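# p4r2scan

Simulation and analysis of Pol IV/RDR2-dependent siRNA precursors
(P4R2 RNAs) and 24 nt siRNAs in *Arabidopsis*-style small-RNA
sequencing data.

In plants, 24 nt small interfering RNAs guide RNA-directed DNA
methylation. Their precursors — P4R2 RNAs — are short (mostly 26–45 nt)
transcripts made by RNA polymerase IV and copied into blunt duplexes by
RDR2, which also adds occasional untemplated 3' nucleotides. DCL3 cuts
each duplex **once**, 24 nt measured from a 5' adenosine on whichever
strand provides one, so siRNAs coincide with either the 5' or the 3'
end of their precursor. This package implements both sides of that
picture, for bioinformaticians who want a fully testable version of the
analysis without downloading an accession:

* **a generative simulator** — synthetic genomes with annotated feature
  classes and a sequence-identical 5S-like tandem array; per-genotype
  libraries (Col-0, *dcl2/3/4*, *nrpd1*, *rdr2*) under the
  pyrimidine–purine initiation rule, negative-binomial length models,
  5'-base-conditioned 3' ends, terminal-transferase tails, and the
  A-register dicing rule; plus in vitro Pol IV / Pol II transcription on
  a 7,249 nt circular single-stranded template — with complete ground
  truth;
* **the analysis pipeline** — an exact ≤1-mismatch best-stratum
  ≤50-hit read mapper (with a SAM/NM/MD ingest path for external
  mappers), unique-species tables with staged contaminant exclusions and
  scale-to-deepest normalization, size profiles, terminal-nucleotide and
  ±3 nt genomic-context consensus matrices, precursor/siRNA end-offset
  histograms, the encompass/overlap statistic, per-length × per-position
  3'-mismatch matrices with background subtraction, and genotype-contrast
  100 bp interval calls.

## Worked example

Simulate the default study (two 80 kb chromosomes, ~200 siRNA loci,
50,000 reads per library), map the *dcl2/3/4* and wild-type libraries,
and compute the two headline statistics:

```python
from p4r2scan import (SampleMeta, SimParams, build_catalog, build_index,
                      exclude_stage1, exclude_stage2, normalize,
                      build_species_table, overlap_fraction,
                      simulate_genome, simulate_sample, terminal_mismatch_fraction)
from p4r2scan.genome import LocusPlan

genome = simulate_genome(2, 80_000, LocusPlan(), seed=1)
params = SimParams(seed=1)
catalog = build_catalog(genome, params)
index = build_index(genome, k=7)

tables = {}
for genotype, seed in [("dcl2/3/4", 11), ("Col-0", 12)]:
    sim = simulate_sample(genotype, genome, params, seed=seed, catalog=catalog)
    table, _ = build_species_table(sim.reads, index, SampleMeta(genotype, genotype))
    tables[genotype] = exclude_stage1(table, genome.features)
normalize(list(tables.values()))
tables = {g: exclude_stage2(t, genome.features) for g, t in tables.items()}

frac, breakdown = overlap_fraction(tables["dcl2/3/4"], tables["Col-0"])
print(f"overlap: {100 * frac:.2f}%  {breakdown}")
print(f"terminal mismatch: {terminal_mismatch_fraction(tables['dcl2/3/4'], seed=5):.2f}%")
```

```
overlap: 95.68%  {'encompass': 1544, 'partial': 8, 'none': 70}
terminal mismatch: 4.93%
```

95.7% of precursor species sequenced in the dicing-deficient mutant
encompass or overlap a 24 nt siRNA represented by ≥5 normalized reads in
wild type — the spatial correspondence expected if siRNAs are cut from
precursor ends. And 4.9% of precursor species carry their single
mismatch at the 3'-terminal read position, the sequence footprint of
RDR2's untemplated (C-rich) 3' additions at its ~5% observable rate.

The full analysis is organized as numbered drivers:

```bash
python analysis/01_simulate.py      # genome + 8 libraries (FASTQ + truth)
python analysis/02_align.py         # map everything, write SAM
python analysis/03_tabulate.py      # species tables, exclusions, normalization
python analysis/04_size_profiles.py # size classes per genotype
python analysis/05_end_analysis.py  # 5'/3' consensus, offsets, overlap
python analysis/06_mismatch.py      # 3'-mismatch matrices
python analysis/07_locus_calls.py   # genotype-contrast interval calls
python analysis/08_invitro.py       # circular-template transcription
```

Each driver prints what it found and writes tables under
`results/analysis/` (bulky intermediates go to `scratch/`). There is
also a thin CLI (`p4r2scan simulate|align|tabulate|simulate-invitro|run`)
over the same library, and `p4r2scan run --config cfg.json` executes the
whole pipeline from one validated JSON config.

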