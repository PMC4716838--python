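# Methods

`p4r2scan` couples a generative model of 24 nt siRNA biogenesis in
*Arabidopsis* with the analysis pipeline used to characterize the
pathway from size-selected small-RNA sequencing. This note documents the
model, its parameters and calibrations, the numerical choices, and what
the simulation-based tests do and do not establish about real data.

## The biogenesis model

The model follows the short-precursor, single-dicing view of
RNA-directed DNA methylation:

1. **Initiation.** Pol IV initiates at a genomic position whose
   (−1, +1) dinucleotide context is drawn with probability proportional
   to a 16-entry weight table. The default weights encode the
   pyrimidine–purine rule with a specific preference for T at −1:
   (T, purine) = 1.0, (C, purine) = 0.5, all other contexts 0.08. The
   off-consensus weights are deliberately nonzero — initiation-context
   logos show dominance, not exclusivity — and they also keep the
   in vitro start-site occupancy realistic (thousands of distinct starts
   on a 7.2 kb circle). A and G at +1 are weighted equally, matching the
   observed ~50/50 split of precursor 5' purines.

2. **Elongation and termination.** Templated length is drawn from a
   shifted negative binomial, `L = min + NB(mean − min, k)`, resampled
   while `L > max`. One right-skewed family covers every context:

   | context | mean | dispersion k | range |
   |---|---|---|---|
   | in vivo precursor | 30 | 3.0 | 26–45 nt |
   | 5S-array preset | 30 | 3.0 | 26–42 nt |
   | in vitro Pol IV | 44 | 1.2 | 15–2000 nt |
   | in vitro Pol II | 85 | 1.2 | 15–2000 nt |

   The low dispersion of the in vitro models produces the strong right
   skew that separates mean from median (Pol IV 44 vs ~37 nt, Pol II 85
   vs ~68 nt). After the length draw, the 3' end is re-drawn among
   candidates within ±2 nt so the terminal templated base follows the
   5'-base-conditioned preference: 5'-A precursors end U > A > C (the
   weak ...ACU motif), 5'-G precursors end U > C > A. If no candidate
   has weight the drawn length stands. The in vitro Pol IV profile
   applies an analogous ±2 re-draw favouring an A at the template
   position immediately past the 3' end (weight 10 : 1).

3. **Second-strand synthesis and terminal transfer.** Each precursor is
   a blunt duplex; the complementary (RDR2) strand is the reverse
   complement of the templated portion. Either strand independently
   acquires an untemplated 3' tail with probability `tt_rate`; tails are
   1 nt (90%) or 2 nt (10%) and composed of C, the addition demonstrated
   in vitro (composition configurable — the in vivo composition is not
   known).

4. **Dicing.** DCL3 cuts each duplex once. The register is measured
   from a 5' adenosine: top strand starting with A → product anchored at
   the precursor 5' end; bottom strand starting with A (equivalently,
   top strand ending in U) → product anchored at the templated 3' end;
   both → a fair coin; neither → a uniformly chosen end. The product
   length is 24 nt (75%) or 23 nt (25%) per dicing event; duplexes
   shorter than `dicing_len + 1` are not cut. Each diced read reports
   one strand of the product duplex (chosen 50/50), so both strand
   species exist in wild type — consistent with the ribonuclease
   evidence that the siRNA pool is largely double-stranded, and
   necessary for both precursor strands to have same-strand siRNA
   partners.

5. **Genotypes.** The species catalogue (which duplexes exist, where,
   with which tails and abundances) is drawn once per genome and shared
   by all genotypes; genotype only changes processing. dcl2/3/4
   sequences every duplex undiced (both strands, 50/50); Col-0 dices a
   `dice_through_prob = 0.9` fraction of duplex reads at coupled loci
   and retains the residual as wild-type-detectable precursor signal;
   nrpd1 and rdr2 produce neither precursors nor siRNAs, their depth
   filled with short (15–20 nt) gene-derived degradation fragments so
   library totals stay comparable across genotypes. All libraries carry
   a constant 21 nt miRNA background (15% of reads) from gene loci and
   contaminant fragments from 45S/organellar (5%) and tRNA/sn(o)RNA (3%)
   features to exercise the staged exclusions. Reads receive uniform
   per-base substitution errors (default 2×10⁻⁴, a post-quality-filter
   Illumina-like rate) and are size-selected to 15–94 nt.

### Calibrated defaults

Two defaults are calibrated analytically to observed quantities rather
than set directly, because the observable is downstream of the
mechanism:

* **`tt_rate` ≈ 0.065.** The observable is the fraction of mapped
  precursor species whose single mismatch sits at the 3'-terminal read
  position (~5% in vivo). A C tail is invisible when the adjacent
  genomic base happens to be C, and a 2 nt tail mismatching at both
  positions makes the read unmappable under the ≤1-mismatch policy.
  Moreover the two strands differ: the base past the *bottom* strand's
  3' end is the complement of the top strand's −1 initiation context,
  which the T-at-−1 rule biases away from C, so bottom-strand tails are
  visible more often than top-strand ones. `default_tt_rate()` inverts
  the closed-form visible fraction (strand-averaged) so the expected
  observed fraction equals 5%.

* **Catalogue shape.** ~3 duplex species per 300 bp locus
  (1 + Poisson(2)), 100 species at the 5S-like tandem array, lognormal
  abundance spread σ = 0.3, and a 3% rate of loci silent in wild type.
  At 50,000 reads per library these choices make the expected loss from
  the ≥5-read wild-type siRNA filter ~1%, which together with silent
  loci reproduces the ~96% precursor/siRNA overlap statistic. The
  calibration was done on paper from the read-budget arithmetic, then
  verified.

Tails are assigned per catalogued species, not per sequenced molecule.
Per-molecule tails would give every abundant species a low-count tailed
twin, and the species-level mismatch fraction would then depend on the
abundance distribution rather than on the addition rate; real data,
dominated by singleton species, do not distinguish the two conventions,
but desk-scale simulations with concentrated abundances do.

## The analysis pipeline

* **Mapping.** End-to-end, ≤1 mismatch, best stratum (perfect hits
  suppress one-mismatch hits), at most 50 mappings reported in
  deterministic (chrom, start, strand) order with a truncation flag.
  The seed-and-extend index uses two *outer* seeds of k = 7, which makes
  the policy exact down to the 15 nt minimum read length (one of two
  non-overlapping seeds must be mismatch-free); k = 8 would require
  ≥16 nt reads. Reads with N are skipped and counted. Equivalence with
  an independent brute-force scanner is asserted in the tests.
  Externally mapped SAM/BAM with NM/MD tags can be ingested instead;
  NM > 1 records are dropped and counted.

* **Species tables.** Reads collapse to unique sequences (each distinct
  sequence is aligned once). The pipeline order is fixed: stage-1
  exclusion (45S rRNA, chloroplast, mitochondrion; any-overlap ≥1 nt
  over any mapping) → normalization (divide by the sample's surviving
  mapped total, multiply by the maximum total across samples; the
  deepest library is unchanged) → stage-2 exclusion (tRNA, snRNA,
  snoRNA; normalization not recomputed) → inclusive ≥5 normalized-read
  threshold where an analysis calls for it.

* **End statistics.** All end logic is transcript-oriented (the 5' end
  of a minus-strand alignment is its highest genomic coordinate).
  Offsets are signed so that a precursor end *upstream* of the siRNA end
  is negative. Overlap, offset and logo computations take one mapping
  per species chosen by a seeded RNG shared between the logo and
  mismatch modules. Opposite-strand precursor/siRNA pairs are excluded
  from offsets (a 5'-to-5' distance across strands is ill-defined).
  Context logos read every position, including the read-covered ones,
  from the genome at the selected mapping, ±3 nt.

* **Mismatch profiles.** Read-weighted per-(length, position)
  frequencies in percent; the 3'-terminal summary is species-weighted
  (with a read-weighted variant emitted alongside) over species ≥26 nt.
  Background subtraction is cellwise with negatives clamped to zero by
  default; the signed matrix is always available.

* **Interval calls.** Non-overlapping 100 bp windows; per-window
  abundance sums fractionally weighted normalized counts (norm /
  n_mappings per mapping) of 24 nt siRNAs and 26–94 nt precursors. A
  window is called when Col-0 siRNA signal ≥1, Col-0 precursor signal
  ≥1, and both nrpd1 and rdr2 precursor signals are ≤25% of the mean
  dcl2/3/4 signal in at least one replicate. Elevation in dcl2/3/4 is
  reported but not required. Raising the depletion stringency can only
  shrink the call set.

## Problem sizes

The default study simulates a two-chromosome 160 kb genome with ~200
siRNA loci (one of them a 3 × 500 bp sequence-identical 5S-like tandem
array, a deliberate multimapping case) and 50,000 reads per library —
the scale at which the calibrated statistics (96% overlap, 5% terminal
mismatch, 30 nt 5S mean) hold with comfortable sampling margins. The
numbered drivers under `analysis/` and the acceptance script both run at
this scale; the in vitro analyses use n = 10,000 transcripts on a
7,249 nt circular template.

## What the simulations do not show

* The generator emulates the *statistical structure* of the study's
  libraries (genotype-dependent size classes, end consensus,
  terminal-transferase mismatches, multimapping repeats), not
  Arabidopsis sequence. Headline counts from the real accession
  (millions of unique species, ≥5500 genome-wide intervals) are not
  reproducible at desk scale and are not targeted.
* Wild-type background subtraction of the mismatch matrix behaves
  differently here than on real data: the simulated wild-type ≥26 nt
  pool consists entirely of residual precursors carrying tails at the
  same rate, so subtraction cancels the terminal signal. In real
  libraries the wild-type long-RNA pool is dominated by non-precursor
  RNAs and the subtraction isolates sequencing error. The band-structure
  test therefore uses a tail-free control simulation; the raw dcl2/3/4
  matrix shows the terminal band directly. Relatedly, the band test
  covers rows 27–37: row 26 is the templated length floor, so the
  shortest read that can carry a tail mismatch is 27 nt.
* Sequencing error is uniform per-base substitution; no quality-score,
  indel, or position-dependent error structure.
* No DNA methylation, AGO4 loading, Pol V transcription or chromatin
  feedback — the model stops at precursor biogenesis and dicing.
* The +2 A/U preference visible in real precursor logos is not modelled
  (initiation weights condition on −1/+1 only).

## Reproducibility

Every stochastic step draws from a `numpy` Generator derived from a
single run seed plus a stage tag (CRC-hashed), so runs are
deterministic end to end, stages are decoupled, and replicates differ
only by their library seed. Fixed seeds yield byte-identical FASTA,
GFF3 and FASTQ output; the test suite asserts this.
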