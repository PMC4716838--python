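"""Generative model of P4R2 RNA / 24 nt siRNA biogenesis.

The model implemented here follows the short-precursor, single-dicing
view of RNA-directed DNA methylation in Arabidopsis:

* Pol IV initiates with a purine at +1, preferentially preceded by a
  pyrimidine at -1 in the corresponding DNA strand (the pyrimidine-purine
  rule), and terminates after a short, right-skewed number of nucleotides
  (mostly 26-45 nt in vivo).
* The templated 3' terminal base depends on the 5' base: 5'-A precursors
  favour a 3' ...ACU motif (terminal U > A), 5'-G precursors favour a
  terminal U > C > A, so their RDR2-made complements begin with A.
* RDR2 copies the transcript into a blunt duplex and, acting as a
  terminal transferase, occasionally appends one or two untemplated
  (C-rich) nucleotides to 3' ends.
* DCL3 cuts each duplex once, 24 nt measured from a 5' adenosine on
  whichever strand provides one, releasing the siRNA from the 5' end or
  the 3' end of the precursor.

Genotypes differ only in which stages run: dcl2/3/4 accumulates undiced
duplexes, Col-0 dices most of them, and nrpd1 / rdr2 make neither
precursors nor siRNAs. A constant DCL1-dependent 21 nt miRNA background
and small contaminant classes (45S/organellar, tRNA/sn(o)RNA) are added
to every genotype so the downstream filters have something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._util import BASES, PURINES, PYRIMIDINES, revcomp, stage_rng
from .genome import (
    STAGE1_CATEGORIES,
    STAGE2_CATEGORIES,
    GenomeBundle,
    SirnaLocus,
)

GENOTYPES = ("Col-0", "dcl2/3/4", "nrpd1", "rdr2")

_ALIASES = {
    "col-0": "Col-0", "col0": "Col-0", "wt": "Col-0",
    "dcl2/3/4": "dcl2/3/4", "dcl234": "dcl2/3/4",
    "nrpd1": "nrpd1", "pol iv": "nrpd1", "poliv": "nrpd1",
    "rdr2": "rdr2",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def canonical_genotype(genotype: str) -> str:
    try:
        return _ALIASES[genotype.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {GENOTYPES}"
        ) from None


# --------------------------------------------------------------------------- params
@dataclass(frozen=True)
class LengthModel:
    """Shifted negative-binomial transcript length distribution.

    L = min + NB(mean - min, dispersion), resampled while L > max.  One
    right-skewed family covers the in vivo precursor band (mean 30,
    26-45 nt), the 5S-locus band (26-42 nt) and the in vitro profiles
    (Pol IV mean 44 / median ~37; Pol II mean 85 / median ~68).
    """

    mean: float
    dispersion: float
    min: int
    max: int

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"need min <= mean <= max, got {self}")

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        mu = self.mean - self.min
        if mu <= 0:
            return np.full(n, self.min)
        k = self.dispersion
        p = k / (k + mu)
        out = self.min + rng.negative_binomial(k, p, size=n)
        while True:
            bad = out > self.max
            if not bad.any():
                return out
            out[bad] = self.min + rng.negative_binomial(k, p, size=int(bad.sum()))


def default_initiation_weights(
    t_weight: float = 1.0, c_weight: float = 0.5, other: float = 0.08
) -> dict:
    """(-1 base, +1 base) -> weight.

    Initiation favours a purine at +1 preceded by a pyrimidine at -1,
    with T preferred over C at -1 (the 5' purine is preferentially
    preceded by a T in the genomic sequence); A and G at +1 are weighted
    equally.
    """
    w = {}
    for prev in BASES:
        for base in BASES:
            if base in PURINES and prev == "T":
                w[(prev, base)] = t_weight
            elif base in PURINES and prev == "C":
                w[(prev, base)] = c_weight
            else:
                w[(prev, base)] = other
    return w


def default_end3_weights() -> dict:
    """5' base -> templated 3' base -> weight (DNA alphabet; T stands for U)."""
    uniform = {b: 0.25 for b in BASES}
    return {
        "A": {"T": 0.40, "A": 0.25, "C": 0.20, "G": 0.15},  # ...ACU motif: U > A > C
        "G": {"T": 0.45, "C": 0.25, "A": 0.15, "G": 0.15},  # U > C > A
        "C": dict(uniform),
        "T": dict(uniform),
    }


def tt_visibility(
    tail_len_weights: dict[int, float],
    tail_base_weights: dict[str, float],
    initiation_weights: dict | None = None,
) -> tuple[float, float]:
    """(visible, dropped) fractions of tailed strand species.

    A tail base coincidentally equal to the next genomic base produces no
    mismatch; a 2-nt tail mismatching at both positions exceeds the
    1-mismatch mapping policy and the read is lost.  `visible` is the
    probability that a tailed species shows exactly one mismatch at its
    3'-terminal read position, `dropped` that it is unmappable.

    The base beyond the top strand's 3' end is uniform in a random
    genome, but the base beyond the *bottom* strand's 3' end is the
    complement of the top strand's -1 initiation context, which the
    pyrimidine-purine rule biases away from C; both strands are averaged.
    """
    wl = {k: v / sum(tail_len_weights.values()) for k, v in tail_len_weights.items()}
    wb = {k: v / sum(tail_base_weights.values()) for k, v in tail_base_weights.items()}
    iw = initiation_weights or default_initiation_weights()
    total = sum(iw.values())
    # P(-1 context base = p | site selected), uniform genome
    p_prev = {p: sum(iw[(p, b)] for b in BASES) / total for p in BASES}
    p_match_top = sum(w * 0.25 for w in wb.values())
    p_match_bottom = sum(w * p_prev[_COMP[b]] for b, w in wb.items())
    visible = dropped = 0.0
    for p_match1 in (p_match_top, p_match_bottom):
        p_mm1 = 1.0 - p_match1
        visible += 0.5 * (wl.get(1, 0.0) * p_mm1 + wl.get(2, 0.0) * p_match1 * 0.75)
        dropped += 0.5 * wl.get(2, 0.0) * p_mm1 * 0.75
    return visible, dropped


def default_tt_rate(
    observed_terminal_fraction: float = 0.05,
    tail_len_weights: dict[int, float] | None = None,
    tail_base_weights: dict[str, float] | None = None,
    initiation_weights: dict | None = None,
) -> float:
    """Underlying untemplated-addition rate giving a target *observed* fraction.

    The observable quantity is the fraction of mapped precursor species
    whose single mismatch sits at the 3'-terminal position (~5% in vivo);
    the underlying addition rate must be higher because coincidental
    matches hide tails and double-mismatch tails are unmappable.  Solves
    r * visible / (1 - r * dropped) = target.
    """
    visible, dropped = tt_visibility(
        tail_len_weights or {1: 0.9, 2: 0.1},
        tail_base_weights or {"C": 1.0},
        initiation_weights,
    )
    return observed_terminal_fraction / (visible + observed_terminal_fraction * dropped)


def _default_length_models() -> dict[str, LengthModel]:
    return {
        "in_vivo": LengthModel(mean=30.0, dispersion=3.0, min=26, max=45),
        "fiveS": LengthModel(mean=30.0, dispersion=3.0, min=26, max=42),
        "invitro_polIV": LengthModel(mean=44.0, dispersion=1.2, min=15, max=2000),
        "invitro_polII": LengthModel(mean=85.0, dispersion=1.2, min=15, max=2000),
    }


@dataclass
class SimParams:
    """All tunable parameters of the biogenesis simulator.

    Defaults encode the study conditions: precursor sizes mostly 26-45 nt
    peaking near 30, purine starts split ~50/50 between A and G, ~5% of
    precursors with visible untemplated 3' nucleotides, 24 nt (75%) and
    23 nt (25%) dicing products, and 50,000 reads per library.
    """

    initiation_weights: dict = field(default_factory=default_initiation_weights)
    length_models: dict = field(default_factory=_default_length_models)
    end3_weights_by_start: dict = field(default_factory=default_end3_weights)
    tt_rate: float = field(default_factory=default_tt_rate)
    tt_tail_len_weights: dict = field(default_factory=lambda: {1: 0.9, 2: 0.1})
    tt_tail_base_weights: dict = field(default_factory=lambda: {"C": 1.0})
    dicing_len: int = 24
    dicing_register_base: str = "A"
    sirna_len_weights: dict = field(default_factory=lambda: {24: 0.75, 23: 0.25})
    dice_through_prob: float = 0.9
    orphan_sirna_rate: float = 0.04
    emit_both_sirna_strands: bool = True
    depth: int = 50_000
    error_rate: float = 2e-4
    seed: int = 0  # catalogue seed: shared across genotypes of one study
    # read-budget shares
    mirna_share: float = 0.15
    contaminant_share_stage1: float = 0.05
    contaminant_share_stage2: float = 0.03
    # catalogue shape
    species_per_locus_mean: float = 2.0  # Poisson(mean) + 1 duplex species per locus
    fiveS_n_species: int = 100
    n_mirna_species: int = 60
    mirna_len: int = 21
    abundance_sigma: float = 0.3  # lognormal spread of species weights
    n_degradation_species: int = 150

    def validate(self) -> None:
        for prob in (self.tt_rate, self.dice_through_prob, self.orphan_sirna_rate,
                     self.error_rate, self.mirna_share,
                     self.contaminant_share_stage1, self.contaminant_share_stage2):
            if not (0.0 <= prob <= 1.0):
                raise ValueError(f"probability out of [0,1]: {prob}")
        for w in list(self.initiation_weights.values()) + list(
            self.tt_tail_len_weights.values()
        ):
            if w < 0:
                raise ValueError("weights must be non-negative")
        if self.dicing_register_base not in BASES:
            raise ValueError("dicing_register_base must be a DNA base")


# --------------------------------------------------------------------------- types
@dataclass
class P4R2Molecule:
    chrom: str
    strand: str
    start: int  # leftmost genomic coordinate of the templated portion (0-based)
    templated_length: int
    sequence: str  # transcript-oriented, templated only (DNA alphabet)
    tt_tail: str = ""
    diced: bool = False
    id: int = -1

    @property
    def end(self) -> int:
        return self.start + self.templated_length

    @property
    def read_sequence(self) -> str:
        return self.sequence + self.tt_tail

    def duplex_partner(self) -> str:
        """Sequence of the complementary (RDR2) strand, transcript-oriented."""
        return revcomp(self.sequence)


class SiRNATruth(NamedTuple):
    chrom: str
    strand: str
    start: int  # leftmost genomic coordinate, 0-based
    length: int
    parent_p4r2: int
    derivation_end: str  # five_prime | three_prime | orphan


# --------------------------------------------------------------------------- initiation
def _site_weights(
    genome: GenomeBundle,
    chrom: str,
    start: int,
    end: int,
    initiation_weights: dict,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eligible (position, strand, weight) arrays over a locus, both strands.

    Position is the genomic coordinate of the transcript's +1 (5') base.
    On the minus strand the -1 context base lies one coordinate higher.
    """
    seq = genome.chromosomes[chrom]
    positions, strands, weights = [], [], []
    lo = max(start, 1)
    hi = min(end, len(seq) - 1)
    for i in range(lo, hi):
        w = initiation_weights.get((seq[i - 1], seq[i]), 0.0)
        if w > 0:
            positions.append(i)
            strands.append("+")
            weights.append(w)
        wm = initiation_weights.get((_COMP.get(seq[i + 1], "N"), _COMP.get(seq[i], "N")), 0.0)
        if wm > 0:
            positions.append(i)
            strands.append("-")
            weights.append(wm)
    return (
        np.asarray(positions, dtype=int),
        np.asarray(strands, dtype=object),
        np.asarray(weights, dtype=float),
    )


def sample_initiation_site(
    locus: tuple[str, int, int],
    genome: GenomeBundle,
    initiation_weights: dict,
    rng: np.random.Generator,
    n: int = 1,
) -> list[tuple[str, str, int]]:
    """Draw transcription start sites within a locus.

    Returns (chrom, strand, pos) tuples where pos is the genomic
    coordinate of the +1 base; draw probability is proportional to the
    initiation weight of the (-1, +1) dinucleotide context on the
    respective strand.
    """
    chrom, start, end = locus
    pos, strands, w = _site_weights(genome, chrom, start, end, initiation_weights)
    if len(pos) == 0:
        raise ValueError(f"no eligible initiation position in {chrom}:{start}-{end}")
    idx = rng.choice(len(pos), size=n, p=w / w.sum())
    return [(chrom, str(strands[i]), int(pos[i])) for i in idx]


# --------------------------------------------------------------------------- synthesis
def synthesize_p4r2(
    site: tuple[str, str, int],
    genome: GenomeBundle,
    params: SimParams,
    rng: np.random.Generator,
    length_model: str = "in_vivo",
) -> P4R2Molecule:
    """Extend a transcript from an initiation site.

    Length is drawn from the preset model, then adjusted by at most ±2 nt
    so the templated 3' base lands on a base favoured by
    end3_weights_by_start conditioned on the molecule's 5' base (falling
    back to the drawn length when no candidate has weight). With
    probability tt_rate an untemplated C-rich tail of 1-2 nt is appended.
    """
    chrom, strand, pos = site
    seq = genome.chromosomes[chrom]
    model: LengthModel = params.length_models[length_model]
    drawn = int(model.sample(rng, 1)[0])

    five_base = seq[pos] if strand == "+" else _COMP[seq[pos]]
    end3w = params.end3_weights_by_start.get(five_base, {})
    candidates, weights = [], []
    for length in range(max(model.min, drawn - 2), min(model.max, drawn + 2) + 1):
        if strand == "+":
            j = pos + length - 1
            if j >= len(seq):
                continue
            base3 = seq[j]
        else:
            j = pos - length + 1
            if j < 0:
                continue
            base3 = _COMP[seq[j]]
        candidates.append(length)
        weights.append(end3w.get(base3, 0.0))
    if candidates and sum(weights) > 0:
        w = np.asarray(weights) / sum(weights)
        length = int(candidates[int(rng.choice(len(candidates), p=w))])
    else:
        length = drawn

    if strand == "+":
        left = pos
        templated = seq[pos : pos + length]
    else:
        left = pos - length + 1
        templated = revcomp(seq[left : pos + 1])

    tail = ""
    if rng.random() < params.tt_rate:
        lens = sorted(params.tt_tail_len_weights)
        lw = np.array([params.tt_tail_len_weights[l] for l in lens], dtype=float)
        tail_len = int(lens[int(rng.choice(len(lens), p=lw / lw.sum()))])
        tb = sorted(params.tt_tail_base_weights)
        bw = np.array([params.tt_tail_base_weights[b] for b in tb], dtype=float)
        tail = "".join(
            tb[int(i)] for i in rng.choice(len(tb), size=tail_len, p=bw / bw.sum())
        )

    return P4R2Molecule(
        chrom=chrom, strand=strand, start=left,
        templated_length=length, sequence=templated, tt_tail=tail,
    )


# --------------------------------------------------------------------------- dicing
def dice_duplex(
    p4r2: P4R2Molecule,
    params: SimParams,
    rng: np.random.Generator,
    dicing_len: int | None = None,
) -> list[SiRNATruth]:
    """One DCL3 dicing event on a precursor duplex.

    The cut register is measured from a 5' adenosine: if the top strand
    begins with the register base the product is anchored at the
    precursor 5' end; if the bottom strand does (i.e. the top strand ends
    with U), the product is anchored at the templated 3' end. Both
    registers available -> one is chosen at random; neither -> a uniform
    end. Duplexes shorter than dicing_len + 1 are not cut.
    """
    dlen = int(dicing_len if dicing_len is not None else params.dicing_len)
    L = p4r2.templated_length
    if L < dlen + 1:
        return []
    reg = params.dicing_register_base
    top5 = p4r2.sequence[0]
    bottom5 = _COMP[p4r2.sequence[-1]]
    ends = []
    if top5 == reg:
        ends.append("five_prime")
    if bottom5 == reg:
        ends.append("three_prime")
    if not ends:
        ends = ["five_prime", "three_prime"]
    end = ends[0] if len(ends) == 1 else ends[int(rng.integers(len(ends)))]

    if end == "five_prime":
        # product shares the precursor 5' terminus (transcript orientation)
        left = p4r2.start if p4r2.strand == "+" else p4r2.end - dlen
    else:
        # product shares the precursor templated 3' terminus
        left = p4r2.end - dlen if p4r2.strand == "+" else p4r2.start
    sirna = SiRNATruth(
        chrom=p4r2.chrom, strand=p4r2.strand, start=left, length=dlen,
        parent_p4r2=p4r2.id, derivation_end=end,
    )
    _assert_register(p4r2, sirna)
    return [sirna]


def _assert_register(p4r2: P4R2Molecule, s: SiRNATruth) -> None:
    """Derivation-end coordinate invariants, checked on every simulation."""
    if s.derivation_end == "five_prime":
        p5 = p4r2.start if p4r2.strand == "+" else p4r2.end - 1
        s5 = s.start if s.strand == "+" else s.start + s.length - 1
        assert p5 == s5, "five_prime product must share the precursor 5' coordinate"
    elif s.derivation_end == "three_prime":
        p3 = p4r2.end - 1 if p4r2.strand == "+" else p4r2.start
        s3 = s.start + s.length - 1 if s.strand == "+" else s.start
        assert p3 == s3, "three_prime product must share the precursor 3' coordinate"


# --------------------------------------------------------------------------- catalogue
@dataclass
class DuplexSpecies:
    molecule: P4R2Molecule
    bottom_tail: str
    weight: float
    locus_idx: int
    coupled: bool

    def top_read(self) -> str:
        return self.molecule.read_sequence

    def bottom_read(self) -> str:
        return self.molecule.duplex_partner() + self.bottom_tail


class SimpleSpecies(NamedTuple):
    """A non-precursor species (miRNA, orphan siRNA, contaminant, degradation)."""

    chrom: str
    strand: str
    start: int
    length: int
    sequence: str
    weight: float
    kind: str


@dataclass
class Catalog:
    """Per-genome transcription-unit catalogue, shared by all genotypes.

    The catalogue fixes which precursor duplex species exist at which
    loci, with which tails and base abundances; genotype determines how
    they are processed and sampled.
    """

    duplexes: list[DuplexSpecies]
    orphans: list[SimpleSpecies]
    mirnas: list[SimpleSpecies]
    contaminants1: list[SimpleSpecies]
    contaminants2: list[SimpleSpecies]
    degradation: list[SimpleSpecies]


def _random_fragment_species(
    rng, genome, features, n, min_len, max_len, kind
) -> list[SimpleSpecies]:
    out = []
    if not features or n <= 0:
        return out
    for _ in range(n):
        f = features[int(rng.integers(len(features)))]
        length = int(rng.integers(min_len, max_len + 1))
        if f.end - f.start <= length:
            continue
        s = int(rng.integers(f.start, f.end - length))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome.chromosomes[f.chrom][s : s + length]
        if strand == "-":
            seq = revcomp(seq)
        out.append(
            SimpleSpecies(f.chrom, strand, s, length, seq,
                          float(rng.lognormal(0.0, 1.0)), kind)
        )
    return out


def _make_tail(params: SimParams, rng: np.random.Generator) -> str:
    if rng.random() >= params.tt_rate:
        return ""
    lens = sorted(params.tt_tail_len_weights)
    lw = np.array([params.tt_tail_len_weights[l] for l in lens], dtype=float)
    tail_len = int(lens[int(rng.choice(len(lens), p=lw / lw.sum()))])
    tb = sorted(params.tt_tail_base_weights)
    bw = np.array([params.tt_tail_base_weights[b] for b in tb], dtype=float)
    return "".join(tb[int(i)] for i in rng.choice(len(tb), size=tail_len, p=bw / bw.sum()))


def build_catalog(genome: GenomeBundle, params: SimParams) -> Catalog:
    """Draw the fixed species catalogue for a genome (seeded by params.seed)."""
    rng = stage_rng(params.seed, "catalog")
    duplexes: list[DuplexSpecies] = []
    next_id = 0
    for li, locus in enumerate(genome.sirna_loci):
        if locus.preset == "fiveS":
            n_species = params.fiveS_n_species
        else:
            n_species = 1 + int(rng.poisson(params.species_per_locus_mean))
        try:
            sites = sample_initiation_site(
                (locus.chrom, locus.start, locus.end),
                genome, params.initiation_weights, rng, n=n_species,
            )
        except ValueError:
            continue
        for site in sites:
            mol = synthesize_p4r2(site, genome, params, rng, length_model=locus.preset)
            mol.id = next_id
            next_id += 1
            duplexes.append(
                DuplexSpecies(
                    molecule=mol,
                    bottom_tail=_make_tail(params, rng),
                    weight=float(rng.lognormal(0.0, params.abundance_sigma)),
                    locus_idx=li,
                    coupled=locus.coupled,
                )
            )

    # orphan siRNAs: qualifying small RNAs with no sampled parent precursor
    coupled_loci = [l for l in genome.sirna_loci if l.coupled]
    n_orphans = int(round(params.orphan_sirna_rate * len(duplexes)))
    orphans: list[SimpleSpecies] = []
    if coupled_loci and n_orphans:
        total_w = sum(d.weight for d in duplexes) or 1.0
        scale = (
            params.orphan_sirna_rate / max(1e-9, 1.0 - params.orphan_sirna_rate)
            * params.dice_through_prob * total_w / n_orphans
        )
        for _ in range(n_orphans):
            locus = coupled_loci[int(rng.integers(len(coupled_loci)))]
            length = 24
            if locus.end - locus.start <= length:
                continue
            s = int(rng.integers(locus.start, locus.end - length))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome.chromosomes[locus.chrom][s : s + length]
            if strand == "-":
                seq = revcomp(seq)
            orphans.append(
                SimpleSpecies(locus.chrom, strand, s, length, seq,
                              float(rng.lognormal(0.0, params.abundance_sigma)) * scale,
                              "orphan_sirna")
            )

    genes = [f for f in genome.features if f.category == "gene"]
    mirnas = _random_fragment_species(
        rng, genome, genes, params.n_mirna_species,
        params.mirna_len, params.mirna_len, "mirna",
    )
    c1_feats = [f for f in genome.features if f.category in STAGE1_CATEGORIES]
    c2_feats = [f for f in genome.features if f.category in STAGE2_CATEGORIES]
    contaminants1 = _random_fragment_species(rng, genome, c1_feats, 40, 15, 30, "contaminant1")
    contaminants2 = _random_fragment_species(rng, genome, c2_feats, 25, 15, 30, "contaminant2")
    # degradation fragments kept below 21 nt so the miRNA (21), siRNA (23/24)
    # and precursor (>=26) size classes stay diagnostic of the pathway
    degradation = _random_fragment_species(
        rng, genome, genes, params.n_degradation_species, 15, 20, "degradation"
    )
    return Catalog(duplexes, orphans, mirnas, contaminants1, contaminants2, degradation)


# --------------------------------------------------------------------------- sampling
@dataclass
class SimulatedSample:
    genotype: str
    replicate: int
    reads: list[str]
    truth: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.reads):
                fh.write(f"@read{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _mutate_reads(reads: list[str], error_rate: float, rng: np.random.Generator) -> list[str]:
    if error_rate <= 0 or not reads:
        return reads
    lengths = np.fromiter((len(r) for r in reads), dtype=int)
    n_err = rng.binomial(lengths, error_rate)
    hit = np.nonzero(n_err)[0]
    for i in hit:
        s = list(reads[i])
        for pos in rng.choice(len(s), size=int(n_err[i]), replace=False):
            alt = [b for b in BASES if b != s[pos]]
            s[pos] = alt[int(rng.integers(3))]
        reads[i] = "".join(s)
    return reads


def _multinomial_counts(rng, n: int, weights: list[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if n <= 0 or len(w) == 0 or w.sum() <= 0:
        return np.zeros(len(w), dtype=int)
    return rng.multinomial(n, w / w.sum())


def _sirna_read(genome: GenomeBundle, s: SiRNATruth, as_top: bool) -> tuple[str, str]:
    """(sequence, strand) for one sequenced strand of a diced siRNA duplex."""
    seq = genome.chromosomes[s.chrom][s.start : s.start + s.length]
    strand = s.strand
    if strand == "-":
        seq = revcomp(seq)
    if not as_top:
        seq = revcomp(seq)
        strand = "-" if strand == "+" else "+"
    return seq, strand


def simulate_sample(
    genotype: str,
    genome: GenomeBundle,
    params: SimParams,
    seed: int,
    catalog: Catalog | None = None,
    replicate: int = 1,
) -> SimulatedSample:
    """Sequence one size-selected (15-94 nt) small-RNA library.

    The species catalogue is derived from `params.seed` (shared across
    genotypes of a study); `seed` drives per-library sampling, so
    replicates are obtained by varying `seed` only.
    """
    genotype = canonical_genotype(genotype)
    params.validate()
    if catalog is None:
        catalog = build_catalog(genome, params)
    rng = stage_rng(seed, "sample", genotype, str(replicate))

    depth = params.depth
    n_mirna = int(round(depth * params.mirna_share))
    n_c1 = int(round(depth * params.contaminant_share_stage1))
    n_c2 = int(round(depth * params.contaminant_share_stage2))
    n_silencing = depth - n_mirna - n_c1 - n_c2

    reads: list[str] = []
    truth_rows: list[dict] = []

    def emit_simple(species: list[SimpleSpecies], n: int) -> None:
        counts = _multinomial_counts(rng, n, [s.weight for s in species])
        for sp, c in zip(species, counts):
            if c == 0:
                continue
            reads.extend([sp.sequence] * int(c))
            truth_rows.append(dict(
                chrom=sp.chrom, start=sp.start, end=sp.start + sp.length,
                strand=sp.strand, kind=sp.kind, length=sp.length,
                derivation_end="orphan" if sp.kind == "orphan_sirna" else "",
                parent_p4r2=-1, tail_len=0, count=int(c),
            ))

    emit_simple(catalog.mirnas, n_mirna)
    emit_simple(catalog.contaminants1, n_c1)
    emit_simple(catalog.contaminants2, n_c2)

    if genotype in ("nrpd1", "rdr2"):
        # no Pol IV / RDR2 products at all; depth filled with degradation fragments
        emit_simple(catalog.degradation, n_silencing)
    else:
        pool: list = list(catalog.duplexes)
        if genotype == "Col-0":
            pool = pool + list(catalog.orphans)
        counts = _multinomial_counts(
            rng, n_silencing,
            [p.weight if isinstance(p, DuplexSpecies) else p.weight for p in pool],
        )
        slens = sorted(params.sirna_len_weights)
        slw = np.array([params.sirna_len_weights[l] for l in slens], dtype=float)
        slw = slw / slw.sum()
        for sp, m in zip(pool, counts):
            m = int(m)
            if m == 0:
                continue
            if isinstance(sp, SimpleSpecies):  # orphan siRNA
                reads.extend([sp.sequence] * m)
                truth_rows.append(dict(
                    chrom=sp.chrom, start=sp.start, end=sp.start + sp.length,
                    strand=sp.strand, kind="sirna", length=sp.length,
                    derivation_end="orphan", parent_p4r2=-1, tail_len=0, count=m,
                ))
                continue
            mol = sp.molecule
            n_diced = 0
            if genotype == "Col-0" and sp.coupled:
                n_diced = int(rng.binomial(m, params.dice_through_prob))
            # residual (or all, in dcl2/3/4) precursor reads, strands 50/50
            n_resid = m - n_diced
            n_top = int(rng.binomial(n_resid, 0.5))
            sirna_counts: dict[tuple, int] = {}
            for _ in range(n_diced):
                dlen = int(slens[int(rng.choice(len(slens), p=slw))])
                products = dice_duplex(mol, params, rng, dicing_len=dlen)
                if not products:
                    n_top += int(rng.integers(2))  # too short to dice: stays a precursor
                    n_resid += 1
                    continue
                s = products[0]
                as_top = True
                if params.emit_both_sirna_strands:
                    as_top = bool(rng.integers(2))
                seq, strand = _sirna_read(genome, s, as_top)
                reads.append(seq)
                key = (s.chrom, strand, s.start, s.length, s.derivation_end)
                sirna_counts[key] = sirna_counts.get(key, 0) + 1
            for (chrom, strand, start, length, dend), c in sorted(sirna_counts.items()):
                truth_rows.append(dict(
                    chrom=chrom, start=start, end=start + length, strand=strand,
                    kind="sirna", length=length, derivation_end=dend,
                    parent_p4r2=mol.id, tail_len=0, count=c,
                ))
            if n_resid > 0:
                n_bottom = n_resid - n_top
                if n_top:
                    reads.extend([sp.top_read()] * n_top)
                    truth_rows.append(dict(
                        chrom=mol.chrom, start=mol.start, end=mol.end,
                        strand=mol.strand, kind="p4r2",
                        length=len(sp.top_read()), derivation_end="",
                        parent_p4r2=mol.id, tail_len=len(mol.tt_tail), count=n_top,
                    ))
                if n_bottom:
                    bstrand = "-" if mol.strand == "+" else "+"
                    reads.extend([sp.bottom_read()] * n_bottom)
                    truth_rows.append(dict(
                        chrom=mol.chrom, start=mol.start, end=mol.end,
                        strand=bstrand, kind="p4r2",
                        length=len(sp.bottom_read()), derivation_end="",
                        parent_p4r2=mol.id, tail_len=len(sp.bottom_tail), count=n_bottom,
                    ))

    reads = _mutate_reads(reads, params.error_rate, rng)
    reads = [r for r in reads if 15 <= len(r) <= 94]  # size selection
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "strand", "kind", "length",
                 "derivation_end", "parent_p4r2", "tail_len", "count"],
    )
    _check_truth_invariants(genotype, truth)
    return SimulatedSample(genotype=genotype, replicate=replicate, reads=reads, truth=truth)


def _check_truth_invariants(genotype: str, truth: pd.DataFrame) -> None:
    if len(truth) == 0:
        return
    if genotype in ("nrpd1", "rdr2"):
        assert not (truth["kind"].isin(["p4r2", "sirna"])).any(), (
            "knockout genotypes must contain no precursor or siRNA truth"
        )
    if genotype == "dcl2/3/4":
        diced = truth["derivation_end"].isin(["five_prime", "three_prime"])
        assert not diced.any(), "dcl2/3/4 must contain no diced siRNA truth"
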