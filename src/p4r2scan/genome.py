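"""Synthetic genomes with categorized feature annotation.

A simulated genome carries the feature classes the analysis pipeline
filters on (45S rRNA arrays, organellar regions, tRNA/snRNA/snoRNA
decoys), gene space for the DCL1-dependent miRNA background, transposable
elements hosting siRNA-producing loci, and a 5S-like tandem repeat array
whose ~500 bp units are sequence-identical (a deliberate multimapping
stress case). Coordinates are 0-based half-open internally; GFF3 output
is 1-based closed per the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from ._util import BASES, stage_rng

CATEGORIES = frozenset(
    {
        "gene",
        "transposable_element",
        "pseudogene",
        "fiveS_repeat",
        "rRNA_45S",
        "chloroplast",
        "mitochondrion",
        "tRNA",
        "snRNA",
        "snoRNA",
    }
)

#: categories removed before normalization (stage 1) / before genomic analyses (stage 2)
STAGE1_CATEGORIES = frozenset({"rRNA_45S", "chloroplast", "mitochondrion"})
STAGE2_CATEGORIES = frozenset({"tRNA", "snRNA", "snoRNA"})


class Feature(NamedTuple):
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    category: str


class SirnaLocus(NamedTuple):
    """Ground-truth siRNA-producing region (not part of the GFF3 annotation)."""

    chrom: str
    start: int
    end: int
    coupled: bool  # diced into siRNAs in wild type
    preset: str  # length-model preset name ("in_vivo" or "fiveS")


@dataclass
class LocusPlan:
    """Counts and sizes of planned features on the simulated genome."""

    n_sirna_loci: int = 200
    sirna_locus_len: int = 300
    n_gene: int = 30
    gene_len: int = 1200
    n_pseudogene: int = 5
    pseudogene_len: int = 400
    fiveS_units: int = 3
    fiveS_unit_len: int = 500
    n_rrna45S: int = 1
    rrna45S_len: int = 900
    n_chloroplast: int = 1
    chloroplast_len: int = 1500
    n_mitochondrion: int = 1
    mitochondrion_len: int = 1200
    n_trna: int = 8
    trna_len: int = 75
    n_snrna: int = 3
    snrna_len: int = 150
    n_snorna: int = 3
    snorna_len: int = 100

    @classmethod
    def empty(cls) -> "LocusPlan":
        return cls(
            n_sirna_loci=0, n_gene=0, n_pseudogene=0, fiveS_units=0,
            n_rrna45S=0, n_chloroplast=0, n_mitochondrion=0,
            n_trna=0, n_snrna=0, n_snorna=0,
        )


@dataclass
class GenomeBundle:
    chromosomes: dict[str, str]
    features: list[Feature] = field(default_factory=list)
    sirna_loci: list[SirnaLocus] = field(default_factory=list)

    def validate(self) -> None:
        for f in self.features:
            if f.category not in CATEGORIES:
                raise ValueError(f"unknown feature category {f.category!r}")
            if f.chrom not in self.chromosomes:
                raise ValueError(f"feature on unknown chromosome {f.chrom!r}")
            if not (0 <= f.start < f.end <= len(self.chromosomes[f.chrom])):
                raise ValueError(f"feature out of chromosome bounds: {f}")

    # ---------------------------------------------------------------- I/O
    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in self.chromosomes:
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for i, f in enumerate(self.features):
                # GFF3 is 1-based, closed
                fh.write(
                    f"{f.chrom}\tp4r2scan\t{f.category}\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t.\tID=feat{i:05d}\n"
                )

    @classmethod
    def read(cls, fasta: str | Path, gff3: str | Path | None = None) -> "GenomeBundle":
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), as_raw=True, rebuild=True)
        chroms = {name: str(fa[name][:]).upper() for name in fa.keys()}
        features: list[Feature] = []
        if gff3 is not None:
            with open(gff3) as fh:
                for line in fh:
                    if line.startswith("#") or not line.strip():
                        continue
                    c, _, cat, s, e, _, strand, _, _ = line.rstrip("\n").split("\t")
                    if cat in CATEGORIES:
                        features.append(Feature(c, int(s) - 1, int(e), strand, cat))
        return cls(chromosomes=chroms, features=features)


def _place_features(
    rng: np.random.Generator,
    occupied: list[list[tuple[int, int]]],
    chrom_len: int,
    n_chrom: int,
    length: int,
    gap: int = 40,
    max_tries: int = 2000,
) -> tuple[int, int]:
    """Find a non-overlapping slot; returns (chrom index, start)."""
    for _ in range(max_tries):
        ci = int(rng.integers(n_chrom))
        if chrom_len < length:
            break
        start = int(rng.integers(0, chrom_len - length + 1))
        end = start + length
        if all(end + gap <= s or start >= e + gap for s, e in occupied[ci]):
            occupied[ci].append((start, end))
            return ci, start
    raise ValueError(
        f"cannot place feature of length {length} on {n_chrom} chromosome(s) of {chrom_len} bp"
    )


def simulate_genome(
    n_chrom: int,
    chrom_len: int,
    locus_plan: LocusPlan | None = None,
    seed: int = 0,
    silent_locus_rate: float = 0.03,
) -> GenomeBundle:
    """Simulate a genome with planned, non-overlapping features.

    Base composition is uniform outside planned structure; the 5S-like
    array consists of `fiveS_units` identical tandem copies of one random
    unit. A `silent_locus_rate` fraction of siRNA loci is flagged as not
    diced in wild type (loci whose precursors accumulate in dcl2/3/4 but
    lack abundant wild-type siRNAs). Deterministic for a fixed seed.
    """
    plan = locus_plan or LocusPlan()
    rng = stage_rng(seed, "genome")
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = [rng.choice(list(BASES), size=chrom_len) for _ in range(n_chrom)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_chrom)]
    features: list[Feature] = []
    sirna_loci: list[SirnaLocus] = []

    def rand_strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    # 5S-like tandem array: identical units, annotated per unit
    if plan.fiveS_units > 0:
        total = plan.fiveS_units * plan.fiveS_unit_len
        ci, start = _place_features(rng, occupied, chrom_len, n_chrom, total)
        unit = rng.choice(list(BASES), size=plan.fiveS_unit_len)
        for u in range(plan.fiveS_units):
            s = start + u * plan.fiveS_unit_len
            seqs[ci][s : s + plan.fiveS_unit_len] = unit
            features.append(
                Feature(names[ci], s, s + plan.fiveS_unit_len, "+", "fiveS_repeat")
            )
        sirna_loci.append(
            SirnaLocus(names[ci], start, start + total, coupled=True, preset="fiveS")
        )

    simple = [
        ("rRNA_45S", plan.n_rrna45S, plan.rrna45S_len),
        ("chloroplast", plan.n_chloroplast, plan.chloroplast_len),
        ("mitochondrion", plan.n_mitochondrion, plan.mitochondrion_len),
        ("gene", plan.n_gene, plan.gene_len),
        ("pseudogene", plan.n_pseudogene, plan.pseudogene_len),
        ("tRNA", plan.n_trna, plan.trna_len),
        ("snRNA", plan.n_snrna, plan.snrna_len),
        ("snoRNA", plan.n_snorna, plan.snorna_len),
    ]
    for category, count, length in simple:
        for _ in range(count):
            try:
                ci, start = _place_features(rng, occupied, chrom_len, n_chrom, length)
            except ValueError as err:
                raise ValueError(f"{err} (first unplaceable: {category})") from None
            features.append(Feature(names[ci], start, start + length, rand_strand(), category))

    # siRNA loci sit inside transposable elements (TE annotation shares the interval)
    for _ in range(plan.n_sirna_loci):
        try:
            ci, start = _place_features(
                rng, occupied, chrom_len, n_chrom, plan.sirna_locus_len
            )
        except ValueError as err:
            raise ValueError(f"{err} (first unplaceable: siRNA locus)") from None
        end = start + plan.sirna_locus_len
        features.append(Feature(names[ci], start, end, rand_strand(), "transposable_element"))
        sirna_loci.append(
            SirnaLocus(
                names[ci], start, end,
                coupled=bool(rng.random() >= silent_locus_rate),
                preset="in_vivo",
            )
        )

    bundle = GenomeBundle(
        chromosomes={n: "".join(s) for n, s in zip(names, seqs)},
        features=features,
        sirna_loci=sirna_loci,
    )
    bundle.validate()
    return bundle


def write_sirna_loci(loci: list[SirnaLocus], path: str | Path) -> None:
    """Truth siRNA loci as BED-like TSV (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcoupled\tpreset\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{int(l.coupled)}\t{l.preset}\n")
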