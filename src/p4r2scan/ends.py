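"""Terminal-nucleotide statistics, end-anchored genomic-context consensus
matrices, precursor/siRNA end-offset histograms and the overlap statistic.

All end logic is in transcript orientation: the 5' end of a minus-strand
alignment is its highest genomic coordinate, and "upstream" means toward
the transcript 5' side on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from ._util import BASES, revcomp, stage_rng
from .align import Alignment
from .genome import GenomeBundle
from .species import SpeciesTable


def select_mappings(table: SpeciesTable, seed: int) -> dict[str, Alignment]:
    """One mapping per species, chosen by a seeded RNG.

    Multimapped species contribute sequence context from a single site
    selected at random; the same (table, seed) always yields the same
    choice, keeping context logos and mismatch profiles reproducible and
    mutually consistent.
    """
    rng = stage_rng(seed, "select-mapping", table.sample.sample_id)
    out = {}
    for seq in table.df.index:
        hits = table.mappings[seq]
        out[seq] = hits[int(rng.integers(len(hits)))] if len(hits) > 1 else hits[0]
    return out


# --------------------------------------------------------------------------- terminal
def terminal_freq(
    table: SpeciesTable,
    end: str = "five_prime",
    size_filter: tuple[int, int] | None = None,
) -> dict[str, float]:
    """Base frequencies at the 5' or 3' terminus over unique species.

    Each species counts once; terminal bases are read in transcript
    orientation from the read sequence itself. `size_filter` is an
    inclusive (min, max) length window, e.g. (20, 25) for small RNAs or
    (26, 32) for the precursor peak range.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be five_prime or three_prime")
    counts = {b: 0 for b in BASES}
    n = 0
    for seq in table.df.index:
        if size_filter and not (size_filter[0] <= len(seq) <= size_filter[1]):
            continue
        base = seq[0] if end == "five_prime" else seq[-1]
        if base in counts:
            counts[base] += 1
            n += 1
    if n == 0:
        raise ValueError("no species after filter")
    return {b: c / n for b, c in counts.items()}


# --------------------------------------------------------------------------- logos
@dataclass
class LogoMatrix:
    """Position x base counts of genomic context around an anchored end.

    Positions are anchor-relative in transcript orientation: negative
    positions lie 5' (upstream) of the anchor base and the anchor side of
    the read occupies positive positions, so a five_prime logo spans
    -window..+inner and a three_prime logo -inner..+window (position 0
    unused). All bases, including the read-covered ones, come from the
    genome at the selected mapping.
    """

    anchor: str
    counts: pd.DataFrame  # index: position, columns: A C G T
    n_species: int
    n_skipped: int = 0

    @property
    def freqs(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.where(totals > 0, 1), axis=0)

    def modal_base(self, position: int) -> str:
        return self.freqs.loc[position].idxmax()

    def write_tsv(self, path: str | Path) -> None:
        out = self.freqs.copy()
        out.insert(0, "position", out.index)
        out.to_csv(path, sep="\t", index=False)


def context_logo(
    table: SpeciesTable,
    genome: GenomeBundle,
    anchor: str = "five_prime",
    window: int = 3,
    inner: int = 3,
    stratify_by_start: str | None = None,
    length: int | None = None,
    seed: int = 0,
) -> LogoMatrix:
    """Genomic-context consensus matrix around read ends.

    One mapping per species is chosen with a seeded RNG; the genomic
    slice is extracted in transcript orientation (reverse-complemented
    for minus-strand mappings). `stratify_by_start` restricts to species
    whose read begins with that base; `length` to one size class.
    Species whose context would run off a contig edge are skipped and
    counted.
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError("anchor must be five_prime or three_prime")
    if anchor == "five_prime":
        positions = list(range(-window, 0)) + list(range(1, inner + 1))
    else:
        positions = list(range(-inner, 0)) + list(range(1, window + 1))
    counts = pd.DataFrame(
        0, index=pd.Index(positions, name="position"), columns=list(BASES)
    )
    chosen = select_mappings(table, seed)
    n, skipped = 0, 0
    for seq, a in chosen.items():
        if stratify_by_start and seq[0] != stratify_by_start:
            continue
        if length is not None and len(seq) != length:
            continue
        ref = genome.chromosomes[a.chrom]
        if anchor == "five_prime":
            if a.strand == "+":
                lo, hi = a.start - window, a.start + inner
                ctx = ref[lo:hi] if lo >= 0 and hi <= len(ref) else None
            else:
                lo, hi = a.end - inner, a.end + window
                ctx = revcomp(ref[lo:hi]) if lo >= 0 and hi <= len(ref) else None
        else:
            if a.strand == "+":
                lo, hi = a.end - inner, a.end + window
                ctx = ref[lo:hi] if lo >= 0 and hi <= len(ref) else None
            else:
                lo, hi = a.start - window, a.start + inner
                ctx = revcomp(ref[lo:hi]) if lo >= 0 and hi <= len(ref) else None
        if ctx is None:
            skipped += 1
            continue
        for pos, base in zip(positions, ctx):
            if base in BASES:
                counts.at[pos, base] += 1
        n += 1
    return LogoMatrix(anchor=anchor, counts=counts, n_species=n, n_skipped=skipped)


# --------------------------------------------------------------------------- offsets
@dataclass
class OffsetHistogram:
    end: str
    counts: dict[int, float] = field(default_factory=dict)

    def add(self, offset: int, weight: float = 1.0) -> None:
        self.counts[offset] = self.counts.get(offset, 0.0) + weight

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def peak(self) -> int:
        return max(self.counts, key=lambda o: (self.counts[o], -abs(o)))

    def mass(self, lo: int | None = None, hi: int | None = None) -> float:
        return float(
            sum(w for o, w in self.counts.items()
                if (lo is None or o >= lo) and (hi is None or o <= hi))
        )

    def to_series(self) -> pd.Series:
        s = pd.Series(self.counts, dtype=float).sort_index()
        s.index.name = "offset"
        return s

    def write_tsv(self, path: str | Path) -> None:
        self.to_series().rename("weight").to_csv(path, sep="\t")


def _signed_offset(p: Alignment, s: Alignment, end: str) -> int:
    """Signed end distance in transcript orientation: negative when the
    precursor end lies upstream (5'-ward) of the siRNA end."""
    if end == "five_prime":
        pe, se = p.five_prime, s.five_prime
    else:
        pe, se = p.three_prime, s.three_prime
    return pe - se if p.strand == "+" else se - pe


def _mapping_trees(table: SpeciesTable) -> dict:
    trees: dict[tuple, IntervalTree] = {}
    for seq in table.df.index:
        for a in table.mappings[seq]:
            trees.setdefault((a.chrom, a.strand), IntervalTree()).addi(
                a.start, a.end, (seq, a)
            )
    return trees


def end_offsets(
    p4r2_table: SpeciesTable,
    sirna_table: SpeciesTable,
    end: str = "five_prime",
    abundance_weighted: bool = False,
) -> OffsetHistogram:
    """Histogram of signed end offsets between precursor and siRNA species.

    Pairs are same-chromosome, same-strand species whose mappings overlap
    by >= 1 nt; each overlapping (precursor species, siRNA species)
    mapping pair contributes weight 1 (or the product of normalized
    abundances with `abundance_weighted`). Offset 0 means coincident
    termini; negative offsets place the precursor end upstream of the
    siRNA end in transcript orientation. The caller pre-filters the
    siRNA table (24 nt, abundance threshold).
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError("end must be five_prime or three_prime")
    hist = OffsetHistogram(end=end)
    strees = _mapping_trees(sirna_table)
    for pseq in p4r2_table.df.index:
        for pa in p4r2_table.mappings[pseq]:
            tree = strees.get((pa.chrom, pa.strand))
            if tree is None:
                continue
            for iv in tree.overlap(pa.start, pa.end):
                sseq, sa = iv.data
                if abundance_weighted:
                    w = float(
                        p4r2_table.df.at[pseq, "norm"] * sirna_table.df.at[sseq, "norm"]
                    )
                else:
                    w = 1.0
                hist.add(_signed_offset(pa, sa, end), w)
    return hist


# --------------------------------------------------------------------------- overlap
def overlap_fraction(
    p4r2_table: SpeciesTable,
    sirna_table: SpeciesTable,
    min_sirna_reads: float = 5.0,
    sirna_length: int = 24,
    p4r2_size: tuple[int, int] = (26, 94),
) -> tuple[float, dict[str, int]]:
    """Fraction of precursor species overlapping qualifying siRNAs.

    The siRNA universe is restricted to `sirna_length` species with
    normalized abundance >= min_sirna_reads (in the siRNA table's sample,
    i.e. wild type). A precursor species counts as overlapping when any
    of its mappings shares >= 1 nt, same strand, with any qualifying
    siRNA mapping; the breakdown distinguishes encompass (siRNA interval
    contained in the precursor interval) from partial overlap.
    """
    col = "norm" if "norm" in sirna_table.df.columns else "raw"
    qual = sirna_table.df.index[
        (sirna_table.df["length"] == sirna_length)
        & (sirna_table.df[col] >= min_sirna_reads)
    ]
    strees = _mapping_trees(sirna_table.subset(qual))
    breakdown = {"encompass": 0, "partial": 0, "none": 0}
    n = 0
    for pseq in p4r2_table.df.index:
        L = len(pseq)
        if not (p4r2_size[0] <= L <= p4r2_size[1]):
            continue
        n += 1
        best = "none"
        for pa in p4r2_table.mappings[pseq]:
            tree = strees.get((pa.chrom, pa.strand))
            if tree is None:
                continue
            for iv in tree.overlap(pa.start, pa.end):
                _, sa = iv.data
                if pa.start <= sa.start and sa.end <= pa.end:
                    best = "encompass"
                    break
                best = "partial"
            if best == "encompass":
                break
        breakdown[best] += 1
    fraction = (breakdown["encompass"] + breakdown["partial"]) / n if n else 0.0
    return fraction, breakdown
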