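"""Per-length, per-position mismatch profiles and the 3'-terminal summary.

Only perfectly matching or single-mismatch reads exist downstream of the
mapping policy, so every species contributes at most one mismatch
position. The matrix is read-weighted (% of reads of a length with a
mismatch at each position); wild-type background subtraction removes the
position-independent sequencing-error floor, leaving the untemplated
3'-addition signal concentrated at the last one or two read positions of
the precursor size band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ends import select_mappings
from .species import SpeciesTable

LENGTH_RANGE = (15, 76)


@dataclass
class MismatchMatrix:
    """lengths x read positions -> % of reads with a mismatch there."""

    freq: pd.DataFrame  # index: length, columns: 1..max_len, percent units
    read_totals: pd.Series  # reads per length

    def row_mass(self) -> pd.Series:
        """Sum over positions = 100 x fraction of reads with any mismatch."""
        return self.freq.sum(axis=1)

    def write_tsv(self, path: str | Path) -> None:
        out = self.freq.copy()
        out.insert(0, "length", out.index)
        out.insert(1, "n_reads", self.read_totals.reindex(out.index).fillna(0).astype(int))
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def mismatch_matrix(
    table: SpeciesTable,
    length_range: tuple[int, int] = LENGTH_RANGE,
    seed: int = 0,
) -> MismatchMatrix:
    """Read-weighted mismatch frequencies per (length, read position).

    frequency(L, p) = 100 * reads of length L with a mismatch at position
    p / reads of length L. Multimapped species contribute through their
    seeded single-site selection, consistent with the context logos.
    """
    lo, hi = length_range
    lengths = pd.Index(range(lo, hi + 1), name="length")
    positions = list(range(1, hi + 1))
    counts = pd.DataFrame(0.0, index=lengths, columns=positions)
    totals = pd.Series(0, index=lengths, dtype=int)
    chosen = select_mappings(table, seed)
    for seq, a in chosen.items():
        L = len(seq)
        if not (lo <= L <= hi):
            continue
        raw = int(table.df.at[seq, "raw"])
        totals[L] += raw
        if a.mismatch is not None:
            counts.at[L, a.mismatch.read_pos] += raw
    freq = counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
    return MismatchMatrix(freq=freq, read_totals=totals)


def background_subtract(
    mut: MismatchMatrix, wt: MismatchMatrix, clamp: bool = True
) -> MismatchMatrix:
    """Cellwise mutant - wild type; negatives clamped to 0 unless disabled."""
    diff = mut.freq.sub(wt.freq.reindex_like(mut.freq).fillna(0.0))
    if clamp:
        diff = diff.clip(lower=0.0)
    return MismatchMatrix(freq=diff, read_totals=mut.read_totals)


def terminal_mismatch_fraction(
    table: SpeciesTable,
    min_length: int = 26,
    seed: int = 0,
    weight: str = "species",
) -> float:
    """Percentage of precursor species with a 3'-terminal mismatch.

    Over species of >= min_length nt, the share whose selected mapping
    carries its single mismatch at the last read position — the signature
    of an untemplated 3' addition. `weight="reads"` gives the
    read-weighted variant of the same quantity.
    """
    if weight not in ("species", "reads"):
        raise ValueError("weight must be 'species' or 'reads'")
    chosen = select_mappings(table, seed)
    num = den = 0.0
    for seq, a in chosen.items():
        L = len(seq)
        if L < min_length:
            continue
        w = float(table.df.at[seq, "raw"]) if weight == "reads" else 1.0
        den += w
        if a.mismatch is not None and a.mismatch.read_pos == L:
            num += w
    return 100.0 * num / den if den else 0.0
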