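"""Size-class profiles of unique species and feature-category breakdowns."""

from __future__ import annotations

import pandas as pd

from ._util import BASES
from .genome import Feature
from .species import SpeciesTable, build_feature_trees

SIZE_RANGE = (15, 94)
CATEGORY_PRIORITY = ("transposable_element", "gene", "intergenic")


def size_profile(table: SpeciesTable, by_first_base: bool = True) -> pd.DataFrame:
    """Unique-species counts per length, optionally split by 5' base.

    Counts species (each distinct sequence once), not reads; the 5' base
    is the first base of the read sequence. Rows cover the full
    size-selection window even where empty.
    """
    lengths = range(SIZE_RANGE[0], SIZE_RANGE[1] + 1)
    cols = ["total"] + (list(BASES) if by_first_base else [])
    out = pd.DataFrame(0, index=pd.Index(lengths, name="length"), columns=cols)
    for seq in table.df.index:
        L = len(seq)
        if L not in out.index:
            continue
        out.at[L, "total"] += 1
        if by_first_base and seq[0] in BASES:
            out.at[L, seq[0]] += 1
    return out


def categorize(
    mappings,
    trees: dict,
) -> str:
    """Feature category of a species from all its mappings.

    Each mapping votes for the highest-priority category it overlaps
    (transposable_element > gene > intergenic); the species takes the
    majority vote, ties resolved toward higher priority.
    """
    votes = {c: 0 for c in CATEGORY_PRIORITY}
    for a in mappings:
        tree = trees.get(a.chrom)
        cats = {iv.data for iv in tree.overlap(a.start, a.end)} if tree else set()
        for c in CATEGORY_PRIORITY:
            if c in cats:
                votes[c] += 1
                break
        else:
            votes["intergenic"] += 1
    best = max(votes.values())
    for c in CATEGORY_PRIORITY:  # priority order breaks ties
        if votes[c] == best:
            return c
    return "intergenic"


def category_proportions(
    table: SpeciesTable,
    features: list[Feature],
    weight: str = "reads",
) -> pd.DataFrame:
    """Per-length proportions of gene / intergenic / transposable_element.

    `weight="reads"` weights each species by its raw read count (the
    default, matching proportions of sequencing reads); `"species"`
    counts each species once. Rows with no species are all-zero.
    """
    if weight not in ("reads", "species"):
        raise ValueError("weight must be 'reads' or 'species'")
    trees = build_feature_trees(features, {"transposable_element", "gene"})
    lengths = range(SIZE_RANGE[0], SIZE_RANGE[1] + 1)
    out = pd.DataFrame(
        0.0, index=pd.Index(lengths, name="length"), columns=list(CATEGORY_PRIORITY)
    )
    for seq in table.df.index:
        L = len(seq)
        if L not in out.index:
            continue
        cat = categorize(table.mappings[seq], trees)
        out.at[L, cat] += table.df.at[seq, "raw"] if weight == "reads" else 1
    totals = out.sum(axis=1)
    nonzero = totals > 0
    out.loc[nonzero] = out.loc[nonzero].div(totals[nonzero], axis=0)
    return out


def unique_species_counts(
    tables: dict[str, SpeciesTable],
    size_range: tuple[int, int] = SIZE_RANGE,
) -> pd.DataFrame:
    """Per-length partition of unique species across two samples.

    A species present in both samples is counted once, in the overlap
    partition; otherwise in the exclusive partition of its sample.
    Species identity is the (sequence, strand-polarity) pair, which the
    sequence alone encodes.
    """
    if len(tables) != 2:
        raise ValueError("expected exactly two samples to partition")
    (name_a, ta), (name_b, tb) = tables.items()
    set_a, set_b = set(ta.df.index), set(tb.df.index)
    lo, hi = size_range
    lengths = range(lo, hi + 1)
    out = pd.DataFrame(
        0,
        index=pd.Index(lengths, name="length"),
        columns=[f"only_{name_a}", f"only_{name_b}", "overlap"],
    )
    for seq in set_a | set_b:
        L = len(seq)
        if not (lo <= L <= hi):
            continue
        if seq in set_a and seq in set_b:
            out.at[L, "overlap"] += 1
        elif seq in set_a:
            out.at[L, f"only_{name_a}"] += 1
        else:
            out.at[L, f"only_{name_b}"] += 1
    return out
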