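"""Unique-species tables: collapse, exclusion, normalization, thresholding.

The pipeline order is fixed and mirrors the study's processing sequence:

    collapse -> exclude_stage1 -> normalize -> exclude_stage2 -> threshold

Stage 1 removes species with any mapping in 45S rRNA arrays, chloroplast
or mitochondrial regions; library totals for normalization are the read
counts surviving stage 1. Counts are normalized by dividing by the
sample's mapped total and multiplying by the maximum total across
samples, so the deepest library is unchanged. Stage 2 removes
tRNA/snRNA/snoRNA species after normalization; the abundance threshold
("at least five reads after normalization and filtering") is inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd
from intervaltree import IntervalTree

from .align import Alignment, Hits, KmerIndex, MapStats, map_species
from .genome import STAGE1_CATEGORIES, STAGE2_CATEGORIES, Feature

PIPELINE_ORDER = ("collapse", "exclude_stage1", "normalize", "exclude_stage2", "threshold")


@dataclass
class SampleMeta:
    sample_id: str
    genotype: str
    replicate: int = 1
    total_mapped: int | None = None  # mapped reads surviving stage-1 exclusion


@dataclass
class SpeciesTable:
    """One record per distinct read sequence of one sample.

    `df` is indexed by sequence with columns: length, raw, norm (after
    `normalize`), n_mappings, truncated; `mappings` holds each species'
    deduplicated alignments.
    """

    sample: SampleMeta
    df: pd.DataFrame
    mappings: dict[str, tuple[Alignment, ...]]

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, sequences: Iterable[str]) -> "SpeciesTable":
        keep = [s for s in sequences if s in self.mappings]
        return SpeciesTable(
            sample=replace(self.sample),
            df=self.df.loc[keep].copy(),
            mappings={s: self.mappings[s] for s in keep},
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.insert(0, "sequence", out.index)
        out.to_csv(path, sep="\t", index=False)

    def write_bed(self, path: str | Path) -> None:
        """All mappings as BED6 (score = raw count)."""
        with open(path, "w") as fh:
            for seq, hits in self.mappings.items():
                raw = int(self.df.at[seq, "raw"])
                for a in hits:
                    fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{seq}\t{raw}\t{a.strand}\n")


def collapse(
    alignments_by_read: Iterable[tuple[str, Hits | tuple]],
    sample: SampleMeta,
) -> SpeciesTable:
    """Collapse read-level alignments into unique species.

    Input is (read sequence, alignments) per read; identical sequences
    share identical alignments, so the species' mappings are the
    deduplicated union. Unmapped/skipped reads are not included.
    """
    counts: Counter = Counter()
    mappings: dict[str, tuple[Alignment, ...]] = {}
    for seq, hits in alignments_by_read:
        if not hits:
            continue
        counts[seq] += 1
        if seq not in mappings:
            mappings[seq] = tuple(dict.fromkeys(hits))
    return _assemble(counts, mappings, sample)


def build_species_table(
    reads: Iterable[str],
    index: KmerIndex,
    sample: SampleMeta,
    max_mm: int = 1,
    max_hits: int = 50,
) -> tuple[SpeciesTable, MapStats]:
    """Count unique read sequences, map each once, and collapse.

    Equivalent to mapping every read then calling `collapse`, but each
    distinct sequence is aligned a single time.
    """
    counts = Counter(reads)
    hit_map, stats = map_species(counts.keys(), index, max_mm=max_mm, max_hits=max_hits)
    mapped_counts = Counter()
    mappings = {}
    for seq, n in counts.items():
        hits = hit_map[seq]
        if not hits:
            stats.n_unmapped += 0  # species-level stats already counted
            continue
        mapped_counts[seq] = n
        mappings[seq] = tuple(dict.fromkeys(hits))
    return _assemble(mapped_counts, mappings, sample), stats


def _assemble(counts: Counter, mappings: dict, sample: SampleMeta) -> SpeciesTable:
    seqs = sorted(counts)
    df = pd.DataFrame(
        {
            "length": [len(s) for s in seqs],
            "raw": [int(counts[s]) for s in seqs],
            "n_mappings": [len(mappings[s]) for s in seqs],
        },
        index=pd.Index(seqs, name="sequence"),
    )
    return SpeciesTable(sample=sample, df=df, mappings=mappings)


# --------------------------------------------------------------------------- exclusion
def build_feature_trees(features: Iterable[Feature], categories: frozenset | set) -> dict:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.category in categories:
            trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.category)
    return trees


def _overlaps_any(trees: dict, hits: tuple[Alignment, ...]) -> bool:
    for a in hits:
        tree = trees.get(a.chrom)
        if tree is not None and tree.overlaps(a.start, a.end):
            return True
    return False


def _exclude(table: SpeciesTable, features, categories) -> SpeciesTable:
    trees = build_feature_trees(features, categories)
    keep = [s for s in table.df.index if not _overlaps_any(trees, table.mappings[s])]
    return table.subset(keep)


def exclude_stage1(table: SpeciesTable, features: Iterable[Feature]) -> SpeciesTable:
    """Remove species with any mapping in 45S rRNA / chloroplast /
    mitochondrion features, then set the sample's mapped total."""
    out = _exclude(table, list(features), STAGE1_CATEGORIES)
    out.sample.total_mapped = int(out.df["raw"].sum())
    return out


def exclude_stage2(table: SpeciesTable, features: Iterable[Feature]) -> SpeciesTable:
    """Remove tRNA/snRNA/snoRNA species. Normalization is NOT recomputed
    (it precedes this step in the pipeline order)."""
    return _exclude(table, list(features), STAGE2_CATEGORIES)


# --------------------------------------------------------------------------- scaling
def normalize(tables: list[SpeciesTable]) -> list[SpeciesTable]:
    """Scale raw counts to the deepest library.

    norm = raw / total_mapped(sample) * max(total_mapped); the deepest
    sample's counts are unchanged. Totals must be set (exclude_stage1
    does this); raw counts are left untouched.
    """
    totals = []
    for t in tables:
        if t.sample.total_mapped is None:
            t.sample.total_mapped = int(t.df["raw"].sum())
        if t.sample.total_mapped <= 0:
            raise ValueError(f"sample {t.sample.sample_id} has no mapped reads")
        totals.append(t.sample.total_mapped)
    max_total = max(totals)
    for t, total in zip(tables, totals):
        t.df["norm"] = t.df["raw"] * (max_total / total)
    return tables


def threshold(table: SpeciesTable, min_norm: float = 5.0) -> SpeciesTable:
    """Retain species with normalized count >= min_norm (inclusive)."""
    if "norm" not in table.df.columns:
        raise ValueError("normalize() must run before threshold()")
    keep = table.df.index[table.df["norm"] >= min_norm]
    return table.subset(keep)
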