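"""Self-contained short-read mapper implementing the study's alignment policy.

End-to-end alignment of 15-94 nt reads with at most one mismatch,
best-stratum reporting (perfect hits suppress one-mismatch hits) and a
deterministic cap of 50 mappings per read — the policy under which all
downstream statistics are defined. A seed-and-extend k-mer index makes
this exact: with two non-overlapping seeds per read, any alignment with
<= 1 mismatch leaves at least one seed exact.

A SAM ingest path (`ingest_sam`) accepts externally mapped data with
NM/MD tags and yields records in the same schema.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from ._util import revcomp
from .genome import GenomeBundle

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class Mismatch(NamedTuple):
    read_pos: int  # 1-based, 5'->3' in the read
    ref_base: str  # transcript-oriented (complemented for - strand alignments)
    read_base: str


class Alignment(NamedTuple):
    chrom: str
    start: int  # 0-based leftmost reference coordinate
    strand: str
    read_length: int
    mismatch: Mismatch | None = None

    @property
    def end(self) -> int:
        return self.start + self.read_length

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' base (transcript orientation)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class Hits(list):
    """Alignment list with mapper bookkeeping flags."""

    truncated: bool = False
    skipped_reason: str | None = None


@dataclass
class KmerIndex:
    k: int
    positions: dict  # k-mer -> list[(chrom, pos)] on the + strand
    encoded: dict = field(default_factory=dict)  # chrom -> uint8 array
    chrom_names: list = field(default_factory=list)

    def lookup(self, kmer: str) -> list:
        return self.positions.get(kmer, [])


def build_index(genome: GenomeBundle | dict, k: int = 7) -> KmerIndex:
    """Index every k-mer of the + strand (reads are searched in both
    orientations against it). Positions containing N are not seeded."""
    chroms = genome.chromosomes if isinstance(genome, GenomeBundle) else genome
    if not (4 <= k <= 16):
        raise ValueError(f"k={k} out of supported range [4, 16]")
    positions: dict[str, list] = {}
    encoded = {}
    for name in sorted(chroms):
        seq = chroms[name].upper()
        encoded[name] = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            positions.setdefault(kmer, []).append((name, i))
    return KmerIndex(k=k, positions=positions, encoded=encoded,
                     chrom_names=sorted(chroms))


def _mismatches(index: KmerIndex, chrom: str, start: int, read_bytes: np.ndarray) -> np.ndarray:
    ref = index.encoded[chrom]
    end = start + len(read_bytes)
    if start < 0 or end > len(ref):
        return np.array([0, 1])  # sentinel: >1
    return np.nonzero(ref[start:end] != read_bytes)[0]


def _candidates(index: KmerIndex, seq: str) -> set:
    """Candidate (chrom, alignment start) pairs from the two outer seeds."""
    k, L = index.k, len(seq)
    cands = set()
    for offset in (0, L - k):
        for chrom, pos in index.lookup(seq[offset : offset + k]):
            start = pos - offset
            if start >= 0:
                cands.add((chrom, start))
    return cands


def map_read(
    seq: str,
    index: KmerIndex,
    genome: GenomeBundle | None = None,
    max_mm: int = 1,
    max_hits: int = 50,
) -> Hits:
    """All end-to-end best-stratum alignments of one read.

    Returns 0-mismatch hits if any exist, otherwise 1-mismatch hits,
    sorted by (chrom, start, strand) and truncated to `max_hits`
    (`Hits.truncated` set when the cap applies). Reads containing
    non-ACGT characters are skipped, not raised.
    """
    seq = seq.upper()
    hits = Hits()
    if not set(seq) <= _ACGT:
        hits.skipped_reason = "non-ACGT characters"
        log.debug("skipping read with %s: %s...", hits.skipped_reason, seq[:20])
        return hits
    if len(seq) < 2 * index.k:
        hits.skipped_reason = "read shorter than two seeds"
        return hits

    L = len(seq)
    found: dict[tuple, Alignment] = {}
    best = max_mm
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        rb = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for chrom, start in _candidates(index, oriented):
            mm = _mismatches(index, chrom, start, rb)
            if len(mm) > max_mm:
                continue
            if len(mm) == 0:
                mismatch = None
                n_mm = 0
            else:
                o = int(mm[0])
                ref_b = chr(index.encoded[chrom][start + o])
                read_b = oriented[o]
                if strand == "+":
                    mismatch = Mismatch(o + 1, ref_b, read_b)
                else:
                    # convert to 5'->3' read coordinates and complement bases
                    mismatch = Mismatch(L - o, _COMP[ref_b], _COMP[read_b])
                n_mm = 1
            best = min(best, n_mm)
            found[(chrom, start, strand)] = Alignment(chrom, start, strand, L, mismatch)

    stratum = [a for a in found.values() if (a.mismatch is None) == (best == 0)]
    stratum.sort(key=lambda a: (a.chrom, a.start, a.strand))
    if len(stratum) > max_hits:
        hits.truncated = True
        stratum = stratum[:max_hits]
    hits.extend(stratum)
    return hits


@dataclass
class MapStats:
    n_reads: int = 0
    n_mapped: int = 0
    n_skipped: int = 0
    n_unmapped: int = 0
    n_truncated: int = 0


def map_species(
    seqs: Iterable[str],
    index: KmerIndex,
    max_mm: int = 1,
    max_hits: int = 50,
) -> tuple[dict, MapStats]:
    """Map each distinct sequence once; returns {sequence: Hits} and counters."""
    out: dict[str, Hits] = {}
    stats = MapStats()
    for seq in seqs:
        if seq in out:
            continue
        hits = map_read(seq, index, max_mm=max_mm, max_hits=max_hits)
        stats.n_reads += 1
        if hits.skipped_reason:
            stats.n_skipped += 1
        elif not hits:
            stats.n_unmapped += 1
        else:
            stats.n_mapped += 1
            stats.n_truncated += int(hits.truncated)
        out[seq] = hits
    return out, stats


# --------------------------------------------------------------------------- SAM I/O
def _md_and_nm(ref_seq: str, aligned_seq: str) -> tuple[str, int]:
    """MD tag and NM for an ungapped alignment (reference orientation)."""
    md, run, nm = [], 0, 0
    for r, q in zip(ref_seq, aligned_seq):
        if r == q:
            run += 1
        else:
            md.append(f"{run}{r}")
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def write_sam(
    path: str | Path,
    genome: GenomeBundle,
    records: Iterable[tuple[str, str, Alignment]],
) -> None:
    """Write (read name, read sequence 5'->3', alignment) records as SAM."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for qname, seq, a in records:
            flag = 16 if a.strand == "-" else 0
            aligned = revcomp(seq) if a.strand == "-" else seq
            ref = genome.chromosomes[a.chrom][a.start : a.end]
            md, nm = _md_and_nm(ref, aligned)
            fh.write(
                f"{qname}\t{flag}\t{a.chrom}\t{a.start + 1}\t255\t{a.read_length}M\t"
                f"*\t0\t0\t{aligned}\t{'I' * a.read_length}\tNM:i:{nm}\tMD:Z:{md}\n"
            )


_MD_RE = re.compile(r"(\d+)([ACGTN]|\^[ACGTN]+)?")


@dataclass
class IngestStats:
    n_records: int = 0
    n_kept: int = 0
    n_dropped_nm: int = 0
    n_dropped_no_md: int = 0
    n_dropped_other: int = 0


def ingest_sam(
    path: str | Path,
    samples: dict | None = None,
) -> tuple[list[tuple[str, str, str, Alignment]], IngestStats]:
    """Read an external SAM/BAM into the mapper's alignment schema.

    Returns (records, stats) where each record is (sample id, read name,
    read sequence 5'->3', Alignment). The sample id is looked up from the
    read-group tag or read-name prefix via `samples` (identity when
    absent). Records with NM > 1, gapped CIGARs, or NM = 1 without an MD
    tag are dropped and counted.
    """
    import pysam

    records: list[tuple[str, str, str, Alignment]] = []
    stats = IngestStats()
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as sam:
        for rec in sam:
            stats.n_records += 1
            if rec.is_unmapped or rec.cigartuples is None:
                stats.n_dropped_other += 1
                continue
            if any(op != 0 for op, _ in rec.cigartuples):  # ungapped only
                stats.n_dropped_other += 1
                continue
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                stats.n_dropped_other += 1
                continue
            if nm > 1:
                stats.n_dropped_nm += 1
                continue
            L = rec.query_length
            strand = "-" if rec.is_reverse else "+"
            mismatch = None
            if nm == 1:
                try:
                    md = rec.get_tag("MD")
                except KeyError:
                    stats.n_dropped_no_md += 1
                    log.warning("NM=1 record %s lacks MD tag; dropped", rec.query_name)
                    continue
                m = _MD_RE.match(md)
                if m is None or m.group(2) is None or m.group(2).startswith("^"):
                    stats.n_dropped_other += 1
                    continue
                ref_off = int(m.group(1))  # 0-based offset of mismatch on reference
                ref_base = m.group(2)
                aligned = rec.query_sequence.upper()
                read_base_aln = aligned[ref_off]
                if strand == "+":
                    mismatch = Mismatch(ref_off + 1, ref_base, read_base_aln)
                else:
                    mismatch = Mismatch(L - ref_off, _COMP[ref_base], _COMP[read_base_aln])
            seq = rec.query_sequence.upper()
            if strand == "-":
                seq = revcomp(seq)  # back to the read's own 5'->3'
            a = Alignment(rec.reference_name, rec.reference_start, strand, L, mismatch)
            sample = rec.query_name.split(".")[0]
            if samples:
                sample = samples.get(sample, sample)
            records.append((sample, rec.query_name, seq, a))
            stats.n_kept += 1
    return records, stats
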