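"""Mapper correctness: oracle equivalence, strand symmetry, SAM round trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_map
from p4r2scan._util import revcomp
from p4r2scan.align import (
    Alignment,
    build_index,
    ingest_sam,
    map_read,
    write_sam,
)
from p4r2scan.genome import GenomeBundle


def _key(a: Alignment):
    return (a.chrom, a.start, a.strand, a.mismatch)


# ----------------------------------------------------------------------- index
def test_index_kmer_positions_by_inspection():
    idx = build_index({"c": "ACGTACGT"}, k=4)
    assert [(c, p) for c, p in idx.lookup("ACGT")] == [("c", 0), ("c", 4)]
    assert idx.lookup("TTTT") == []


def test_empty_genome_empty_index():
    idx = build_index({"c": ""}, k=7)
    assert idx.positions == {}


def test_k_out_of_range():
    with pytest.raises(ValueError, match="out of supported range"):
        build_index({"c": "ACGT" * 100}, k=2)


def test_every_indexed_kmer_verified_by_slicing(toy_genome):
    idx = build_index(toy_genome, k=7)
    rng = np.random.default_rng(0)
    kmers = rng.choice(list(idx.positions), size=500, replace=False)
    for kmer in kmers:
        for chrom, pos in idx.lookup(str(kmer)):
            assert toy_genome.chromosomes[chrom][pos : pos + 7] == kmer


# ------------------------------------------------------------------- map_read
def test_planted_unique_read_single_perfect_hit(toy_genome):
    idx = build_index(toy_genome, k=7)
    read = toy_genome.chromosomes["chrA"][1000:1030]
    hits = map_read(read, idx)
    oracle = brute_force_map(read, toy_genome.chromosomes)
    assert [_key(a) for a in hits] == [_key(a) for a in oracle]
    assert any(a.chrom == "chrA" and a.start == 1000 and a.mismatch is None
               for a in hits)


def test_unmappable_read_returns_empty(toy_genome):
    idx = build_index(toy_genome, k=7)
    # alternating dimer of this length is absent from a random genome
    assert map_read("AC" * 20, idx) == brute_force_map("AC" * 20, toy_genome.chromosomes)


def test_non_acgt_read_skipped_not_raised(toy_genome):
    idx = build_index(toy_genome, k=7)
    hits = map_read("ACGTNACGTNACGTNACGTN", idx)
    assert hits == [] and hits.skipped_reason is not None


def test_oracle_equivalence_on_planted_and_random_reads(toy_genome):
    """1,000 reads (perfect, one-mismatch and random): hit sets equal the
    brute-force enumeration exactly, including mismatch records."""
    idx = build_index(toy_genome, k=7)
    rng = np.random.default_rng(7)
    chroms = toy_genome.chromosomes
    reads = []
    for _ in range(400):  # planted perfect matches, both strands
        chrom = "chrA" if rng.random() < 0.6 else "chrB"
        L = int(rng.integers(15, 45))
        s = int(rng.integers(0, len(chroms[chrom]) - L))
        read = chroms[chrom][s : s + L]
        reads.append(read if rng.random() < 0.5 else revcomp(read))
    for _ in range(400):  # planted single mismatches
        chrom = "chrA" if rng.random() < 0.6 else "chrB"
        L = int(rng.integers(15, 45))
        s = int(rng.integers(0, len(chroms[chrom]) - L))
        read = list(chroms[chrom][s : s + L])
        pos = int(rng.integers(L))
        read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1 + int(rng.integers(3))) % 4]
        read = "".join(read)
        reads.append(read if rng.random() < 0.5 else revcomp(read))
    for _ in range(200):  # random reads, mostly unmappable
        reads.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(15, 40)))))
    for read in reads:
        got = [_key(a) for a in map_read(read, idx)]
        want = [_key(a) for a in brute_force_map(read, chroms)]
        assert got == want, f"read {read}"


def test_max_hits_truncation_is_deterministic():
    genome = {"c": ("TTTT" + "ACGTACGTACGTACGTACG") * 80}
    idx = build_index(genome, k=7)
    read = "ACGTACGTACGTACG"
    hits = map_read(read, idx, max_hits=50)
    assert hits.truncated and len(hits) == 50
    again = map_read(read, idx, max_hits=50)
    assert [_key(a) for a in hits] == [_key(a) for a in again]
    # deterministic order: sorted by (chrom, start, strand)
    keys = [(a.chrom, a.start, a.strand) for a in hits]
    assert keys == sorted(keys)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_strand_symmetry(toy_genome, seed):
    """Mapping revcomp(r) yields the same loci with strands flipped."""
    idx = build_index(toy_genome, k=7)
    rng = np.random.default_rng(seed)
    chrom = "chrA"
    L = int(rng.integers(16, 40))
    s = int(rng.integers(0, 5000 - L))
    read = list(toy_genome.chromosomes[chrom][s : s + L])
    if rng.random() < 0.5:  # sometimes plant a mismatch
        p = int(rng.integers(L))
        read[p] = "ACGT"[int(rng.integers(4))]
    read = "".join(read)
    fwd = map_read(read, idx)
    rev = map_read(revcomp(read), idx)
    flip = {"+": "-", "-": "+"}
    assert {(a.chrom, a.start, a.strand) for a in fwd} == {
        (a.chrom, a.start, flip[a.strand]) for a in rev
    }


def test_round_trip_error_free_reads_recover_all_truth(clean_study):
    """At zero sequencing error, every truth coordinate of every genotype
    is recovered by mapping (untailed species map perfectly; tailed ones
    map to the same interval with their tail mismatch or extension)."""
    index = clean_study["index"]
    for genotype in ("Col-0", "dcl2/3/4"):
        sim = clean_study["sims"][genotype]
        table = clean_study["tables"][genotype]
        mapped_sites = {
            (a.chrom, a.start, a.strand)
            for hits in table.mappings.values() for a in hits
        }
        truth = sim.truth
        clean = truth[
            (truth["tail_len"] == 0) & truth["kind"].isin(["p4r2", "sirna", "mirna"])
        ]
        missing = 0
        for row in clean.itertuples():
            if (row.chrom, row.start, row.strand) not in mapped_sites:
                missing += 1
        assert missing == 0, f"{genotype}: {missing} truth coordinates unrecovered"


# ----------------------------------------------------------------------- SAM
def test_sam_write_ingest_round_trip(toy_genome, tmp_path):
    idx = build_index(toy_genome, k=7)
    rng = np.random.default_rng(3)
    records = []
    for i in range(80):
        L = int(rng.integers(18, 40))
        s = int(rng.integers(0, 4000))
        read = list(toy_genome.chromosomes["chrA"][s : s + L])
        if rng.random() < 0.5:
            p = int(rng.integers(L))
            read[p] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
        for a in map_read(read, idx):
            records.append((f"s1.r{i}", read, a))
    path = tmp_path / "out.sam"
    write_sam(path, toy_genome, records)
    back, stats = ingest_sam(path)
    assert stats.n_kept == len(records)
    got = [(seq, _key(a)) for _, _, seq, a in back]
    want = [(seq, _key(a)) for _, seq, a in records]
    assert sorted(got) == sorted(want)


def test_ingest_sam_md_semantics_and_nm_policy(tmp_path):
    """Hand-worked MD strings: NM=0 -> no mismatch; NM:i:1 MD:Z:10A19 on a
    30 nt + strand read -> read_pos 11, ref A; NM=2 dropped."""
    header = "@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n"
    read0 = "ACGT" * 7 + "AC"  # 30 nt
    lines = [
        f"r0\t0\tc\t5\t255\t30M\t*\t0\t0\t{read0}\t{'I'*30}\tNM:i:0\tMD:Z:30",
        f"r1\t0\tc\t5\t255\t30M\t*\t0\t0\t{read0}\t{'I'*30}\tNM:i:1\tMD:Z:10A19",
        f"r2\t0\tc\t5\t255\t30M\t*\t0\t0\t{read0}\t{'I'*30}\tNM:i:2\tMD:Z:5A4A19",
    ]
    path = tmp_path / "t.sam"
    path.write_text(header + "\n".join(lines) + "\n")
    records, stats = ingest_sam(path)
    assert stats.n_kept == 2 and stats.n_dropped_nm == 1
    by_name = {name: a for _, name, _, a in records}
    assert by_name["r0"].mismatch is None
    mm = by_name["r1"].mismatch
    assert mm.read_pos == 11 and mm.ref_base == "A"
    assert by_name["r1"].start == 4  # SAM 1-based -> internal 0-based
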