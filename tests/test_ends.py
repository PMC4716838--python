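"""Terminal frequencies, context logos, end offsets and overlap statistic."""

import numpy as np
import pytest

from helpers import make_table
from p4r2scan._util import revcomp
from p4r2scan.ends import (
    context_logo,
    end_offsets,
    overlap_fraction,
    terminal_freq,
)
from p4r2scan.genome import GenomeBundle
from p4r2scan.species import threshold


def test_terminal_freq_by_inspection():
    t = make_table([
        dict(sequence="ACG" + "C" * 21, mappings=[("c", 0, "+")]),
        dict(sequence="ATT" + "C" * 21, mappings=[("c", 50, "+")]),
        dict(sequence="GCC" + "C" * 21, mappings=[("c", 90, "+")]),
    ])
    f = terminal_freq(t, "five_prime")
    assert f["A"] == pytest.approx(2 / 3) and f["G"] == pytest.approx(1 / 3)


def test_terminal_freq_empty_after_filter_raises():
    t = make_table([dict(sequence="A" * 24, mappings=[("c", 0, "+")])])
    with pytest.raises(ValueError, match="no species after filter"):
        terminal_freq(t, "five_prime", size_filter=(30, 40))


def test_sirna_5p_adenosine_is_modal(study):
    """Most 24 nt siRNAs begin with an adenosine in wild type."""
    t = threshold(study["tables"]["Col-0"], 5.0)
    f = terminal_freq(t, "five_prime", size_filter=(24, 24))
    assert max(f, key=f.get) == "A"


def test_p4r2_5p_purine_with_a_and_g_similar(study):
    """Precursors start with a purine; A and G at similar frequency."""
    t = threshold(study["tables"]["dcl2/3/4"], 5.0)
    f = terminal_freq(t, "five_prime", size_filter=(26, 32))
    assert f["A"] + f["G"] > 0.6
    assert abs(f["A"] - f["G"]) < 0.15


# ------------------------------------------------------------------ logos
def test_context_logo_plus_strand_coordinates():
    genome = GenomeBundle(chromosomes={"c": "TTTACGTACGTAGGGCCCAT"})
    #                                     0123456789...
    t = make_table([dict(sequence="ACGTACGTA", mappings=[("c", 3, "+")])])
    logo = context_logo(t, genome, "five_prime", window=3, inner=3, seed=0)
    # upstream context = genome[0:3] = TTT; first read bases = ACG
    assert logo.counts.at[-1, "T"] == 1 and logo.counts.at[-3, "T"] == 1
    assert logo.counts.at[1, "A"] == 1 and logo.counts.at[3, "G"] == 1


def test_context_logo_minus_strand_hand_worked():
    # 10 nt toy genome; read maps at [4,7) on the minus strand
    genome = GenomeBundle(chromosomes={"c": "AACCGGTTAA"})
    seq = revcomp(genome.chromosomes["c"][4:7])  # minus-strand read
    t = make_table([dict(sequence=seq, mappings=[("c", 4, "-")])])
    logo = context_logo(t, genome, "five_prime", window=3, inner=3, seed=0)
    # transcript 5' is at genomic position 6; upstream = revcomp(genome[7:10])
    expected = revcomp(genome.chromosomes["c"][4:10])  # TTAACC -> upstream TTA...
    for pos, base in zip([-3, -2, -1, 1, 2, 3], expected):
        assert logo.counts.at[pos, base] == 1


def test_context_logo_edge_species_skipped():
    genome = GenomeBundle(chromosomes={"c": "ACGTACGTACGT"})
    t = make_table([dict(sequence="ACGTA", mappings=[("c", 0, "+")])])
    logo = context_logo(t, genome, "five_prime", window=3, seed=0)
    assert logo.n_species == 0 and logo.n_skipped == 1


def test_context_logo_seed_reproducible(study):
    t = threshold(study["tables"]["dcl2/3/4"], 5.0)
    sub = t.subset(t.df.index[t.df["length"] >= 26][:300])
    a = context_logo(sub, study["genome"], "five_prime", seed=11)
    b = context_logo(sub, study["genome"], "five_prime", seed=11)
    assert a.counts.equals(b.counts)


def test_p4r2_logo_minus1_T_plus1_purine(study):
    """The 5' purine is preceded by T in the genomic sequence."""
    t = threshold(study["tables"]["dcl2/3/4"], 5.0)
    p4 = t.subset(t.df.index[t.df["length"] >= 26])
    logo = context_logo(p4, study["genome"], "five_prime", seed=4)
    assert logo.modal_base(-1) == "T"
    f1 = logo.freqs.loc[1]
    assert f1["A"] + f1["G"] > 0.6
    # stratified logos behave the same way at -1
    for base in ("A", "G"):
        strat = context_logo(p4, study["genome"], "five_prime",
                             stratify_by_start=base, seed=4)
        assert strat.modal_base(-1) == "T"
        assert strat.freqs.at[1, base] > 0.9


# ------------------------------------------------------------------ offsets
def test_offset_sign_convention_plus_strand():
    # + strand precursor 5'@998, siRNA 5'@1000 -> offset -2
    p4 = make_table([dict(sequence="A" * 35, mappings=[("c", 998, "+")])])
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 1000, "+")])])
    h = end_offsets(p4, si, "five_prime")
    assert h.counts == {-2: 1.0}


def test_offset_sign_convention_minus_strand():
    # minus strand: precursor 5'@1010, siRNA 5'@1005 -> -5 (upstream in
    # transcript orientation is the higher genomic coordinate)
    p4 = make_table([dict(sequence="A" * 30, mappings=[("c", 981, "-")])])  # 5' at 1010
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 982, "-")])])  # 5' at 1005
    h = end_offsets(p4, si, "five_prime")
    assert h.counts == {-5: 1.0}


def test_offset_zero_for_coincident_termini():
    p4 = make_table([dict(sequence="A" * 35, mappings=[("c", 100, "+")])])
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 100, "+")])])
    assert end_offsets(p4, si, "five_prime").counts == {0: 1.0}
    # precursor 3' (134) is downstream of the siRNA 3' (123) -> +11
    assert end_offsets(p4, si, "three_prime").counts == {11: 1.0}


def test_opposite_strand_pairs_excluded():
    p4 = make_table([dict(sequence="A" * 35, mappings=[("c", 100, "+")])])
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 100, "-")])])
    assert end_offsets(p4, si, "five_prime").counts == {}


def test_histogram_mass_equals_overlapping_pair_count():
    p4 = make_table([
        dict(sequence="A" * 35, mappings=[("c", 100, "+")]),
        dict(sequence="G" * 30, mappings=[("c", 120, "+")]),
    ])
    si = make_table([
        dict(sequence="C" * 24, mappings=[("c", 110, "+")]),
        dict(sequence="T" * 24, mappings=[("c", 500, "+")]),  # no overlap
    ])
    h = end_offsets(p4, si, "five_prime")
    assert h.total == 2  # both precursors overlap the first siRNA only


def test_offsets_peak_at_zero_with_internal_skew(study):
    """Both histograms peak at 0; off-zero mass is negative-skewed at the
    5' end and positive-skewed at the 3' end (siRNAs internal)."""
    dcl, col = study["tables"]["dcl2/3/4"], study["tables"]["Col-0"]
    p4 = dcl.subset(dcl.df.index[dcl.df["length"] >= 26])
    si = col.subset(col.df.index[(col.df["length"] == 24) & (col.df["norm"] >= 5)])
    h5 = end_offsets(p4, si, "five_prime")
    h3 = end_offsets(p4, si, "three_prime")
    assert h5.peak() == 0 and h3.peak() == 0
    assert h5.mass(hi=-1) > h5.mass(lo=1)
    assert h3.mass(lo=1) > h3.mass(hi=-1)


# ------------------------------------------------------------------ overlap
def test_overlap_classification():
    p4 = make_table([
        dict(sequence="A" * 30, mappings=[("c", 100, "+")]),  # encompasses
        dict(sequence="G" * 30, mappings=[("c", 120, "+")]),  # partial
        dict(sequence="T" * 30, mappings=[("c", 900, "+")]),  # none
    ])
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 100, "+")], raw=9, norm=9.0)])
    frac, brk = overlap_fraction(p4, si, min_sirna_reads=5)
    assert frac == pytest.approx(2 / 3)
    assert brk == {"encompass": 1, "partial": 1, "none": 1}


def test_overlap_requires_qualifying_sirna():
    p4 = make_table([dict(sequence="A" * 30, mappings=[("c", 100, "+")])])
    si = make_table([dict(sequence="C" * 24, mappings=[("c", 100, "+")], raw=2, norm=2.0)])
    frac, _ = overlap_fraction(p4, si, min_sirna_reads=5)
    assert frac == 0.0
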