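"""Biogenesis model: initiation rule, synthesis, dicing register, genotypes."""

import numpy as np
import pytest

from p4r2scan._util import revcomp, stage_rng
from p4r2scan.biogenesis import (
    P4R2Molecule,
    SimParams,
    _site_weights,
    build_catalog,
    canonical_genotype,
    dice_duplex,
    sample_initiation_site,
    simulate_sample,
    synthesize_p4r2,
)
from p4r2scan.genome import GenomeBundle, LocusPlan, simulate_genome


def _bundle(seq: str) -> GenomeBundle:
    return GenomeBundle(chromosomes={"c": seq})


# ------------------------------------------------------------------ initiation
def test_single_eligible_site_with_ta_only_weights():
    g = _bundle("CCTAGG")
    weights = {("T", "A"): 1.0}
    rng = stage_rng(0, "t")
    draws = sample_initiation_site(("c", 0, 6), g, weights, rng, n=50)
    # CCTAGG is its own reverse complement: the A-after-T occurs at +3 on
    # the top strand and at position 2 reading the bottom strand
    assert set(draws) <= {("c", "+", 3), ("c", "-", 2)}
    for chrom, strand, pos in draws:
        base = g.chromosomes[chrom][pos]
        assert (base if strand == "+" else revcomp(base)) == "A"


def test_no_eligible_position_raises():
    # strict weights: only T-then-A contexts are eligible; an all-G locus
    # has none on either strand (default weights are soft and never empty)
    g = _bundle("G" * 40)
    with pytest.raises(ValueError, match="no eligible initiation position"):
        sample_initiation_site(("c", 0, 40), g, {("T", "A"): 1.0},
                               stage_rng(0, "t"))


def test_initiation_frequencies_match_weights_within_3_sigma():
    """Draw frequencies per (-1,+1) context equal the multinomial
    expectation computed by direct site enumeration."""
    rng0 = np.random.default_rng(123)
    g = _bundle("".join(rng0.choice(list("ACGT"), size=10_000)))
    params = SimParams()
    pos, strands, w = _site_weights(g, "c", 0, 10_000, params.initiation_weights)
    # expected probability of each (prev, base) context = summed site weights
    seq = g.chromosomes["c"]
    ctx_prob: dict = {}
    for p, s, wt in zip(pos, strands, w):
        if s == "+":
            ctx = (seq[p - 1], seq[p])
        else:
            ctx = (revcomp(seq[p + 1]), revcomp(seq[p]))
        ctx_prob[ctx] = ctx_prob.get(ctx, 0.0) + wt
    total = sum(ctx_prob.values())
    n = 10_000
    draws = sample_initiation_site(("c", 0, 10_000), g, params.initiation_weights,
                                   stage_rng(1, "draws"), n=n)
    obs: dict = {}
    for chrom, strand, p in draws:
        if strand == "+":
            ctx = (seq[p - 1], seq[p])
        else:
            ctx = (revcomp(seq[p + 1]), revcomp(seq[p]))
        obs[ctx] = obs.get(ctx, 0) + 1
    for ctx, wsum in ctx_prob.items():
        exp = n * wsum / total
        sd = np.sqrt(exp * (1 - wsum / total))
        assert abs(obs.get(ctx, 0) - exp) <= 3 * sd + 1, f"context {ctx}"


# ------------------------------------------------------------------- synthesis
def test_tt_rate_zero_means_templated_only():
    g = simulate_genome(1, 5000, LocusPlan.empty(), seed=1)
    params = SimParams(tt_rate=0.0)
    rng = stage_rng(2, "syn")
    for site in sample_initiation_site(("chr1", 100, 4900), g,
                                       params.initiation_weights, rng, n=200):
        mol = synthesize_p4r2(site, g, params, rng)
        assert mol.tt_tail == ""
        ref = g.chromosomes[mol.chrom][mol.start : mol.end]
        assert mol.sequence == (ref if mol.strand == "+" else revcomp(ref))
        assert 26 <= mol.templated_length <= 45


def test_tt_rate_one_with_single_length_tail():
    g = simulate_genome(1, 5000, LocusPlan.empty(), seed=1)
    params = SimParams(tt_rate=1.0, tt_tail_len_weights={1: 1.0})
    rng = stage_rng(3, "syn")
    for site in sample_initiation_site(("chr1", 100, 4900), g,
                                       params.initiation_weights, rng, n=100):
        mol = synthesize_p4r2(site, g, params, rng)
        assert len(mol.tt_tail) == 1 and mol.tt_tail == "C"


def test_tail_fraction_matches_tt_rate_binomial_3_sigma():
    g = simulate_genome(1, 10_000, LocusPlan.empty(), seed=4)
    params = SimParams()
    rng = stage_rng(5, "syn")
    n = 50_000
    sites = sample_initiation_site(("chr1", 100, 9900), g,
                                   params.initiation_weights, rng, n=n)
    tailed = sum(
        bool(synthesize_p4r2(s, g, params, rng).tt_tail) for s in sites
    )
    p = params.tt_rate
    assert abs(tailed - n * p) <= 3 * np.sqrt(n * p * (1 - p))


# ---------------------------------------------------------------------- dicing
def _duplex(seq: str, strand: str = "+", start: int = 100) -> P4R2Molecule:
    return P4R2Molecule(chrom="c", strand=strand, start=start,
                        templated_length=len(seq), sequence=seq, id=1)


def test_top_strand_adenosine_dices_from_the_5p_end():
    seq = "A" + "C" * 33 + "G"  # 35 nt, top starts A, bottom starts C
    mol = _duplex(seq)
    [s] = dice_duplex(mol, SimParams(), stage_rng(0, "d"))
    assert s.length == 24
    assert s.derivation_end == "five_prime"
    assert s.start == mol.start  # shared 5' coordinate on the + strand


def test_bottom_strand_adenosine_dices_from_the_3p_end():
    seq = "G" + "C" * 33 + "T"  # top starts G and ends U; bottom starts A
    mol = _duplex(seq)
    [s] = dice_duplex(mol, SimParams(), stage_rng(0, "d"))
    assert s.length == 24
    assert s.derivation_end == "three_prime"
    assert s.start + s.length == mol.end  # shared templated 3' coordinate


def test_minus_strand_register_coordinates():
    seq = "A" + "G" * 30 + "C"  # 32 nt top starts A
    mol = _duplex(seq, strand="-")
    [s] = dice_duplex(mol, SimParams(), stage_rng(0, "d"))
    # transcript 5' of a minus-strand molecule is its highest coordinate
    assert s.derivation_end == "five_prime"
    assert s.start + s.length == mol.end


def test_short_duplex_not_diced():
    assert dice_duplex(_duplex("A" * 20), SimParams(), stage_rng(0, "d")) == []
    # boundary: dicing_len + 1 is required
    assert dice_duplex(_duplex("A" * 24), SimParams(), stage_rng(0, "d")) == []
    assert len(dice_duplex(_duplex("A" * 25), SimParams(), stage_rng(0, "d"))) == 1


def test_both_registers_split_roughly_evenly():
    seq = "A" + "G" * 33 + "T"  # both strands start with A
    mol = _duplex(seq)
    rng = stage_rng(1, "d")
    ends = [dice_duplex(mol, SimParams(), rng)[0].derivation_end for _ in range(400)]
    n5 = ends.count("five_prime")
    assert abs(n5 - 200) <= 3 * np.sqrt(400 * 0.25)


# ------------------------------------------------------------------- genotypes
def test_unknown_genotype_raises():
    with pytest.raises(ValueError, match="unknown genotype"):
        canonical_genotype("dcl9")


def test_knockouts_contain_no_precursors_or_sirnas(study):
    for g in ("nrpd1", "rdr2"):
        truth = study["sims"][g].truth
        assert not truth["kind"].isin(["p4r2", "sirna"]).any()
        # every >= 26 nt molecule is a contaminant (45S/organellar/tRNA-like),
        # never pathway-derived; nothing >= 26 nt maps to siRNA loci
        long = truth[truth["length"] >= 26]
        assert long["kind"].isin(["contaminant1", "contaminant2"]).all()


def test_dcl234_truth_has_no_diced_sirnas(study):
    truth = study["sims"]["dcl2/3/4"].truth
    assert not truth["derivation_end"].isin(["five_prime", "three_prime"]).any()
    assert not (truth["kind"] == "sirna").any()


def test_derivation_end_coordinates_in_truth(study):
    """Every diced siRNA shares the stated end with its parent precursor."""
    truth = study["sims"]["Col-0"].truth
    parents = {
        d.molecule.id: d.molecule for d in study["catalog"].duplexes
    }
    diced = truth[truth["derivation_end"].isin(["five_prime", "three_prime"])]
    assert len(diced) > 100
    for row in diced.itertuples():
        mol = parents[row.parent_p4r2]
        if row.derivation_end == "five_prime":
            p5 = mol.start if mol.strand == "+" else mol.end - 1
            s5 = row.start if mol.strand == "+" else row.end - 1
            assert p5 == s5
        else:
            p3 = mol.end - 1 if mol.strand == "+" else mol.start
            s3 = row.end - 1 if mol.strand == "+" else row.start
            assert p3 == s3


def test_fixed_seed_fastq_is_byte_identical(tmp_path):
    g = simulate_genome(1, 30_000, LocusPlan(n_sirna_loci=20, n_gene=5), seed=6)
    params = SimParams(seed=6, depth=3000)
    outs = []
    for run in ("a", "b"):
        sim = simulate_sample("Col-0", g, params, seed=99)
        path = tmp_path / f"{run}.fastq"
        sim.write_fastq(path)
        outs.append(path.read_bytes())
    assert outs[0] == outs[1] and len(outs[0]) > 0


def test_catalog_deterministic_for_fixed_seed():
    g = simulate_genome(1, 30_000, LocusPlan(n_sirna_loci=20, n_gene=5), seed=6)
    params = SimParams(seed=6)
    c1, c2 = build_catalog(g, params), build_catalog(g, params)
    assert [d.molecule.sequence for d in c1.duplexes] == [
        d.molecule.sequence for d in c2.duplexes
    ]
    assert [d.weight for d in c1.duplexes] == [d.weight for d in c2.duplexes]
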