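"""End consensus and precursor/siRNA spatial relationships.

Computes 5' terminal-base frequencies (24 nt siRNAs in wild type vs
26-32 nt precursors in dcl2/3/4), end-anchored genomic-context logos
(expected: purine at +1 preceded by T), the 5' and 3' end-offset
histograms between precursors and qualifying siRNAs (expected: sharp
peak at offset 0 — single dicing events measured from precursor ends),
and the encompass/overlap statistic (~96%).
"""

import importlib
import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

import json

from p4r2scan._util import derive_seed
from p4r2scan.ends import context_logo, end_offsets, overlap_fraction, terminal_freq
from p4r2scan.genome import GenomeBundle
from p4r2scan.species import threshold


def main() -> None:
    out = cfg.RESULTS
    out.mkdir(parents=True, exist_ok=True)
    genome = GenomeBundle.read(cfg.SCRATCH / "sim" / "genome.fa")
    with open(cfg.SCRATCH / "tables.pkl", "rb") as fh:
        tables = pickle.load(fh)
    col0, dcl = tables[("Col-0", 1)], tables[("dcl2/3/4", 1)]

    si_freq = terminal_freq(threshold(col0, 5.0), "five_prime", (24, 24))
    p4_freq = terminal_freq(threshold(dcl, 5.0), "five_prime", (26, 32))
    print("5' base frequencies —")
    print("  24 nt siRNAs (wild type):", {b: round(f, 3) for b, f in si_freq.items()})
    print("  26-32 nt precursors (dcl2/3/4):", {b: round(f, 3) for b, f in p4_freq.items()})

    p4 = dcl.subset(dcl.df.index[dcl.df["length"] >= 26])
    seed = derive_seed(cfg.SEED, "logos")
    for tag, kwargs in [("all", {}), ("5pA", dict(stratify_by_start="A")),
                        ("5pG", dict(stratify_by_start="G"))]:
        logo = context_logo(p4, genome, "five_prime", seed=seed, **kwargs)
        logo.write_tsv(out / f"logo_5p_{tag}.tsv")
        logo3 = context_logo(p4, genome, "three_prime", seed=seed, **kwargs)
        logo3.write_tsv(out / f"logo_3p_{tag}.tsv")
    logo = context_logo(p4, genome, "five_prime", seed=seed)
    print(f"precursor 5' logo: -1 modal base {logo.modal_base(-1)}, "
          f"+1 purine fraction {logo.freqs.loc[1, ['A', 'G']].sum():.2f}")

    si = col0.subset(col0.df.index[(col0.df["length"] == 24) & (col0.df["norm"] >= 5)])
    h5 = end_offsets(p4, si, "five_prime")
    h3 = end_offsets(p4, si, "three_prime")
    h5.write_tsv(out / "offsets_5p.tsv")
    h3.write_tsv(out / "offsets_3p.tsv")
    print(f"offset histograms: 5' peak at {h5.peak()} "
          f"({100 * h5.counts[0] / h5.total:.1f}% of pair mass at zero); "
          f"3' peak at {h3.peak()} ({100 * h3.counts[0] / h3.total:.1f}%)")

    frac, brk = overlap_fraction(dcl, col0, min_sirna_reads=5)
    json.dump({"overlap_fraction_pct": round(100 * frac, 2), **brk},
              open(out / "overlap_fraction.json", "w"), indent=2)
    print(f"precursors encompassing/overlapping qualifying 24 nt siRNAs: "
          f"{100 * frac:.1f}% ({brk})")


if __name__ == "__main__":
    main()
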