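"""Independent oracles and table-building helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from p4r2scan._util import revcomp
from p4r2scan.align import Alignment, Mismatch
from p4r2scan.species import SampleMeta, SpeciesTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_map(
    seq: str,
    chromosomes: dict[str, str],
    max_mm: int = 1,
    max_hits: int = 50,
) -> list[Alignment]:
    """Exhaustive end-to-end scan over every position and strand.

    Written independently of the k-mer mapper: numpy comparison of the
    read against every window of every chromosome, best-stratum
    filtering, deterministic (chrom, start, strand) order, max_hits cap.
    """
    L = len(seq)
    if set(seq) - set("ACGT"):
        return []
    found = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        rb = np.frombuffer(oriented.encode(), dtype=np.uint8)
        for chrom in sorted(chromosomes):
            ref = np.frombuffer(chromosomes[chrom].encode(), dtype=np.uint8)
            if len(ref) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mm_counts = (windows != rb).sum(axis=1)
            for start in np.nonzero(mm_counts <= max_mm)[0]:
                offs = np.nonzero(windows[start] != rb)[0]
                if len(offs) == 0:
                    mismatch = None
                else:
                    o = int(offs[0])
                    ref_b = chr(windows[start][o])
                    read_b = oriented[o]
                    if strand == "+":
                        mismatch = Mismatch(o + 1, ref_b, read_b)
                    else:
                        mismatch = Mismatch(L - o, _COMP[ref_b], _COMP[read_b])
                found.append(Alignment(chrom, int(start), strand, L, mismatch))
    best = min((1 if a.mismatch else 0 for a in found), default=0)
    stratum = [a for a in found if (a.mismatch is None) == (best == 0)]
    stratum.sort(key=lambda a: (a.chrom, a.start, a.strand))
    return stratum[:max_hits]


def make_table(
    records: list[dict],
    sample_id: str = "s",
    genotype: str = "Col-0",
) -> SpeciesTable:
    """Build a SpeciesTable from crafted records.

    Each record: sequence (or length -> synthetic unique sequence),
    mappings (list of (chrom, start, strand) or Alignment), raw, norm.
    """
    rows, mappings = {}, {}
    for i, rec in enumerate(records):
        seq = rec.get("sequence")
        if seq is None:
            rng = np.random.default_rng(1000 + i)
            seq = "".join(rng.choice(list("ACGT"), size=rec["length"]))
        hits = []
        for m in rec["mappings"]:
            if isinstance(m, Alignment):
                hits.append(m)
            else:
                chrom, start, strand = m
                hits.append(Alignment(chrom, start, strand, len(seq),
                                      rec.get("mismatch")))
        rows[seq] = dict(
            length=len(seq),
            raw=rec.get("raw", 1),
            n_mappings=len(hits),
            norm=rec.get("norm", rec.get("raw", 1)),
        )
        mappings[seq] = tuple(hits)
    if rows:
        df = pd.DataFrame.from_dict(rows, orient="index")
    else:
        df = pd.DataFrame(columns=["length", "raw", "n_mappings", "norm"])
    df.index.name = "sequence"
    return SpeciesTable(
        sample=SampleMeta(sample_id, genotype, total_mapped=int(df["raw"].sum()) or 1),
        df=df,
        mappings=mappings,
    )


def truncated_nb_stats(mean: float, dispersion: float, lo: int, hi: int) -> tuple[float, float]:
    """Analytic mean/sd of the shifted, upper-truncated negative binomial."""
    from scipy import stats

    mu = mean - lo
    k = dispersion
    p = k / (k + mu)
    x = np.arange(0, hi - lo + 1)
    pmf = stats.nbinom.pmf(x, k, p)
    pmf = pmf / pmf.sum()
    m = float((x * pmf).sum())
    var = float(((x - m) ** 2 * pmf).sum())
    return lo + m, np.sqrt(var)
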