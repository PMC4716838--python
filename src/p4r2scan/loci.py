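"""Genotype-contrast interval calls: 100-bp windows where 24 nt siRNAs and
overlapping 26-94 nt precursors co-occur in wild type and are depleted in
the polymerase mutants.

The genome is tiled in non-overlapping windows; per-window abundance is
the sum of fractionally weighted normalized counts of species mappings
overlapping the window (each mapping of a species carries norm /
n_mappings by default). A window is called when 24 nt siRNAs are present
in Col-0, precursor signal is detectable in Col-0, and precursor signal
is substantially reduced in both nrpd1 and rdr2 in at least one
replicate. Elevation in dcl2/3/4 is reported but not required.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biogenesis import GENOTYPES, canonical_genotype
from .species import SpeciesTable


@dataclass(frozen=True)
class CallThresholds:
    sirna_min: float = 1.0  # normalized 24 nt abundance for "siRNA present" (Col-0)
    wt_p4r2_min: float = 1.0  # normalized precursor abundance for "detectable" (Col-0)
    depletion_ratio: float = 0.25  # mutant <= ratio x mean dcl2/3/4 precursor signal
    p4r2_size: tuple = (26, 94)
    sirna_length: int = 24


def _window_signal(
    table: SpeciesTable,
    chrom_lengths: dict[str, int],
    window: int,
    size_range: tuple[int, int],
    fractional: bool = True,
) -> dict[str, np.ndarray]:
    out = {
        c: np.zeros((L + window - 1) // window) for c, L in chrom_lengths.items()
    }
    col = "norm" if "norm" in table.df.columns else "raw"
    lo, hi = size_range
    for seq in table.df.index:
        L = len(seq)
        if not (lo <= L <= hi):
            continue
        hits = table.mappings[seq]
        w = float(table.df.at[seq, col])
        if fractional:
            w /= len(hits)
        for a in hits:
            vec = out.get(a.chrom)
            if vec is None:
                continue
            for wi in range(a.start // window, min((a.end - 1) // window + 1, len(vec))):
                vec[wi] += w
    return out


def detect_intervals(
    tables: dict[tuple[str, int], SpeciesTable],
    chrom_lengths: dict[str, int],
    window: int = 100,
    thresholds: CallThresholds | None = None,
    fractional: bool = True,
) -> pd.DataFrame:
    """Tile the genome and call precursor/siRNA co-occurrence intervals.

    `tables` maps (genotype, replicate) to a normalized species table;
    all four genotypes must be present with at least one replicate each.
    Returns one row per window with per-genotype signals, flags and the
    final call.
    """
    th = thresholds or CallThresholds()
    keyed: dict[str, list[SpeciesTable]] = {g: [] for g in GENOTYPES}
    for (genotype, _rep), table in sorted(tables.items()):
        keyed[canonical_genotype(genotype)].append(table)
    missing = [g for g, ts in keyed.items() if not ts]
    if missing:
        raise ValueError(f"missing genotype sample(s): {', '.join(missing)}")

    p4r2 = {
        g: [_window_signal(t, chrom_lengths, window, th.p4r2_size, fractional) for t in ts]
        for g, ts in keyed.items()
    }
    sirna_col0 = [
        _window_signal(t, chrom_lengths, window, (th.sirna_length, th.sirna_length), fractional)
        for t in keyed["Col-0"]
    ]

    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = (length + window - 1) // window
        for wi in range(n_win):
            sirna = max(sig[chrom][wi] for sig in sirna_col0)
            wt = max(sig[chrom][wi] for sig in p4r2["Col-0"])
            dcl_mean = float(np.mean([sig[chrom][wi] for sig in p4r2["dcl2/3/4"]]))
            nrpd1_dep = [
                sig[chrom][wi] <= th.depletion_ratio * dcl_mean for sig in p4r2["nrpd1"]
            ]
            rdr2_dep = [
                sig[chrom][wi] <= th.depletion_ratio * dcl_mean for sig in p4r2["rdr2"]
            ]
            flags = dict(
                sirna_present=bool(sirna >= th.sirna_min),
                p4r2_wt_detectable=bool(wt >= th.wt_p4r2_min),
                p4r2_dcl_elevated=bool(dcl_mean > wt),
                depleted_nrpd1=bool(any(nrpd1_dep)),
                depleted_rdr2=bool(any(rdr2_dep)),
            )
            called = (
                flags["sirna_present"]
                and flags["p4r2_wt_detectable"]
                and flags["depleted_nrpd1"]
                and flags["depleted_rdr2"]
            )
            if not (called or sirna > 0 or wt > 0 or dcl_mean > 0):
                continue  # keep the output sparse: fully empty windows omitted
            rows.append(dict(
                chrom=chrom, start=wi * window, end=min((wi + 1) * window, length),
                sirna_col0=float(sirna), p4r2_col0=float(wt), p4r2_dcl=dcl_mean,
                p4r2_nrpd1=float(np.mean([s[chrom][wi] for s in p4r2["nrpd1"]])),
                p4r2_rdr2=float(np.mean([s[chrom][wi] for s in p4r2["rdr2"]])),
                replicate_support=int(max(1, min(sum(nrpd1_dep), sum(rdr2_dep)))),
                **flags,
                called=bool(called),
            ))
    return pd.DataFrame(rows)


def write_bed6(calls: pd.DataFrame, path: str | Path, called_only: bool = True) -> None:
    with open(path, "w") as fh:
        sub = calls[calls["called"]] if called_only else calls
        for i, row in sub.iterrows():
            score = min(1000, int(round(row["p4r2_dcl"])))
            fh.write(
                f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                f"interval_{i}\t{score}\t.\n"
            )
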