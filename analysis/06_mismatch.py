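"""3'-mismatch profiling: the terminal-transferase signature.

Builds per-length x per-position mismatch matrices for dcl2/3/4 and
wild type, subtracts the wild-type background (sequencing-error floor),
and reports the fraction of precursor species whose single mismatch sits
at the 3'-terminal read position — the footprint of untemplated C
addition, expected near 5%.
"""

import importlib
import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

from p4r2scan._util import derive_seed
from p4r2scan.mismatch import (
    background_subtract,
    mismatch_matrix,
    terminal_mismatch_fraction,
)


def main() -> None:
    out = cfg.RESULTS
    out.mkdir(parents=True, exist_ok=True)
    with open(cfg.SCRATCH / "tables.pkl", "rb") as fh:
        tables = pickle.load(fh)
    dcl, col0 = tables[("dcl2/3/4", 1)], tables[("Col-0", 1)]

    seed = derive_seed(cfg.SEED, "mismatch")
    mat_dcl = mismatch_matrix(dcl, seed=seed)
    mat_wt = mismatch_matrix(col0, seed=seed)
    sub = background_subtract(mat_dcl, mat_wt)
    mat_dcl.write_tsv(out / "mismatch_matrix_dcl234.tsv")
    mat_wt.write_tsv(out / "mismatch_matrix_col0.tsv")
    sub.write_tsv(out / "mismatch_matrix_subtracted.tsv")
    background_subtract(mat_dcl, mat_wt, clamp=False).write_tsv(
        cfg.SCRATCH / "mismatch_matrix_subtracted_signed.tsv"
    )

    band = [L for L in range(27, 38) if mat_dcl.read_totals[L] >= 200]
    at_end = sum(int(mat_dcl.freq.loc[L, 1:L].idxmax()) in (L, L - 1) for L in band)
    print(f"rows {band[0]}-{band[-1]} of the dcl2/3/4 matrix: mismatch signal "
          f"maximal at the last one or two read positions in {at_end}/{len(band)} rows")
    print("note: wild-type subtraction cancels most terminal signal here because "
          "the simulated wild-type >=26 nt pool consists of residual precursors "
          "carrying the same untemplated tails; a tail-free control isolates the "
          "addition signature (see the test suite)")

    sp = terminal_mismatch_fraction(dcl, seed=seed, weight="species")
    rd = terminal_mismatch_fraction(dcl, seed=seed, weight="reads")
    print(f"precursor species with 3'-terminal mismatch: {sp:.2f}% "
          f"(read-weighted: {rd:.2f}%)")


if __name__ == "__main__":
    main()
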