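"""Shared configuration for the analysis drivers.

One study: a two-chromosome 160 kb genome with ~200 siRNA loci and a
5S-like tandem array, four genotypes x two replicates at the study
depth of 50,000 reads per library. Bulky intermediates
(FASTQ/SAM) live under scratch/, small result tables under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

SEED = 11
DEPTH = 50_000
REPLICATES = 2
GENOTYPES = {"Col-0": "col0", "dcl2/3/4": "dcl234", "nrpd1": "nrpd1", "rdr2": "rdr2"}


def sample_id(genotype: str, rep: int) -> str:
    return f"{GENOTYPES[genotype]}_rep{rep}"
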