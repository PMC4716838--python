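"""In vitro transcription on a circular single-stranded template.

Emulates run-off style transcription by affinity-purified Pol IV or
Pol II on a closed-circular single-stranded DNA genome (M13-like,
7,249 nt): initiation is near-uniform around the circle subject to the
pyrimidine-purine context preference, transcript lengths follow the
polymerase-specific right-skewed model (Pol IV mean 44 / median ~37 nt,
Pol II mean 85 / median ~68 nt), and Pol IV additionally prefers to stop
immediately before an A in the template. Wrap-around past the origin is
allowed and recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import BASES, revcomp, stage_rng
from .biogenesis import SimParams

POL_PROFILES = {"polIV": "invitro_polIV", "polII": "invitro_polII"}


@dataclass
class InvitroResult:
    pol: str
    template: str  # circular, transcript sense is the complement
    transcripts: pd.DataFrame  # start, length, wrapped, sequence

    def write_template_fasta(self, path: str | Path, name: str = "circular_template") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name} circular=true\n")
            for i in range(0, len(self.template), 70):
                fh.write(self.template[i : i + 70] + "\n")


def _random_circle(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_invitro(
    template_len: int = 7249,
    pol_profile: str = "polIV",
    n: int = 10_000,
    seed: int = 0,
    params: SimParams | None = None,
    template: str | None = None,
) -> InvitroResult:
    """Simulate `n` transcripts from a circular single-stranded template.

    The template string is the strand being read 5'->3' in transcript
    coordinates (so transcript sequence is its complement, reported here
    in DNA alphabet as the template slice itself for mapping parity).
    Pol IV ends are re-drawn within ±2 nt to favour an A at the template
    position immediately downstream of the RNA 3' end.
    """
    if pol_profile not in POL_PROFILES:
        raise ValueError(f"pol_profile must be one of {sorted(POL_PROFILES)}")
    params = params or SimParams()
    rng = stage_rng(seed, "invitro", pol_profile)
    if template is None:
        template = _random_circle(template_len, rng)
    elif len(template) != template_len:
        raise ValueError("template length mismatch")
    model = params.length_models[POL_PROFILES[pol_profile]]
    if template_len < model.max:
        raise ValueError("template shorter than the maximum transcript length")

    # initiation: weight every circle position by its (-1, +1) context
    prev = np.array([template[i - 1] for i in range(template_len)])
    base = np.array(list(template))
    w = np.fromiter(
        (params.initiation_weights.get((p, b), 0.0) for p, b in zip(prev, base)),
        dtype=float, count=template_len,
    )
    if w.sum() <= 0:
        raise ValueError("no eligible initiation position on the template")
    starts = rng.choice(template_len, size=n, p=w / w.sum())
    lengths = model.sample(rng, n)

    if pol_profile == "polIV":
        # strong preference for an A at the template position just past the 3' end
        doubled = template + template
        for i in range(n):
            L = int(lengths[i])
            cand = [j for j in range(max(model.min, L - 2), min(model.max, L + 2) + 1)]
            wts = [10.0 if doubled[(starts[i] + j) % template_len] == "A" else 1.0 for j in cand]
            wt = np.asarray(wts, dtype=float)
            lengths[i] = cand[int(rng.choice(len(cand), p=wt / wt.sum()))]

    doubled = template + template
    rows = []
    for s, L in zip(starts, lengths):
        s, L = int(s), int(L)
        rows.append(dict(
            start=s, length=L, wrapped=bool(s + L > template_len),
            sequence=doubled[s : s + L],
        ))
    return InvitroResult(pol=pol_profile, template=template, transcripts=pd.DataFrame(rows))
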