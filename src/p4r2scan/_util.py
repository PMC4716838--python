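"""Shared helpers: reproducible RNG derivation and sequence utilities."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = ("A", "C", "G", "T")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def stage_rng(seed: int, *tags: str) -> np.random.Generator:
    """Derive an independent Generator from a global seed and stage tags.

    Every stochastic step in the package draws its randomness from a
    Generator obtained here, so a single run-level seed determines all
    outputs while stages stay decoupled (adding draws to one stage does
    not perturb another).
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *tags: str) -> int:
    """A stable 31-bit child seed for APIs that take an integer seed."""
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode()) for t in tags)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)


def weighted_choice(rng: np.random.Generator, items: list, weights) -> object:
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("all weights are zero")
    return items[int(rng.choice(len(items), p=w / total))]
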