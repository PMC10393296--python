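"""Shared helpers: sequence alphabet encoding, multiple-testing wrappers, small I/O."""

from __future__ import annotations

import logging

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("ciliareg")

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; N and anything else -> 4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return np.minimum(p * p.size, 1.0)


def check_rng(seed_or_rng) -> np.random.Generator:
    """Accept an int seed or a Generator; default seed is 1."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    if seed_or_rng is None:
        seed_or_rng = 1
    return np.random.default_rng(seed_or_rng)
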