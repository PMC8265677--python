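"""Small shared helpers: printed-table rounding and seeded substreams."""

from __future__ import annotations

import math
import zlib

import numpy as np


def round1(x: float) -> float:
    """Round to one decimal, half away from zero.

    Published count tables round 0.25 -> 0.3, which differs from banker's
    rounding; percentages reported by this package follow the same convention.
    """
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


def percent(count: float, total: float) -> float:
    """A percentage rounded to one decimal as printed in summary tables."""
    if total == 0:
        raise ValueError("percentage with zero denominator")
    return round1(100.0 * count / total)


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-purpose RNG derived from one global seed.

    Each named stream is independent, so adding a consumer never perturbs
    the draws of existing ones.
    """
    tag = zlib.crc32(label.encode())  # stable across processes, unlike hash()
    ss = np.random.SeedSequence([seed, tag])
    return np.random.default_rng(ss)


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


_COMP = str.maketrans("ACGTN", "TGCAN")
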