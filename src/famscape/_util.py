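"""Shared numeric/RNG helpers."""

from __future__ import annotations

import math
import zlib

import numpy as np


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (68.75 -> 69)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


def percentage(part: float, whole: float) -> int:
    """Integer percentage of ``part`` in ``whole``, half-away-from-zero."""
    if whole == 0:
        raise ValueError("percentage of an empty total is undefined")
    return round_half_up(100.0 * part / whole)


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named, reproducible substream of a root seed.

    Streams for distinct labels are statistically independent; the mapping
    label -> stream is stable across platforms (CRC32 of the label).
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )
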