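"""Seed management.

All randomness in the package flows through labelled child generators derived
from one master seed, so any pipeline stage can be re-run independently and
reproducibly: ``child_rng(seed, "stock")`` always yields the same stream
regardless of what other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng"]


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Return a generator for the stream identified by ``label``.

    The stream is a deterministic function of ``(seed, label)`` only.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
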