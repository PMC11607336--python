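"""Named child seeds: every stage draws from its own stream.

All randomness in the package flows from one master seed through
:func:`child_seed`, so each pipeline stage (corpus, phrases, generation,
training, attack) is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master_seed: int, name: str) -> int:
    """Derive a stable 31-bit seed for a named stage from the master seed."""
    h = zlib.crc32(name.encode("utf-8"))
    return int((master_seed * 1_000_003 + h) % (2**31))


def rng_for(master_seed: int, name: str) -> np.random.Generator:
    """A dedicated generator for one named stage."""
    return np.random.default_rng(child_seed(master_seed, name))
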