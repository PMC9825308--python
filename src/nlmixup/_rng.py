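"""Seed derivation shared by all modules.

One user-facing integer seed deterministically derives a distinct sub-seed
per named purpose, so a partial re-run (e.g. re-generating only the
augmented images) reproduces the original streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, purpose: str, index: int = 0) -> int:
    """Derive a sub-seed below 2**31 from (seed, purpose, index)."""
    tag = zlib.crc32(purpose.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag, int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(seed: int, purpose: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, purpose, index))
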