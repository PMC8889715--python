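"""Seed-stream derivation shared by every stochastic stage.

All randomness in the package flows from one master seed. Independent,
reproducible streams for named stages (reference-subset choice, permutation
cells, Tukey Monte-Carlo, simulation) are derived by hashing the stage key
into a :class:`numpy.random.SeedSequence` spawn key, so any stage can be
re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def _key_ints(keys: tuple) -> list[int]:
    out = []
    for k in keys:
        out.append(zlib.crc32(str(k).encode("utf8")))
    return out


def derive_seed(master_seed: int, *keys) -> int:
    """A 31-bit integer seed for stage ``keys``, stable across runs."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF] + _key_ints(keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, *keys) -> np.random.Generator:
    """Generator on the independent stream keyed by ``keys``."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF] + _key_ints(keys))
    return np.random.default_rng(ss)
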