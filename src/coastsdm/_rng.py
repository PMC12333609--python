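"""Deterministic seed derivation for every stochastic stage.

A single master seed fans out to per-stage, per-counter generators via
``numpy.random.SeedSequence`` spawn keys, so reruns with the same master
seed are bit-identical and stages are statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """A stable 31-bit integer seed for (master, stage, counter)."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(zlib.crc32(stage.encode()), int(counter)),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, stage: str, counter: int = 0) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage, counter))
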