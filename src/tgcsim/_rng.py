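"""Seed handling: one root seed per run, split per component by name.

Each component (cohort sampling, sensor noise, per-patient trial, ...) draws
from its own named stream derived from the run seed, so adding a component
or reordering draws in one place cannot perturb another component's stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Return the named child RNG stream of a root seed."""
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)


def child_seeds(seed: int, name: str, n: int) -> list[int]:
    """Derive ``n`` independent integer seeds (< 2**31) from a named stream."""
    rng = rng_for(seed, name)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]
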