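"""Deterministic named random substreams derived from one pipeline seed.

Every module draws randomness from a substream named after the operation,
so adding draws in one stage never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _name_key(name: str) -> int:
    # crc32 is stable across platforms and Python versions
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``."""
    keys = tuple(_name_key(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=keys))


def substream_seed(seed: int, *names: str) -> int:
    """A 31-bit integer seed for libraries that take plain int seeds."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
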