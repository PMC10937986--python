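"""Seeded random-number substreams.

A single master seed drives a whole validation run.  Every stochastic
component (partitioning, sample draws, learn/validate splits, tree
tie-breaking, scene synthesis) pulls its generator from a *named*
substream so that each component is independently reproducible and
insensitive to the order in which the others consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_int"]


def _key(name: object) -> int:
    return zlib.crc32(str(name).encode("utf-8"))


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream is a deterministic function of ``seed`` and the name
    path; distinct name paths give statistically independent streams.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [_key(n) for n in names]
    return np.random.default_rng(entropy)


def spawn_int(rng: np.random.Generator) -> int:
    """Draw a 31-bit integer suitable as a child seed (e.g. sklearn)."""
    return int(rng.integers(0, 2**31 - 1))
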