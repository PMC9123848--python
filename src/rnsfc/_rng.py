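"""Seed-stream plumbing.

Every stochastic stage derives its generator from one root seed plus a
stable textual label, so reruns with the same seed are bit-identical and
stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Generator for the substream identified by ``names`` under ``seed``."""
    keys = [zlib.crc32(str(n).encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *keys]))


def child_seed(seed: int, *names: object) -> int:
    """A derived integer seed (< 2**31) for the given substream."""
    return int(substream(seed, *names).integers(2**31))
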