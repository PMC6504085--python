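"""Named reproducible random sub-streams derived from a single run seed."""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator keyed by (seed, name).

    Different names give independent streams; the same (seed, name) pair
    always reproduces the same stream, so individual pipeline stages can be
    re-run in isolation.
    """
    return np.random.default_rng([int(seed) & 0xFFFFFFFF, zlib.crc32(name.encode("utf-8"))])
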