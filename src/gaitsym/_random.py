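"""Named, reproducible random sub-streams.

All randomness in the package flows from one master seed.  Each consumer asks
for a sub-stream identified by a path of names/integers, e.g.
``substream(seed, "cohort", 7)``.  Streams are independent (SeedSequence
spawn keys), so adding a subject or another repeat never perturbs draws made
from earlier streams.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep derived keys in uint32 range


def _key_part(part: str | int) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8")) & _MASK
    return int(part) & _MASK


def substream(seed: int, *path: str | int) -> np.random.Generator:
    """Return a Generator for the sub-stream identified by ``path``."""
    key = tuple(_key_part(p) for p in path)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def subseed(seed: int, *path: str | int) -> int:
    """A plain integer seed (< 2**31) derived from a sub-stream, for APIs that want one."""
    return int(substream(seed, *path).integers(0, 2**31 - 1))
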