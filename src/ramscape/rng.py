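"""Seeded random-number substreams.

All stochastic stages derive their generator from one root seed plus a stable
stream name, so partial re-runs of any stage reproduce exactly regardless of
what ran before them.
"""

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The name is hashed with CRC32 so the mapping is stable across sessions
    and platforms (Python's ``hash`` is salted per process).
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
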