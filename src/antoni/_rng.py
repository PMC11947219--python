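"""Seeded random-number substreams.

All stochastic code in the package draws from a single root seed through
named substreams, so stages can be re-run independently and still be
reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream ``names`` of root ``seed``.

    The substream key is derived from CRC32 of the names, so the same
    (seed, names) always yields the same stream and distinct names yield
    independent streams.
    """
    keys = [zlib.crc32(str(n).encode("utf8")) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))
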