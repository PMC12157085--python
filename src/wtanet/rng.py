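"""Named, independent random-number streams.

Every source of randomness in the package (weight sampling, initial
conditions, WTA tie-breaks, external input noise, finite-size mean-field
sampling) draws from its own named stream derived from a single base seed.
Changing one experimental factor therefore never reshuffles another.
"""
from __future__ import annotations

import zlib

import numpy as np

#: Stream names used across the package.
STREAMS = ("weights", "init", "ties", "external", "meanfield")


def stream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Return a Generator for the stream ``name`` under ``seed``.

    ``extra`` integers (e.g. a block index or a trial number) further
    separate sub-streams deterministically.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key, *map(int, extra)])
    return np.random.default_rng(ss)


def spawn_seeds(seed: int, name: str, n: int) -> list[int]:
    """Derive ``n`` reproducible integer sub-seeds (< 2**31) from a stream."""
    g = stream(seed, name)
    return [int(s) for s in g.integers(0, 2**31 - 1, size=n)]
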