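"""Seed-substream plumbing.

Every generator in the package derives its random state from one integer
seed through a named substream, so adding a new generator (or calling one
more often) never perturbs the draws of any other component.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent ``Generator`` for component ``name``.

    The stream key is a CRC32 hash of the component name, used as a
    ``spawn_key`` on the master ``SeedSequence`` — a counter-based scheme
    in which each named component owns a fixed, order-independent stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
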