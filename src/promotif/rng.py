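"""Named random substreams derived from one master seed.

Every stochastic stage (genome, planting, counts, null resampling, per-motif
nulls) draws from its own generator, derived from the master seed plus a
stable hash of the stream name. Stages are therefore independently
reproducible: rerunning only the planting stage with the same master seed
yields the same plantings regardless of what else ran.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    The stream key is ``crc32(name)``, mixed with the master seed through
    :class:`numpy.random.SeedSequence`, so streams are decorrelated and
    stable across platforms and sessions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for the named substream."""
    key = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]).generate_state(1)[0] & 0x7FFFFFFF)
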