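"""Named random substreams derived from a single global seed.

Every stochastic operation in the package draws from its own substream so that
any pipeline stage can be re-run in isolation and reproduce its output exactly,
independent of what ran before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The stream name is hashed with CRC-32 and mixed into a SeedSequence, so
    distinct names give statistically independent streams while identical
    ``(seed, name)`` pairs always reproduce the same draws.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
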