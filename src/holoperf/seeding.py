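"""Named random substreams.

All randomness in a run flows from a single top-level seed.  Each stage
draws from its own named substream so that, e.g., regenerating the noise
does not perturb the vascular trees.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named substream of ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )
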