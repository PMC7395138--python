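"""Named random substreams derived from a single top-level seed.

Every stochastic step draws from ``substream(seed, name)`` so that the
whole pipeline is reproducible from one integer and independent stages
never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic generator for a named stage under a top-level seed."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
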