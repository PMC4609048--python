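"""Named substreams derived from one master seed.

Every stochastic stage draws from a stream keyed by the master seed plus a
stable textual tag, so stages can be re-run independently and a whole run is
reproducible bit-for-bit from the master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "stream_rng", "derive_seed"]


def substream(master: int, *tags: object) -> np.random.SeedSequence:
    """SeedSequence for the stream named by ``tags`` under ``master``."""
    key = tuple(zlib.crc32(str(t).encode("utf-8")) for t in tags)
    return np.random.SeedSequence(entropy=int(master), spawn_key=key)


def stream_rng(master: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(substream(master, *tags))


def derive_seed(master: int, *tags: object) -> int:
    """A plain integer seed (< 2**31) for the named stream."""
    return int(substream(master, *tags).generate_state(1, dtype=np.uint32)[0] % (2**31))
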