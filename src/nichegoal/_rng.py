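"""Named random substreams.

All randomness in the package flows from a single user seed.  Independent
substreams are derived deterministically from (seed, name) so that, e.g.,
environment draws and phenotype draws never share a stream and adding a new
consumer of randomness does not perturb existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream is a PCG64 generator keyed by the user seed and a CRC32 of the
    stream name, so it is reproducible across processes and platforms.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
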