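"""Deterministic RNG stream derivation.

Every stochastic component draws from a :class:`numpy.random.Generator`
derived from a single user seed plus a small integer *stream* index via
``numpy.random.SeedSequence(seed, spawn_key=(stream,))``.  Sub-components
therefore stay independently reproducible: re-running only the trait
simulation, say, consumes the same stream regardless of what else ran.

Stream indices used by the simulator:

====== =========================
stream component
====== =========================
0      Yule tree
1      Brownian-motion traits
2      transect metadata noise
3      metacommunity sampling
====== =========================
"""

from __future__ import annotations

import numpy as np

STREAM_TREE = 0
STREAM_TRAITS = 1
STREAM_METADATA = 2
STREAM_COMMUNITY = 3


def rng_stream(seed: int, stream: int = 0) -> np.random.Generator:
    """Return the generator for (``seed``, ``stream``)."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(int(stream),)))


def derive_seed(seed: int, stream: int = 0) -> int:
    """Derive a child integer seed (< 2**31) from (``seed``, ``stream``)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=(int(stream),))
    return int(ss.generate_state(1)[0] % (2**31))
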