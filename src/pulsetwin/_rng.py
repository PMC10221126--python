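"""Named random substreams derived from one master seed.

Every source of randomness in the package (synthetic data, pair sampling,
weight initialisation, evaluation shuffles) draws from its own substream so
that changing how one stage consumes randomness never perturbs another.
"""

from __future__ import annotations

import numpy as np

# Stable substream indices; append only, never renumber.
_STREAMS = {
    "data": 0,
    "pairs": 1,
    "init": 2,
    "eval": 3,
    "noise": 4,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a deterministic Generator for the named purpose.

    Parameters
    ----------
    seed : master seed (any non-negative int).
    name : one of ``data``, ``pairs``, ``init``, ``eval``, ``noise``.
    """
    if name not in _STREAMS:
        raise KeyError(f"unknown substream {name!r}; known: {sorted(_STREAMS)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    return np.random.Generator(np.random.PCG64(ss))
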