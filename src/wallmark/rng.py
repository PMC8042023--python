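"""Seeded random-number substreams.

One root seed controls the whole run; every stochastic element draws from a
named substream so that toggling one stage (e.g. rendering shot noise) never
perturbs the draws of another (e.g. motor placement).
"""

from __future__ import annotations

import numpy as np

# Fixed registry: the spawn key of each substream is its index here, so the
# mapping name -> stream is stable across versions and platforms.
_SUBSTREAMS = (
    "placement",
    "lateral",
    "noise",
    "miss",
    "coin",
    "shot",
    "bootstrap",
    "initial_law",
    "body_noise",
)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return the independent generator for ``name`` under ``root_seed``."""
    if name not in _SUBSTREAMS:
        raise KeyError(f"unknown RNG substream {name!r}; known: {_SUBSTREAMS}")
    key = _SUBSTREAMS.index(name)
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(key,)))


def substream_seeds(root_seed: int) -> dict[str, int]:
    """Stable integer seed per substream, for manifests."""
    out = {}
    for i, name in enumerate(_SUBSTREAMS):
        ss = np.random.SeedSequence(root_seed, spawn_key=(i,))
        out[name] = int(ss.generate_state(1, dtype=np.uint32)[0])
    return out
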