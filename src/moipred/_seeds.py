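"""Deterministic seed derivation.

One user-facing integer seed drives every stochastic step; components derive
independent streams through named spawn keys so each can be regenerated in
isolation.
"""

from __future__ import annotations

import numpy as np


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Child generator of ``seed`` under a fixed spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def sk_seed(rng: np.random.Generator) -> int:
    """An integer seed below 2**31 for scikit-learn random_state."""
    return int(rng.integers(0, 2**31 - 1))
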