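"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def logit(p: np.ndarray | float) -> np.ndarray | float:
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Deterministic child seed sequences for hierarchical seeding."""
    return np.random.SeedSequence(seed).spawn(n)
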