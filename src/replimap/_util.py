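"""Shared helpers: deterministic child RNG streams and small numerics."""

from __future__ import annotations

import numpy as np


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic child generator for a named stream of a master seed.

    Each generator role in the package owns a fixed stream number, so adding
    a new generator never perturbs the draws of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(int(stream),)))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation over positions where both arrays are finite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 2:
        return float("nan")
    a, b = a[m], b[m]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
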