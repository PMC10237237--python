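"""Small shared numerics: apportionment and seed derivation."""

from __future__ import annotations

import numpy as np


def largest_remainder(total: int, weights) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Floors the exact quotas, then hands the leftover units to the largest
    fractional remainders; remainder ties break toward the earlier index.
    The result always sums to ``total`` exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    if total < 0:
        raise ValueError("total must be non-negative")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short:
        remainder = quota - counts
        # stable sort on -remainder: ties go to the earlier index
        order = np.argsort(-remainder, kind="stable")
        counts[order[:short]] += 1
    return counts


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent, reproducible generators from one seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
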