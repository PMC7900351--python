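"""Seed derivation and sampling helpers used throughout the simulators."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "rng_for", "weighted_sample"]

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def child_seed(seed: int, label: str) -> int:
    """Derive a reproducible per-stage seed from a master seed and a stage label.

    The derivation is position-independent: a stage's seed depends only on the
    master seed and its label, so adding stages never reshuffles existing ones.
    """
    ss = np.random.SeedSequence([int(seed) & _SEED_MASK, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0]) & _SEED_MASK


def rng_for(seed: int, label: str) -> np.random.Generator:
    """A Generator seeded deterministically for the named stage."""
    return np.random.default_rng(child_seed(seed, label))


def weighted_sample(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """Draw ``k`` indices with replacement, proportional to nonnegative ``weights``.

    Implemented as inverse-CDF sampling; faster than ``Generator.choice`` for
    the many-small-populations pattern of per-cell read sampling.
    """
    cdf = np.cumsum(weights, dtype=np.float64)
    total = cdf[-1]
    if not total > 0:
        raise ValueError("weights must have a positive sum")
    u = rng.random(k) * total
    return np.searchsorted(cdf, u, side="right").astype(np.int64)
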