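"""Deterministic random-stream derivation.

Every stochastic step in the pipeline (near-zero-noise imputation, fold
splitting, forest seeding, augmentation sampling, simulation) draws from a
stream derived from a single root seed plus a stable string key, so that a
fixed configuration seed makes the whole pipeline reproducible while keeping
independent steps statistically decoupled.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key: str) -> int:
    # crc32 is stable across processes (unlike hash()) and cheap.
    return zlib.crc32(key.encode("utf-8"))


def derive_rng(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and a sequence of keys.

    Keys may be strings or integers; strings are hashed with CRC-32 so the
    derivation does not depend on the process hash seed.
    """
    entropy = [int(seed)]
    for k in keys:
        entropy.append(_key_to_int(k) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def derive_seed(seed: int, *keys: object) -> int:
    """A 31-bit integer seed derived from ``seed`` and keys (for sklearn)."""
    return int(derive_rng(seed, *keys).integers(0, 2**31 - 1))
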