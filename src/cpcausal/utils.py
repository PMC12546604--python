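"""Small shared helpers: seeding, validation, stable hashing."""

from __future__ import annotations

import hashlib
import zlib

import numpy as np


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of ``"{global_seed}:{stage}"``, masked to 31 bits."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def stable_digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()
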