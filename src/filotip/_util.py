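"""Small shared helpers: seed derivation and array validation."""

from __future__ import annotations

import hashlib

import numpy as np

from .errors import ArgumentError


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a global seed.

    Stages seeded this way are reproducible independently of the order in
    which other stages run.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def as_1d_float(values, name: str, min_len: int = 0) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < min_len:
        raise ArgumentError(f"{name} needs at least {min_len} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ArgumentError(f"{name} contains non-finite values")
    return arr
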