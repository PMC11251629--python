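"""Deterministic seed derivation.

One root seed governs a whole simulation; every stochastic component draws
from a child stream keyed by a stable token path (muscle name, unit rank,
trial id, ...).  Hashing the token path means adding one unit or trial never
perturbs the draws of any other.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(root_seed: int, *tokens) -> int:
    """A 63-bit seed that is a pure function of (root_seed, tokens)."""
    key = repr((int(root_seed),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "little") & ((1 << 63) - 1)


def child_rng(root_seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(child_seed(root_seed, *tokens))
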