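"""Small shared helpers (seed derivation, validation)."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, name: str) -> int:
    """Derive a child seed from a global seed and a stage/component name.

    Stable across sessions and platforms (SHA-256 based), always < 2**31,
    so stages can be rerun in isolation with the seed recorded in a manifest.
    """
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_from(seed: int, name: str | None = None) -> np.random.Generator:
    if name is not None:
        seed = derive_seed(seed, name)
    return np.random.default_rng(seed)
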