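"""Deterministic seed derivation.

Child seeds are derived by hashing (master_seed, component_name) with SHA-256,
so adding a new random component to a simulation never shifts the draws of
existing components, and any component can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK = 2**31 - 1


def child_seed(master_seed: int, name: str) -> int:
    """Stable sub-seed for a named component, in [0, 2^31)."""
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:8], "little") & _MASK


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, name))


def counter_rng(master_seed: int, counter: int) -> np.random.Generator:
    """Counter-based generator: realization ``counter`` is reproducible from
    (master_seed, counter) alone, enabling parallel Monte-Carlo."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & _MASK, int(counter)]))
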