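"""Seed-stream derivation.

Every stage of a run draws from its own generator, derived from the master
seed by a stable text label, so adding or reordering stages never perturbs
the draws of the others.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 2**31 - 1


def derive_seed(master_seed: int, label: str) -> int:
    """A stable 31-bit sub-seed for ``label`` under ``master_seed``."""
    return (int(master_seed) ^ zlib.crc32(label.encode("utf-8"))) & _MASK


def derive_rng(master_seed: int, label: str) -> np.random.Generator:
    """An independent generator for the stage named ``label``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & _MASK, zlib.crc32(label.encode("utf-8"))])
    )


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept a Generator, an int seed, or None (fresh entropy)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
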