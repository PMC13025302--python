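"""Deterministic seed derivation.

One master seed fans out to named substreams (data sampling, weight init,
augmentation, evaluation, per-sample generation) so each subsystem is
independently reproducible and insensitive to execution order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(master: int, *keys) -> int:
    """A stable 31-bit seed derived from a master seed and hashable keys."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(master: int, *keys) -> np.random.Generator:
    """A numpy Generator seeded from (master, keys)."""
    return np.random.default_rng(derive_seed(master, *keys))
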