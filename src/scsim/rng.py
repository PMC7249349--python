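"""Deterministic seed derivation.

Every stage of the simulator draws from its own ``numpy.random.Generator``
seeded by a child seed derived from the master seed plus a stable tuple of
string tokens (stage name, unit id, sample id, ...).  Adding a sample to a
design therefore never perturbs the draws of any other sample, and reruns
with the same master seed are bitwise reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master_seed: int, *tokens: object) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and tokens."""
    key = "|".join([str(int(master_seed)), *(str(t) for t in tokens)])
    digest = hashlib.blake2b(key.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, *tokens: object) -> np.random.Generator:
    """A fresh Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *tokens))
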