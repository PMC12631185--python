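"""Deterministic seed derivation.

All randomness in the package flows from a single master seed through
named sub-streams, so that any stage can be re-run in isolation and the
whole pipeline is a pure function of its configuration.
"""

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_from"]

_MOD = 2**31 - 1


def child_seed(master: int, *keys) -> int:
    """Derive a stable 31-bit seed from a master seed and a key path.

    The derivation hashes the repr of (master, *keys) with SHA-256, so it
    is stable across processes and platforms and independent of numpy's
    own seeding internals.
    """
    payload = repr((int(master),) + tuple(keys)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def rng_from(master: int, *keys) -> np.random.Generator:
    """A numpy Generator seeded from a named sub-stream of ``master``."""
    return np.random.default_rng(child_seed(master, *keys))
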