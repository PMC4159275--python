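"""Deterministic seed fan-out.

A single master seed is expanded into independent per-stage / per-bin /
per-replicate seeds by hashing the key path. This keeps every replicate
reproducible on its own (order-independent), which matters when ensembles
are generated lazily or in parallel.
"""

from __future__ import annotations

import hashlib


def derive_seed(base_seed: int, *keys: object) -> int:
    """Derive a child seed from ``base_seed`` and a path of hashable keys.

    The result is a non-negative int below 2**31, stable across runs and
    platforms (blake2b of the repr of the key path).
    """
    payload = repr((int(base_seed),) + tuple(str(k) for k in keys)).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
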