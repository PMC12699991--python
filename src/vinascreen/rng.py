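"""Deterministic seed derivation.

Per-job seeds are derived from a master seed by hashing the job identity,
not by drawing from shared RNG state, so a seed manifest is reproducible
regardless of enumeration order, worker count, or interrupted runs.
"""

from __future__ import annotations

import hashlib


def stable_seed(*parts: object, modulus: int = 2**31) -> int:
    """A stable integer in [0, modulus) from a tuple of identity parts."""
    key = "\x1f".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % modulus
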