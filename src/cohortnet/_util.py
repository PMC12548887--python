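"""Small shared helpers."""

from __future__ import annotations

import zlib


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a reproducible sub-seed from a master seed and context tokens.

    Keeps every derived seed in [0, 2**31 - 2] so it is safe for any RNG
    constructor. Distinct token tuples give (with overwhelming probability)
    distinct streams, so per-pair / per-network randomness is independent yet
    fully determined by the master seed.
    """
    h = zlib.crc32("|".join(str(t) for t in tokens).encode("utf-8"))
    return (int(master) * 1_000_003 + h) % (2**31 - 1)
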