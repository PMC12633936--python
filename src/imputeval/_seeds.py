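"""Deterministic seed derivation.

Every stochastic component of the pipeline draws from a
``numpy.random.Generator`` seeded through :func:`derive_seed`, so that any
cell of the experiment grid can be reproduced in isolation from the master
seed and the cell's coordinates.
"""

from __future__ import annotations

import hashlib


def derive_seed(*parts: object) -> int:
    """Derive a stable 31-bit seed from an arbitrary key.

    The key is the ``repr`` of the parts joined with ``|``; hashing is
    BLAKE2b, so the mapping is stable across processes and platforms
    (unlike builtin ``hash``).
    """
    key = "|".join(repr(p) for p in parts).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)
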