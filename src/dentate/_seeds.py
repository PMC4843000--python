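"""Deterministic child-seed derivation.

Every stochastic stage derives its generator from a single master seed plus a
stable sequence of tokens (stage name, grid indices).  The scheme is pure
arithmetic on the tokens, so results are independent of execution order and
individual stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_sequence", "child_rng"]


def _token_key(token: object) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    return zlib.crc32(str(token).encode("utf-8"))


def child_sequence(master_seed: int, *tokens: object) -> np.random.SeedSequence:
    """SeedSequence for a stage identified by ``tokens`` under ``master_seed``."""
    entropy = [int(master_seed) & 0xFFFFFFFF] + [_token_key(t) for t in tokens]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *tokens: object) -> np.random.Generator:
    """Independent Generator for a stage identified by ``tokens``."""
    return np.random.default_rng(child_sequence(master_seed, *tokens))
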