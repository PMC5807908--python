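"""Deterministic seed fan-out.

A single master seed is expanded into independent per-stage seeds by hashing
a stage tag, so adding a new stage never perturbs the random streams of
existing stages.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(master: int, *tags: object) -> int:
    """Derive a sub-seed (< 2^31) from a master seed and a stage tag path."""
    key = "/".join(str(t) for t in tags)
    crc = zlib.crc32(key.encode("utf-8"))
    ss = np.random.SeedSequence([int(master) % _MOD, crc])
    return int(ss.generate_state(1)[0] % _MOD)


def derive_rng(master: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tags))
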