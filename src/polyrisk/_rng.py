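"""Seed-hierarchy helpers.

All randomness in the package flows through :func:`spawn_rng` /
:func:`spawn_seed` so that a single integer seed plus a stage name yields an
independent, reproducible stream per stage (simulation, fold splitting,
relatedness pruning, MCMC, ...).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "spawn_seed"]


def _key(parts: tuple) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode()))
        else:
            out.append(int(p) & 0xFFFFFFFF)
    return tuple(out)


def spawn_rng(seed: int, *stage: str | int) -> np.random.Generator:
    """Generator for stream ``stage`` derived from the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=_key(stage)))


def spawn_seed(seed: int, *stage: str | int) -> int:
    """A plain 31-bit integer seed for code that cannot take a Generator."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_key(stage))
    return int(ss.generate_state(1)[0] % (2**31))
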