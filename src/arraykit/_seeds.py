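"""Deterministic per-stage seed derivation.

A single user-facing seed reproduces the whole pipeline, while each stage
(shearing, assembly, duplication, reads, permutation) gets an independent
stream: ``stage_seed(seed, name)`` hashes the stage name into a
``numpy.random.SeedSequence`` spawn key. Derived seeds stay below 2**31 so
they survive round-trips through JSON/YAML and command lines.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named pipeline stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from :func:`stage_seed`."""
    return np.random.default_rng(stage_seed(seed, stage))
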