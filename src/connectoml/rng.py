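"""Deterministic per-stage random streams.

Every stage of the pipeline draws from its own stream derived from one
top-level seed plus a string label, so stages are independently reproducible
and no stage perturbs another's draws. Derivation goes through
``numpy.random.SeedSequence`` with the CRC-32 of each label as extra entropy.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_int_seed"]


def _seed_sequence(seed: int, labels: tuple[str, ...]) -> np.random.SeedSequence:
    entropy = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(l.encode()) for l in labels]
    return np.random.SeedSequence(entropy)


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """A ``numpy`` Generator unique to (seed, labels...)."""
    return np.random.default_rng(_seed_sequence(seed, labels))


def derive_int_seed(seed: int, *labels: str) -> int:
    """A 31-bit integer seed for libraries that take plain ints (sklearn)."""
    return int(_seed_sequence(seed, labels).generate_state(1)[0] % (2**31))
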