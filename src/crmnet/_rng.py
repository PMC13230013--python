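"""Hierarchical random-number streams.

One master seed spawns an independent, named stream per pipeline stage so
that each stage is individually reproducible: regenerating the sequencing
step does not consume draws from the network generator, and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "coerce_rng"]


def stream(master_seed: int, label: str) -> np.random.Generator:
    """Return the named child generator of ``master_seed``.

    The label is hashed with CRC-32 (stable across platforms and Python
    processes, unlike :func:`hash`) into the ``spawn_key`` of a
    :class:`numpy.random.SeedSequence`.
    """
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def coerce_rng(seed_or_rng) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
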