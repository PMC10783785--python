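"""Named, reproducible random substreams.

Every stochastic stage of the pipeline (nucleus placement, stain noise,
expression sampling, survival times, block/nucleus sampling, CV folds,
cohort splits, permutations) draws from its own named substream of a single
master seed, so a stage can be regenerated without replaying the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the generator for substream ``name`` of ``seed``.

    The mapping is stable across processes: the stream is keyed by the
    CRC-32 of the name, spawned off a :class:`numpy.random.SeedSequence`.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_key(name),)))


def substream_seed(seed: int, name: str, index: int = 0) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_key(name), index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
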