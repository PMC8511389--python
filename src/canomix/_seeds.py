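"""Deterministic seed derivation.

A single master seed fans out into named substreams (plant placement,
emergence delays, tiller draws, ...) and into per-row campaign seeds, so that
reruns, partial reruns and parallel execution all see identical random state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "row_seed"]


def _tag_to_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def substream(master_seed: int, tag: str) -> np.random.Generator:
    """Named, independent RNG substream of a master seed."""
    ss = np.random.SeedSequence([int(master_seed), _tag_to_int(tag)])
    return np.random.Generator(np.random.PCG64(ss))


def row_seed(campaign_seed: int, row_index: int) -> int:
    """Counter-based per-row seed, stable under parallelism and reruns.

    Kept below 2**31 so it can be passed anywhere a small int seed is expected.
    """
    ss = np.random.SeedSequence([int(campaign_seed), int(row_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
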