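"""Seed-splitting helpers.

All randomness in the package flows from one master seed. Each pipeline
stage draws its generator from a named substream so that adding or
re-running one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _tag_to_int(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def substream(master_seed: int, tag: str) -> np.random.Generator:
    """Return the deterministic generator for stage `tag` under `master_seed`."""
    ss = np.random.SeedSequence([int(master_seed), _tag_to_int(tag)])
    return np.random.default_rng(ss)


def subseed(master_seed: int, tag: str) -> int:
    """A plain integer seed (< 2**31) derived for stage `tag`."""
    ss = np.random.SeedSequence([int(master_seed), _tag_to_int(tag)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
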