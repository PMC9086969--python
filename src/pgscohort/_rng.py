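"""Deterministic per-stage random substreams.

One global integer seed expands into independent child generators keyed by a
stage label, so any stage can be re-run in isolation and reproduce its draws.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, label: str) -> int:
    """A stable 31-bit integer seed derived from (seed, label)."""
    h = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), h])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def substream(seed: int, label: str) -> np.random.Generator:
    """Child generator for a named stage, deterministic in (seed, label)."""
    h = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))
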