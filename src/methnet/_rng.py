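"""Deterministic random-stream derivation.

One global seed lives in the simulation config; every output type draws
from its own named substream so that adding or reordering one output
does not perturb the randomness of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The label is folded in through CRC32, which is stable across
    processes (unlike ``hash``), so identical (seed, label) pairs give
    byte-identical streams on every platform.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
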