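"""Deterministic substream derivation from one master seed."""

from __future__ import annotations

import zlib

import numpy as np

DEFAULT_SEED = 123


def substream(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for stage ``labels`` derived from ``seed``.

    Independent stages get independent, reproducible streams; the same
    (seed, labels) pair always yields the same stream.
    """
    keys = [zlib.crc32(str(lab).encode("utf8")) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))
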