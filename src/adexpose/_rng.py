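"""Seeded random substreams.

Every stochastic stage of the pipeline pulls from a named substream derived
from a single base seed, so that stages are independently reproducible and
adding draws to one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    Deterministic: the same pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
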