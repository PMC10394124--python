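"""Named per-stage random streams.

Every stochastic stage of a simulation draws from its own generator derived
from (seed, stage name), so adding or reordering stages never perturbs the
stream of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a stable hash of ``stage``."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
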