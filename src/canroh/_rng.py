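"""Seed-stream management.

Every stochastic operation derives its generator from a global seed plus a
small integer key path, so adding samples or stages never perturbs the draws
of earlier ones.
"""

from __future__ import annotations

import numpy as np

# Stable operation indices for substream derivation. New operations append;
# renumbering would silently change all downstream draws.
OP_PANEL = 1
OP_TRUTH = 2
OP_IMPUTE = 3
OP_PSEUDOHAP = 4
OP_COHORTS = 5
OP_DEPTHS = 6
OP_PERMTEST = 7


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for (seed, key-path), independent across key paths."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)
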