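"""Seed plumbing: every stochastic routine accepts an int, None, or an
already-spawned SeedSequence, and derives independent child streams from it."""

import numpy as np


def as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)
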