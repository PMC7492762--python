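"""Named random substreams derived from one integer seed.

Every stochastic routine in the package takes a plain integer seed and
derives its generator here, so stage-level results are reproducible
independently of execution order and no global numpy state is touched.
"""

from __future__ import annotations

import numpy as np

__all__ = ["substream", "child_seed"]


def _label_key(label) -> int:
    # stable, platform-independent mapping of a short string/int label to a 32-bit key
    if isinstance(label, (int, np.integer)):
        return int(label) % (2**32)
    acc = 0
    for ch in str(label):
        acc = (acc * 131 + ord(ch)) % (2**32)
    return acc


def substream(seed: int, *labels) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    keys = [_label_key(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**32), *keys]))


def child_seed(seed: int, *labels) -> int:
    """A derived integer seed (< 2**31) for APIs that want a plain int."""
    return int(substream(seed, *labels).integers(0, 2**31 - 1))
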