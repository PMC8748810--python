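"""Named, order-independent random substreams.

Every stochastic stage derives its generator from (root seed, stage name), so
adding or reordering stages never perturbs the draws of existing ones and
results are independent of call order or threading.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
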