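"""Named random substreams.

All randomness in the package flows from a single integer root seed through
:func:`substream`, which derives an independent child generator from the root
seed plus a string label.  No module touches numpy's global state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels``.

    The same ``(seed, labels)`` pair always yields a bit-identical stream;
    different labels yield statistically independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(lab).encode("utf8")) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy))
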