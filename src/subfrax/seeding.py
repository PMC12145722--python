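"""Counter-based random substreams.

One master seed drives the whole experiment.  Every (patient, fraction,
interval, purpose) combination gets its own :class:`numpy.random.Generator`
derived from a :class:`numpy.random.SeedSequence` keyed on those labels, so
enlarging a cohort or reordering the computation never perturbs the draws of
existing patients.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Independent generator for a named substream of the master seed."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
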