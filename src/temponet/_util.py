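"""Shared helpers: logging and reproducible seed derivation."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("temponet")


def rng_from(seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent generator from a master seed and integer keys.

    Built on :class:`numpy.random.SeedSequence`, so streams derived with
    different key tuples are statistically independent and reproducible.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *(int(k) for k in keys)]))


def int_seed(seed: int, *keys: int) -> int:
    """A plain 31-bit integer seed derived from (seed, keys), for APIs
    that take an int rather than a numpy Generator."""
    state = np.random.SeedSequence([int(seed), *(int(k) for k in keys)]).generate_state(1)[0]
    return int(state) % (2**31)
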