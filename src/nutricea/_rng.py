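"""Seed-substream management.

A single master seed drives every stochastic stage (covariates, utilities,
dropout, costs, survival, bootstrap, imputation, PSA, permutation). Each
stage derives its own independent Generator from (master_seed, stage label),
so results of one stage do not depend on whether another stage ran first.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for stage `label` derived from `seed`.

    The label is hashed with CRC-32 (stable across platforms and Python
    versions, unlike ``hash``) and mixed into the seed sequence entropy.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng([int(seed), zlib.crc32(label.encode("utf-8"))])
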