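"""Deterministic substream derivation from a single master seed.

Every stochastic step (permutation nulls, noise sampling, fold splits,
synthetic generation) draws from a child generator keyed by the master seed
plus a human-readable label, so whole experiments are bit-reproducible and
individual steps can be re-run in isolation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _label_int(label: str) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def substream_seed(master_seed: int, *labels: object) -> int:
    """A 31-bit seed derived from ``master_seed`` and a label path."""
    key = "/".join(str(x) for x in labels)
    return (int(master_seed) ^ _label_int(key)) % (2**31 - 1)


def substream(master_seed: int, *labels: object) -> np.random.Generator:
    """Independent generator for the step identified by ``labels``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), _label_int("/".join(str(x) for x in labels))])
    )
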