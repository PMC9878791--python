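"""Seed-stream management.

All stochastic stages derive their generator from one master seed through
``substream(master_seed, label)``: the label is hashed with SHA-256 and folded
into the seed via :class:`numpy.random.SeedSequence`.  Two stages with
different labels therefore get independent streams, and a full run is
reproducible end to end from the single master seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _label_entropy(label: str) -> list[int]:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Return a Generator for the named stage, derived from the master seed."""
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *_label_entropy(label)])
    return np.random.default_rng(seq)


def substream_seed(master_seed: int, label: str) -> int:
    """A 32-bit integer seed for libraries that take ints (scikit-learn)."""
    seq = np.random.SeedSequence([int(master_seed) & 0xFFFFFFFF, *_label_entropy(label)])
    return int(seq.generate_state(1)[0])
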