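from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from deepintron.variant_model.core import GenomicVariant, ReferenceContext


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_indel_in_context(rng: np.random.Generator, length: int = 60):
    """A random 1-3 bp indel embedded mid-window in a random context."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    pos = int(rng.integers(20, length - 20))
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # deletion
        ref = seq[pos - 1 : pos + size]
        alt = seq[pos - 1]
    else:  # insertion
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice(list("ACGT"), size=size))
    if ref == alt:
        return random_indel_in_context(rng, length)
    return seq, GenomicVariant("ctg", pos, ref, alt)


@pytest.fixture
def context_factory():
    def make(seq: str, chrom: str = "ctg") -> ReferenceContext:
        return ReferenceContext(chrom, 1, seq)

    return make
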