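"""Shared fixtures: a warm coder instance and random payload helpers."""

from __future__ import annotations

import numpy as np
import pytest

from compdist.compression import BuiltinCoder, NucleotidePayload

ALPHABET = "ACGT"


def random_payload(rng: np.random.Generator, length: int, with_n: bool = False) -> NucleotidePayload:
    letters = ALPHABET + ("N" if with_n else "")
    return NucleotidePayload("".join(rng.choice(list(letters), size=length)))


@pytest.fixture(scope="session")
def coder() -> BuiltinCoder:
    """Default built-in coder; session-scoped so numba compiles once."""
    c = BuiltinCoder()
    # warm the jit kernels on a trivial payload
    c.size_bytes(NucleotidePayload("ACGT"))
    return c


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140529)
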