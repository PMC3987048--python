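import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from coevocontact.msa_io import ALPHABET, Alignment, make_alignment  # noqa: E402

SYMBOLS = ALPHABET + "-"


def random_alignment(rng: np.random.Generator, M: int, L: int, gap_p: float = 0.1) -> Alignment:
    """Random alignment over the full 21-symbol alphabet."""
    codes = rng.integers(0, 20, size=(M, L))
    gaps = rng.random((M, L)) < gap_p
    rows = []
    for m in range(M):
        rows.append("".join("-" if gaps[m, i] else ALPHABET[codes[m, i]] for i in range(L)))
    return make_alignment(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240301)


@pytest.fixture
def aln_factory():
    return random_alignment


def random_spd(rng: np.random.Generator, n: int, cond: float = 10.0) -> np.ndarray:
    """Well-conditioned random symmetric positive definite matrix."""
    A = rng.standard_normal((n, n))
    Qm, _ = np.linalg.qr(A)
    eig = np.linspace(1.0, cond, n)
    return (Qm * eig) @ Qm.T


@pytest.fixture
def spd_factory():
    return random_spd
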