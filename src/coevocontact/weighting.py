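"""Identity-clustering sequence weights and effective alignment weight.

Each sequence receives weight ``1/n`` where ``n`` is the number of
alignment members (itself included) whose percentage identity to it
meets the clustering threshold.  The comparison operator is
configurable: ``"ge"`` groups at identity >= threshold, ``"gt"``
strictly above.

Identity convention (documented loudly because the literature varies):
the denominator is the full alignment length L, gap-vs-gap counts as a
match and gap-vs-residue as a mismatch -- i.e. the gap class is treated
as a 21st symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientWeightError
from .msa_io import Alignment

#: Default minimum effective alignment weight: a single effective
#: sequence carries no covariation signal.
DEFAULT_MIN_MEFF = 1.5

_CHUNK = 128


@dataclass(frozen=True)
class WeightSet:
    """Per-sequence clustering weights.

    Attributes
    ----------
    w : numpy.ndarray
        Length-M vector, ``0 < w_m <= 1``.
    meff : float
        Effective alignment weight, ``sum(w)``.
    """

    w: np.ndarray
    meff: float
    clustpc: float
    comparison: str


def pairwise_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Percentage identity between two encoded rows of equal length."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return 100.0 * int(np.count_nonzero(a == b)) / a.shape[0]


def _cluster_sizes(encoded: np.ndarray, clustpc: float, comparison: str) -> np.ndarray:
    """Vectorized cluster-size counts, processed in row chunks.

    Produces counts identical to the per-pair definition: the identity
    percentage is computed with the same expression ``100*matches/L``
    for every pair, so the fast path is bit-compatible with a
    brute-force loop.
    """
    M, L = encoded.shape
    n = np.empty(M, dtype=np.int64)
    for lo in range(0, M, _CHUNK):
        hi = min(lo + _CHUNK, M)
        matches = (encoded[lo:hi, None, :] == encoded[None, :, :]).sum(axis=2)
        pid = 100.0 * matches / L
        if comparison == "ge":
            n[lo:hi] = (pid >= clustpc).sum(axis=1)
        else:
            # self always counts, even at clustpc == 100 where 100 > 100 fails
            inc = pid > clustpc
            inc[np.arange(hi - lo), np.arange(lo, hi)] = True
            n[lo:hi] = inc.sum(axis=1)
    return n


def compute_weights(aln: Alignment, clustpc: float, comparison: str = "ge") -> WeightSet:
    """Compute clustering weights and Meff for an alignment.

    Parameters
    ----------
    clustpc : float
        Clustering threshold in percent, in [0, 100].
    comparison : {"ge", "gt"}
        Whether a pair joins a cluster at identity >= or > the
        threshold.  The member itself always counts.
    """
    if not 0.0 <= clustpc <= 100.0:
        raise ValueError(f"clustpc must be in [0, 100], got {clustpc}")
    if comparison not in ("ge", "gt"):
        raise ValueError(f"comparison must be 'ge' or 'gt', got {comparison!r}")
    n = _cluster_sizes(aln.encoded, float(clustpc), comparison)
    w = 1.0 / n
    return WeightSet(w=w, meff=float(w.sum()), clustpc=float(clustpc), comparison=comparison)


def check_total_weight(ws: WeightSet, min_meff: float = DEFAULT_MIN_MEFF) -> None:
    """Raise :class:`InsufficientWeightError` when Meff < min_meff."""
    if ws.meff < min_meff:
        raise InsufficientWeightError(ws.meff, min_meff)
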