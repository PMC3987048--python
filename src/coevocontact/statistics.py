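"""Weighted, pseudocounted frequency tables and the site-state covariance matrix.

The pseudocount mass actually added to the tables is

    lambda' = pseudocnt * (pscount_weight * Meff + (1 - pscount_weight))

so ``pscount_weight`` interpolates between a fixed pseudocount mass
(weight 0, classic regularization) and a mass proportional to the
effective sequence count (weight 1, mean-field DCA style).

Single-site:  f1[i,a]   = (lambda'/q   + sum_m w_m [x_mi = a])              / (lambda' + Meff)
Pairwise:     f2[i,j,a,b] = (lambda'/q^2 + sum_m w_m [x_mi = a][x_mj = b])  / (lambda' + Meff)

for i != j; the i == j diagonal is set to ``delta_ab * f1[i,a]``.  Under
this shared-mass scheme the marginalization identity
``sum_b f2[i,j,a,b] = f1[i,a]`` holds exactly.

Gap frequencies for column masking are computed from raw weighted
counts, *without* pseudocount -- otherwise an all-gap column could slip
under thresholds near 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import NoColumnsRemainError
from .msa_io import GAP_CODE, N_STATES, Alignment
from .weighting import WeightSet


@dataclass(frozen=True)
class FrequencyTables:
    f1: np.ndarray          # L x q
    f2: np.ndarray          # L x L x q x q
    gapfreq: np.ndarray     # L, weighted, pseudocount-free
    pseudocnt: float
    pscount_weight: float
    meff: float


@dataclass(frozen=True)
class CovarianceMatrix:
    """Site-state covariance over the kept (unmasked) columns.

    ``C[(i,a),(j,b)] = f2[i,j,a,b] - f1[i,a]*f1[j,b]`` with flat index
    ``block*q + state`` (column-major over columns, state-minor).
    """

    C: np.ndarray
    column_index: np.ndarray   # block index -> original 0-based column
    q_reduced: bool            # True when the gap state was dropped (q=20)

    @property
    def q(self) -> int:
        return 20 if self.q_reduced else N_STATES

    @property
    def n_columns(self) -> int:
        return self.column_index.shape[0]


def _lambda_prime(pseudocnt: float, pscount_weight: float, meff: float) -> float:
    return pseudocnt * (pscount_weight * meff + (1.0 - pscount_weight))


def _weighted_onehot(aln: Alignment, ws: WeightSet) -> np.ndarray:
    """M x (L*q) one-hot matrix scaled by sequence weights."""
    M, L = aln.encoded.shape
    X = np.zeros((M, L * N_STATES))
    flat = np.arange(L) * N_STATES + aln.encoded
    X[np.arange(M)[:, None], flat] = 1.0
    return X


def single_frequencies(
    aln: Alignment, ws: WeightSet, pseudocnt: float, pscount_weight: float
) -> np.ndarray:
    """L x q pseudocounted single-site frequency table; rows sum to 1."""
    if pseudocnt < 0:
        raise ValueError("pseudocnt must be >= 0")
    M, L = aln.encoded.shape
    counts = np.zeros((L, N_STATES))
    for a in range(N_STATES):
        counts[:, a] = ((aln.encoded == a) * ws.w[:, None]).sum(axis=0)
    lamp = _lambda_prime(pseudocnt, pscount_weight, ws.meff)
    return (lamp / N_STATES + counts) / (lamp + ws.meff)


def pair_frequencies(
    aln: Alignment, ws: WeightSet, pseudocnt: float, pscount_weight: float
) -> np.ndarray:
    """L x L x q x q pseudocounted pair frequency table.

    The i == j diagonal holds ``delta_ab * f1[i,a]`` so that every
    block marginalizes exactly to the single-site table.
    """
    if pseudocnt < 0:
        raise ValueError("pseudocnt must be >= 0")
    M, L = aln.encoded.shape
    X = _weighted_onehot(aln, ws)
    counts = (ws.w[:, None] * X).T @ X            # (L*q) x (L*q)
    counts = counts.reshape(L, N_STATES, L, N_STATES).transpose(0, 2, 1, 3)
    lamp = _lambda_prime(pseudocnt, pscount_weight, ws.meff)
    f2 = (lamp / N_STATES**2 + counts) / (lamp + ws.meff)
    f1 = single_frequencies(aln, ws, pseudocnt, pscount_weight)
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return f2


def gap_frequencies(aln: Alignment, ws: WeightSet) -> np.ndarray:
    """Weighted per-column gap frequency, no pseudocount."""
    return ((aln.encoded == GAP_CODE) * ws.w[:, None]).sum(axis=0) / ws.meff


def frequency_tables(
    aln: Alignment, ws: WeightSet, pseudocnt: float, pscount_weight: float
) -> FrequencyTables:
    f2 = pair_frequencies(aln, ws, pseudocnt, pscount_weight)
    f1 = single_frequencies(aln, ws, pseudocnt, pscount_weight)
    return FrequencyTables(
        f1=f1,
        f2=f2,
        gapfreq=gap_frequencies(aln, ws),
        pseudocnt=pseudocnt,
        pscount_weight=pscount_weight,
        meff=ws.meff,
    )


def gap_mask(gapfreq: np.ndarray, gapth: float, apply: bool) -> np.ndarray:
    """Boolean exclusion mask: True marks a column to drop.

    A column is dropped when its weighted gap frequency is strictly
    greater than ``gapth``; with ``apply=False`` nothing is dropped.
    """
    if not 0.0 < gapth <= 1.0:
        raise ValueError(f"gapth must be in (0, 1], got {gapth}")
    if not apply:
        return np.zeros(gapfreq.shape[0], dtype=bool)
    mask = gapfreq > gapth
    if mask.all():
        raise NoColumnsRemainError(
            f"no columns remain: all {gapfreq.shape[0]} columns exceed gap threshold {gapth}"
        )
    return mask


def build_covariance(
    f1: np.ndarray,
    f2: np.ndarray,
    mask: Optional[np.ndarray] = None,
    cov20: bool = False,
) -> CovarianceMatrix:
    """Assemble the site-state covariance matrix over kept columns.

    With ``cov20=True`` the gap state (code 20) is dropped from every
    block so the matrix is not overdetermined (q = 20); otherwise all
    21 states are kept.  The result is symmetrized as (C + C.T)/2.
    """
    L = f1.shape[0]
    if mask is None:
        mask = np.zeros(L, dtype=bool)
    kept = np.where(~mask)[0]
    q = 20 if cov20 else N_STATES
    f1k = f1[kept][:, :q]                                  # Lk x q
    f2k = f2[np.ix_(kept, kept)][:, :, :q, :q]             # Lk x Lk x q x q
    n = kept.shape[0] * q
    C = f2k.transpose(0, 2, 1, 3).reshape(n, n) - np.outer(f1k.ravel(), f1k.ravel())
    C = 0.5 * (C + C.T)
    return CovarianceMatrix(C=C, column_index=kept, q_reduced=cov20)
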