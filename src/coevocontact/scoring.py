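"""Contact scoring: block norms, average product correction, ranking.

The coupling matrix is cut into per-column-pair blocks; each block is
collapsed to a single raw score by a norm (Frobenius for the mean-field
DCA route, L1 for the sparse-inverse route), the raw score matrix is
average-product corrected, and surviving pairs are ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional

import numpy as np


class Contact(NamedTuple):
    i: int          # 1-based target column, i < j
    j: int
    raw: float
    corrected: float


@dataclass(frozen=True)
class ContactList:
    entries: List[Contact]
    mincontsep: int
    norm_mode: str
    target_residues: Optional[str] = field(default=None)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def block_norms(
    Gamma: np.ndarray,
    q: int,
    norm_mode: str = "frobenius",
    include_gap_state: bool = False,
) -> np.ndarray:
    """Collapse a (Lk*q) x (Lk*q) coupling matrix to an Lk x Lk score matrix.

    ``norm_mode="frobenius"``: sqrt of the sum of squared block entries;
    ``"l1"``: sum of absolute block entries.  With
    ``include_gap_state=False`` and q == 21, the gap row and column of
    every block are excluded (a no-op when q == 20).  The diagonal is
    zeroed.
    """
    Gamma = np.asarray(Gamma)
    n = Gamma.shape[0]
    if n % q != 0:
        raise ValueError(f"matrix side {n} not divisible by q={q}")
    Lk = n // q
    blocks = Gamma.reshape(Lk, q, Lk, q)
    if not include_gap_state and q == 21:
        blocks = blocks[:, :20, :, :20]
    if norm_mode == "frobenius":
        S = np.sqrt((blocks**2).sum(axis=(1, 3)))
    elif norm_mode == "l1":
        S = np.abs(blocks).sum(axis=(1, 3))
    else:
        raise ValueError(f"unknown norm mode: {norm_mode!r}")
    np.fill_diagonal(S, 0.0)
    return 0.5 * (S + S.T)


def apc(S: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric zero-diagonal score matrix.

    corrected[i,j] = S[i,j] - mean_i * mean_j / grand_mean, where the
    row means and the grand mean exclude the diagonal.  A zero grand
    mean returns an all-zero matrix (degenerate guard).
    """
    S = np.asarray(S, dtype=float)
    L = S.shape[0]
    if L < 2:
        return np.zeros_like(S)
    row_mean = S.sum(axis=1) / (L - 1)           # diagonal is zero
    grand_mean = S.sum() / (L * (L - 1))
    if grand_mean == 0.0:
        return np.zeros_like(S)
    corrected = S - np.outer(row_mean, row_mean) / grand_mean
    np.fill_diagonal(corrected, 0.0)
    return corrected


def rank_contacts(
    corrected: np.ndarray,
    raw: np.ndarray,
    mincontsep: int,
    mask: Optional[np.ndarray] = None,
    target_residues: Optional[str] = None,
    norm_mode: str = "frobenius",
) -> ContactList:
    """Rank all admissible pairs by corrected score.

    ``corrected`` and ``raw`` are over the *kept* columns; ``mask`` is
    the exclusion mask over the original L columns used to map kept
    indices back to 1-based target positions.  A pair is admissible
    when j - i >= mincontsep in original numbering.  Sorted by
    descending corrected score, ties broken by (i, j) ascending.
    """
    if mincontsep < 1:
        raise ValueError("mincontsep must be >= 1")
    Lk = corrected.shape[0]
    if mask is None:
        orig = np.arange(Lk)
    else:
        orig = np.where(~np.asarray(mask, dtype=bool))[0]
        if orig.shape[0] != Lk:
            raise ValueError("mask kept-column count does not match score matrix side")
    entries = []
    for p in range(Lk):
        for r in range(p + 1, Lk):
            i = int(orig[p]) + 1
            j = int(orig[r]) + 1
            if j - i >= mincontsep:
                entries.append(Contact(i, j, float(raw[p, r]), float(corrected[p, r])))
    entries.sort(key=lambda e: (-e.corrected, e.i, e.j))
    return ContactList(
        entries=entries,
        mincontsep=mincontsep,
        norm_mode=norm_mode,
        target_residues=target_residues,
    )
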