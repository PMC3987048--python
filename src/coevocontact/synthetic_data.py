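"""Synthetic alignments with planted pairwise couplings and redundancy.

Sequences are drawn from a Potts-like pairwise model

    p(x) propto exp( sum_i h_i(x_i) + sum_{(i,j) planted} beta_ij * [x_i == x_j] )

by single-site Gibbs sampling on one chain (sequential site order,
burn-in then thinning), so every downstream stage -- weighting,
frequencies, inference, scoring -- has a known ground truth.  The
coupling is an Ising-like same-state bonus rather than a full q x q
table: two parameters per pair are enough to create detectable
covariation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import gibbs_sample
from .msa_io import N_STATES, Alignment, decode_row, make_alignment

#: Sampler defaults: small models mix fast; both are tunable.
DEFAULT_BURN_IN_PER_SITE = 100
DEFAULT_THIN = 10


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth generative model for a synthetic alignment.

    ``coupled_pairs`` holds (i, j, beta) with 0-based columns i < j and
    coupling strength beta > 0 rewarding x_i == x_j.  ``fields`` is an
    optional L x q bias table (defaults to zero = uniform background).
    """

    L: int
    M: int
    seed: int
    q: int = N_STATES
    coupled_pairs: Tuple[Tuple[int, int, float], ...] = ()
    fields: Optional[np.ndarray] = None
    burn_in: Optional[int] = None       # sweeps; default 100 * L
    thin: int = DEFAULT_THIN

    def __post_init__(self):
        for i, j, beta in self.coupled_pairs:
            if not 0 <= i < j < self.L:
                raise ValueError(f"coupled pair ({i},{j}) must satisfy 0 <= i < j < L")
            if not np.isfinite(beta):
                raise ValueError("coupling strength must be finite")
        if self.fields is not None and not np.all(np.isfinite(self.fields)):
            raise ValueError("field biases must be finite")


def sample_alignment(model: PlantedModel) -> Alignment:
    """Draw M sequences from the planted model; deterministic given seed."""
    h = (
        np.zeros((model.L, model.q))
        if model.fields is None
        else np.asarray(model.fields, dtype=float)
    )
    if h.shape != (model.L, model.q):
        raise ValueError(f"fields must have shape ({model.L}, {model.q})")
    pairs = model.coupled_pairs
    pair_i = np.array([p[0] for p in pairs], dtype=np.int64)
    pair_j = np.array([p[1] for p in pairs], dtype=np.int64)
    beta = np.array([p[2] for p in pairs], dtype=float)
    burn = model.burn_in if model.burn_in is not None else DEFAULT_BURN_IN_PER_SITE * model.L
    codes = gibbs_sample(
        model.L, model.q, h, pair_i, pair_j, beta,
        model.M, burn, model.thin, model.seed,
    )
    return make_alignment([decode_row(row) for row in codes])


def add_redundancy(
    aln: Alignment,
    copies: Sequence[Tuple[int, int]],
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """Append near-duplicate rows to exercise sequence weighting.

    ``copies`` lists (row_index, k): append k near-copies of that row,
    each position independently resampled (uniformly over the 21
    states) with probability ``mutation_rate``.  Rate 0 gives exact
    duplicates; rate 1 gives rows uncorrelated with the parent beyond
    chance.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows: List[str] = list(aln.rows)
    for row_idx, k in copies:
        parent = aln.encoded[row_idx].copy()
        for _ in range(k):
            dup = parent.copy()
            if mutation_rate > 0.0:
                hit = rng.random(aln.L) < mutation_rate
                dup[hit] = rng.integers(0, N_STATES, int(hit.sum()))
            rows.append(decode_row(dup))
    return make_alignment(rows)
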