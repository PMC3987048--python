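"""Numba-compiled inner loops: graphical-lasso sweeps and Gibbs sampling.

These are single-threaded by design so that results do not depend on
thread count.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def glasso_sweep(C, W, B, rho, inner_max, inner_tol):
    """One full block coordinate-descent sweep of the graphical lasso.

    For each column j, solves the lasso subproblem

        min_b  0.5 * b' W11 b - s12' b + rho * |b|_1

    by coordinate descent (W11 = W without row/col j, s12 = C[!j, j]),
    then writes w12 = W11 b back into W.  B caches the lasso
    coefficients for warm starts and for recovering the precision
    matrix.  Returns the maximum absolute change of any W entry.
    """
    n = C.shape[0]
    max_dw = 0.0
    r = np.empty(n)
    for j in range(n):
        b = B[:, j]
        # r[k] = (W11 b)[k] for k != j; b[j] == 0 always
        for k in range(n):
            s = 0.0
            for l in range(n):
                s += W[k, l] * b[l]
            r[k] = s
        for _ in range(inner_max):
            max_db = 0.0
            for k in range(n):
                if k == j:
                    continue
                wkk = W[k, k]
                old = b[k]
                u = C[k, j] - (r[k] - wkk * old)
                if u > rho:
                    new = (u - rho) / wkk
                elif u < -rho:
                    new = (u + rho) / wkk
                else:
                    new = 0.0
                d = new - old
                if d != 0.0:
                    b[k] = new
                    for l in range(n):
                        r[l] += W[l, k] * d
                    ad = abs(d)
                    if ad > max_db:
                        max_db = ad
            if max_db < inner_tol:
                break
        for k in range(n):
            if k == j:
                continue
            dw = abs(W[k, j] - r[k])
            if dw > max_dw:
                max_dw = dw
            W[k, j] = r[k]
            W[j, k] = r[k]
    return max_dw


@njit(cache=True)
def glasso_recover_precision(W, B):
    """Recover the precision matrix from the converged (W, B) pair.

    Gamma[j,j] = 1 / (W[j,j] - w12' b);  Gamma[!j, j] = -b * Gamma[j,j].
    Exact zeros in B stay exact zeros in Gamma.
    """
    n = W.shape[0]
    G = np.zeros((n, n))
    for j in range(n):
        s = 0.0
        for k in range(n):
            if k != j:
                s += W[k, j] * B[k, j]
        gjj = 1.0 / (W[j, j] - s)
        G[j, j] = gjj
        for k in range(n):
            if k != j and B[k, j] != 0.0:
                G[k, j] = -B[k, j] * gjj
    return G


@njit(cache=True)
def gibbs_sample(L, q, h, pair_i, pair_j, beta, M, burn_sweeps, thin, seed):
    """Single-chain Gibbs sampler for a Potts-like pairwise model.

    p(x) propto exp( sum_i h[i, x_i] + sum_{(i,j) coupled} beta_ij * [x_i == x_j] )

    Sites are updated in fixed sequential order; after ``burn_sweeps``
    full sweeps one row is recorded every ``thin`` sweeps, M rows total.
    Deterministic for a given seed.
    """
    np.random.seed(seed)
    npairs = pair_i.shape[0]
    x = np.empty(L, dtype=np.int8)
    for i in range(L):
        x[i] = np.random.randint(0, q)
    out = np.empty((M, L), dtype=np.int8)
    logits = np.empty(q)
    probs = np.empty(q)
    total_sweeps = burn_sweeps + M * thin
    taken = 0
    for sweep in range(total_sweeps):
        for i in range(L):
            for a in range(q):
                logits[a] = h[i, a]
            for p in range(npairs):
                if pair_i[p] == i:
                    logits[x[pair_j[p]]] += beta[p]
                elif pair_j[p] == i:
                    logits[x[pair_i[p]]] += beta[p]
            mx = logits[0]
            for a in range(1, q):
                if logits[a] > mx:
                    mx = logits[a]
            z = 0.0
            for a in range(q):
                probs[a] = np.exp(logits[a] - mx)
                z += probs[a]
            u = np.random.random() * z
            acc = 0.0
            pick = q - 1
            for a in range(q):
                acc += probs[a]
                if u < acc:
                    pick = a
                    break
            x[i] = pick
        if sweep >= burn_sweeps and (sweep - burn_sweeps + 1) % thin == 0:
            if taken < M:
                out[taken] = x
                taken += 1
    return out
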