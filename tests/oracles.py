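"""Independent brute-force oracles used to cross-check the fast paths.

Everything here is written as literal loops over the defining formulas,
deliberately sharing no code with the package internals.
"""

import math

import numpy as np

Q = 21
GAP = 20


def identity_percent(a, b):
    assert len(a) == len(b)
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * matches / len(a)


def cluster_weights(encoded, clustpc, comparison="ge"):
    """Per-pair loop cluster counting; returns (w, meff)."""
    M = len(encoded)
    w = []
    for m in range(M):
        n = 0
        for m2 in range(M):
            if m2 == m:
                n += 1
                continue
            pid = identity_percent(encoded[m], encoded[m2])
            if (pid >= clustpc) if comparison == "ge" else (pid > clustpc):
                n += 1
        w.append(1.0 / n)
    # cluster counts are the bit-identity contract; the sum uses numpy's
    # reduction to match summation order
    return np.array(w), float(np.sum(w))


def lambda_prime(pseudocnt, pscount_weight, meff):
    return pseudocnt * (pscount_weight * meff + (1 - pscount_weight))


def single_freq(encoded, w, pseudocnt, pscount_weight):
    M, L = np.asarray(encoded).shape
    meff = float(np.sum(w))
    lamp = lambda_prime(pseudocnt, pscount_weight, meff)
    f1 = np.zeros((L, Q))
    for i in range(L):
        for a in range(Q):
            c = 0.0
            for m in range(M):
                if encoded[m][i] == a:
                    c += w[m]
            f1[i, a] = (lamp / Q + c) / (lamp + meff)
    return f1


def pair_freq(encoded, w, pseudocnt, pscount_weight):
    enc = np.asarray(encoded)
    M, L = enc.shape
    meff = float(np.sum(w))
    lamp = lambda_prime(pseudocnt, pscount_weight, meff)
    f1 = single_freq(encoded, w, pseudocnt, pscount_weight)
    f2 = np.zeros((L, L, Q, Q))
    for i in range(L):
        for j in range(L):
            if i == j:
                for a in range(Q):
                    f2[i, i, a, a] = f1[i, a]
                continue
            counts = np.zeros((Q, Q))
            for m in range(M):
                counts[enc[m, i], enc[m, j]] += w[m]
            f2[i, j] = (lamp / Q**2 + counts) / (lamp + meff)
    return f2


def covariance(f1, f2, kept, q):
    """C[(i,a),(j,b)] = f2 - f1*f1 by literal loops over kept columns."""
    Lk = len(kept)
    C = np.zeros((Lk * q, Lk * q))
    for p, i in enumerate(kept):
        for r, j in enumerate(kept):
            for a in range(q):
                for b in range(q):
                    C[p * q + a, r * q + b] = f2[i, j, a, b] - f1[i, a] * f1[j, b]
    return 0.5 * (C + C.T)


def block_norms(Gamma, q, mode="frobenius", include_gap=False):
    n = Gamma.shape[0]
    Lk = n // q
    qq = q if (include_gap or q != 21) else 20
    S = np.zeros((Lk, Lk))
    for i in range(Lk):
        for j in range(Lk):
            if i == j:
                continue
            acc = 0.0
            for a in range(qq):
                for b in range(qq):
                    v = Gamma[i * q + a, j * q + b]
                    acc += v * v if mode == "frobenius" else abs(v)
            S[i, j] = math.sqrt(acc) if mode == "frobenius" else acc
    return 0.5 * (S + S.T)


def apc(S):
    L = S.shape[0]
    out = np.zeros_like(S)
    grand = sum(S[i, j] for i in range(L) for j in range(L) if i != j) / (L * (L - 1))
    if grand == 0:
        return out
    row = [sum(S[i, j] for j in range(L) if j != i) / (L - 1) for i in range(L)]
    for i in range(L):
        for j in range(L):
            if i != j:
                out[i, j] = S[i, j] - row[i] * row[j] / grand
    return out


def precision_cells(entries, truth_pairs, L, fractions=(1, 2, 5, 10), seps=(4, 8, 11, 23)):
    """entries: ranked list of (i, j) 1-based tuples."""
    values = {}
    for sep in seps:
        for n in fractions:
            take = L // n
            chosen = []
            for (i, j) in entries:
                if len(chosen) == take:
                    break
                if j - i > sep:
                    chosen.append((i, j))
            if not chosen:
                values[(n, sep)] = None
                continue
            tp = sum(1 for p in chosen if p in truth_pairs)
            values[(n, sep)] = 100.0 * tp / len(chosen)
    return values
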