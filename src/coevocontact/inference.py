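"""Coupling estimation: dense inversion or sparse inverse covariance.

Two routes from the covariance matrix to a coupling (precision) matrix:

* ``invert_covariance`` -- direct symmetric inversion (mean-field DCA
  route), after an optional shrinkage step that blends the matrix
  toward a scaled identity until it is positive definite.
* ``glasso_estimate`` / ``glasso_with_density_target`` -- L1-penalized
  sparse precision estimation by block coordinate descent (graphical
  lasso), optionally adjusting the regularization strength until the
  off-diagonal density hits a target, under a cooperative time limit
  checked between coordinate-descent sweeps.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from ._kernels import glasso_recover_precision, glasso_sweep
from .errors import DegenerateInputError, IcmeTimeoutError, SingularMatrixError
from .statistics import CovarianceMatrix

#: Default shrinkage increment toward mean-diagonal * identity.
SHRINK_STEP = 0.05


@dataclass
class PrecisionResult:
    """A coupling matrix with provenance of how it was obtained."""

    Gamma: np.ndarray
    method: str                       # "inversion" | "glasso"
    iterations: int = 0
    elapsed: float = 0.0
    converged: bool = True
    rho_final: Optional[float] = None
    density: Optional[float] = None
    residual: Optional[float] = None  # max |C*Gamma - I| (inversion only)
    objective_history: Optional[list] = None
    # internal warm-start state for density targeting
    _W: Optional[np.ndarray] = None
    _B: Optional[np.ndarray] = None


def _as_array(C) -> np.ndarray:
    return C.C if isinstance(C, CovarianceMatrix) else np.asarray(C, dtype=float)


def _is_posdef(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return True
    except np.linalg.LinAlgError:
        return False


def shrink_to_positive_definite(C, step: float = SHRINK_STEP):
    """Blend C toward (mean diagonal)*I until a Cholesky factorization succeeds.

    Tries C' = (1-alpha)*C + alpha*mu*I for alpha in {0, step, 2*step,
    ..., 1} with mu = mean diagonal of C, and returns the first
    positive-definite C' together with the alpha used.

    Returns
    -------
    (C', alpha) : same type as the input C, and the blend weight.
    """
    if not 0.0 < step < 1.0:
        raise ValueError("step must be in (0, 1)")
    A = _as_array(C)
    mu = float(np.mean(np.diag(A)))
    if mu <= 0.0:
        raise DegenerateInputError(f"mean diagonal of covariance is {mu:g} <= 0")
    target = mu * np.eye(A.shape[0])
    alpha = 0.0
    while alpha < 1.0 + 1e-12:
        alpha = min(alpha, 1.0)
        Ap = (1.0 - alpha) * A + alpha * target
        if _is_posdef(Ap):
            break
        alpha += step
    if isinstance(C, CovarianceMatrix):
        return dataclasses.replace(C, C=Ap), alpha
    return Ap, alpha


def invert_covariance(C) -> PrecisionResult:
    """Dense inverse of a positive-definite covariance matrix.

    Uses a Cholesky factorization; the returned result carries the
    max-norm residual ``|C*Gamma - I|_max``.
    """
    t0 = time.perf_counter()
    A = _as_array(C)
    try:
        cho = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            "covariance factorization failed; apply shrinkage or increase pseudocounts"
        ) from exc
    G = scipy.linalg.cho_solve(cho, np.eye(A.shape[0]), check_finite=False)
    G = 0.5 * (G + G.T)
    residual = float(np.max(np.abs(A @ G - np.eye(A.shape[0]))))
    return PrecisionResult(
        Gamma=G,
        method="inversion",
        iterations=1,
        elapsed=time.perf_counter() - t0,
        residual=residual,
    )


def _offdiag_density(G: np.ndarray) -> float:
    n = G.shape[0]
    if n < 2:
        return 0.0
    nz = int(np.count_nonzero(G)) - int(np.count_nonzero(np.diag(G)))
    return nz / (n * (n - 1))


def penalized_likelihood(C, G: np.ndarray, rho: float) -> float:
    """Primal graphical-lasso objective: log det G - tr(CG) - rho*|G|_1(off)."""
    A = _as_array(C)
    sign, logdet = np.linalg.slogdet(G)
    if sign <= 0:
        return -np.inf
    l1_off = np.abs(G).sum() - np.abs(np.diag(G)).sum()
    return float(logdet - np.tensordot(A, G) - rho * l1_off)


def glasso_estimate(
    C,
    rho: float,
    max_iter: int = 100,
    tol: float = 1e-4,
    deadline: Optional[float] = None,
    warm: Optional[PrecisionResult] = None,
    record_objective: bool = False,
) -> PrecisionResult:
    """Graphical lasso: maximize  log det G - tr(C G) - rho*|G|_1(offdiag).

    Block coordinate descent in the style of the classic GLASSO
    algorithm.  Convergence is declared when the maximum entry change
    of the working covariance between successive sweeps drops below
    ``tol`` (scaled by the mean absolute off-diagonal of C).  A
    ``deadline`` (``time.perf_counter()`` value) is checked between
    sweeps; exceeding it raises :class:`IcmeTimeoutError`.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    t0 = time.perf_counter()
    A = _as_array(C)
    n = A.shape[0]
    if warm is not None and warm._W is not None:
        W = warm._W.copy()
        B = warm._B.copy()
        np.fill_diagonal(W, np.diag(A) + rho)
    else:
        W = A.copy()
        np.fill_diagonal(W, np.diag(A) + rho)
        B = np.zeros((n, n))
    off = np.abs(A).sum() - np.abs(np.diag(A)).sum()
    scale = off / (n * (n - 1)) if n > 1 else 1.0
    thresh = tol * max(scale, 1e-30)
    history = [] if record_objective else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        max_dw = glasso_sweep(A, W, B, float(rho), 200, 0.1 * thresh)
        if deadline is not None and time.perf_counter() > deadline:
            raise IcmeTimeoutError(
                f"inverse covariance estimation timed out after {it} sweeps"
            )
        if record_objective:
            # the block-coordinate sweeps ascend the dual objective
            # log det W (subject to |W - C|_inf <= rho); record that --
            # the primal value of the *recovered* precision iterate is
            # not exactly monotone before convergence
            history.append(float(np.linalg.slogdet(W)[1]))
        if max_dw < thresh:
            converged = True
            break
    G = glasso_recover_precision(W, B)
    G = 0.5 * (G + G.T)
    return PrecisionResult(
        Gamma=G,
        method="glasso",
        iterations=it,
        elapsed=time.perf_counter() - t0,
        converged=converged,
        rho_final=float(rho),
        density=_offdiag_density(G),
        objective_history=history,
        _W=W,
        _B=B,
    )


def glasso_with_density_target(
    C,
    rho0: float,
    target_density: float,
    timeout_s: float,
    max_rounds: int = 12,
    rel_tol: float = 0.2,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> PrecisionResult:
    """Adjust rho until the precision-matrix density approaches a target.

    Starts from ``rho0``, brackets geometrically (factor 2: density is
    non-increasing in rho, so too-dense means raise rho, too-sparse
    means lower it), then bisects geometrically, for at most
    ``max_rounds`` adjustment rounds or until the achieved density is
    within ``rel_tol`` relative of the target.  Returns the closest
    result seen.  Raises :class:`IcmeTimeoutError` when the total time
    exceeds ``timeout_s``.
    """
    if rho0 <= 0:
        raise ValueError("rho0 must be > 0")
    if not 0.0 < target_density <= 1.0:
        raise ValueError("target_density must be in (0, 1]")
    if timeout_s <= 0:
        raise ValueError("timeout_s must be > 0")
    deadline = time.perf_counter() + timeout_s

    def fit(rho, warm):
        return glasso_estimate(C, rho, max_iter=max_iter, tol=tol,
                               deadline=deadline, warm=warm)

    rho = float(rho0)
    res = fit(rho, None)
    best = res
    best_err = abs(res.density - target_density)
    lo = hi = None  # lo: rho known too small (too dense); hi: too large (too sparse)
    for _ in range(max_rounds):
        if abs(res.density - target_density) <= rel_tol * target_density:
            return res
        if res.density > target_density:
            lo = rho
            rho = rho * 2.0 if hi is None else float(np.sqrt(lo * hi))
        else:
            hi = rho
            rho = rho / 2.0 if lo is None else float(np.sqrt(lo * hi))
        if deadline is not None and time.perf_counter() > deadline:
            raise IcmeTimeoutError("density targeting timed out")
        res = fit(rho, res)
        err = abs(res.density - target_density)
        if err < best_err:
            best, best_err = res, err
    if abs(res.density - target_density) <= rel_tol * target_density:
        return res
    return best
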