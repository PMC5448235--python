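"""Conditional maximum likelihood estimation of the Rasch model and LLTM.

Both models are dichotomous Rasch-type models with item response function

    P(X_vi = 1 | theta_v, beta_i) = exp(theta_v - beta_i) / (1 + exp(theta_v - beta_i))

The Rasch model (RM) estimates one difficulty ``beta_i`` per item; the linear
logistic test model (LLTM) restricts the difficulties to a weighted sum of
``p`` basic parameters, ``beta_i = sum_j q_ij eta_j + c``, where the weights
``q_ij`` come from the Q-matrix and ``c`` is a normalization constant.

Estimation conditions on the raw scores, which removes the person parameters
and reduces the data to two sufficient statistics: the per-item totals and
the raw-score counts among persons with non-extreme scores.  The conditional
log-likelihood is strictly concave on the identified parameter space, so a
quasi-Newton ascent with the analytic gradient (from the elementary symmetric
function derivatives) converges quickly; a damped Newton polish with a
finite-difference Hessian of the analytic gradient is applied if the
quasi-Newton step stalls before the gradient tolerance.

Normalization: reported difficulties are sum-zero over items (the conditional
likelihood is invariant under adding a constant to all ``beta_i``), which
makes RM estimates and LLTM-reconstructed difficulties directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .data import ResponseMatrix, WeightMatrix
from .esf import _cond_tables
from .exceptions import EstimationError, IdentifiabilityError, ValidationError

__all__ = ["RaschFit", "LLTMFit", "fit_rasch", "fit_lltm", "reconstruct_item_parameters"]

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


@dataclass(frozen=True)
class _CmlStats:
    """Sufficient statistics of a response matrix for CML estimation."""

    k: int
    n_persons: int
    n_effective: int
    score_counts: np.ndarray  # (k + 1,) counts of raw scores, extremes included
    item_sums: np.ndarray  # (k,) item totals over non-extreme persons
    checksum: str
    item_ids: tuple[str, ...]

    @classmethod
    def from_responses(cls, responses: ResponseMatrix) -> "_CmlStats":
        if not isinstance(responses, ResponseMatrix):
            responses = ResponseMatrix(data=np.asarray(responses))
        X = responses.data.astype(np.int64)
        n, k = X.shape
        scores = X.sum(axis=1)
        interior = (scores > 0) & (scores < k)
        item_sums = X[interior].sum(axis=0).astype(float)
        # extreme scores stay in score_counts for bookkeeping; they carry no
        # conditional information and never enter the likelihood
        score_counts = np.bincount(scores, minlength=k + 1).astype(float)
        return cls(
            k=k,
            n_persons=n,
            n_effective=int(interior.sum()),
            score_counts=score_counts,
            item_sums=item_sums,
            checksum=responses.checksum,
            item_ids=tuple(responses.item_ids),
        )


def _neg_loglik_grad(beta: np.ndarray, stats: _CmlStats) -> tuple[float, np.ndarray]:
    """Negative conditional log-likelihood and its gradient in ``beta``."""
    loggamma, pi = _cond_tables(beta)
    k = stats.k
    nr = stats.score_counts[1:k]
    ll = -(stats.item_sums @ beta) - nr @ loggamma[1:k]
    expected = pi[:, 1:k] @ nr  # expected conditional item margins
    grad = -stats.item_sums + expected
    return -ll, -grad


def _fd_hessian(fun_grad, x: np.ndarray, g0: np.ndarray) -> np.ndarray:
    """Forward-difference Hessian from an analytic gradient."""
    n = x.size
    H = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * (1.0 + abs(x[j]))
        xj = x.copy()
        xj[j] += h
        _, gj = fun_grad(xj)
        H[:, j] = (gj - g0) / h
    return 0.5 * (H + H.T)


def _newton_polish(fun_grad, x: np.ndarray, tol: float, budget: int) -> tuple[np.ndarray, int]:
    """Damped Newton steps until the gradient max-norm drops below ``tol``."""
    used = 0
    f, g = fun_grad(x)
    while used < budget and np.max(np.abs(g)) >= tol:
        H = _fd_hessian(fun_grad, x, g)
        step = None
        ridge = 0.0
        eye = np.eye(x.size)
        for _ in range(8):
            try:
                cand = np.linalg.solve(H + ridge * eye, -g)
            except np.linalg.LinAlgError:
                cand = None
            if cand is not None and cand @ g < 0:
                step = cand
                break
            ridge = 1e-8 if ridge == 0.0 else ridge * 100.0
        if step is None:
            step = -g
        t = 1.0
        accepted = False
        # near the optimum the predicted decrease sinks below rounding noise
        # in f, so accept on sufficient decrease OR on gradient-norm progress
        noise = 16.0 * np.finfo(float).eps * (1.0 + abs(f))
        gnorm = np.max(np.abs(g))
        for _ in range(30):
            f_new, g_new = fun_grad(x + t * step)
            if (f_new <= f + 1e-4 * t * (g @ step) + noise) or (
                np.max(np.abs(g_new)) < 0.5 * gnorm
            ):
                x = x + t * step
                f, g = f_new, g_new
                accepted = True
                break
            t *= 0.5
        used += 1
        if not accepted:
            break
    return x, used


def _maximize(fun_grad, x0: np.ndarray, tol: float, max_iter: int) -> tuple[np.ndarray, int, bool]:
    """Minimize the negative conditional log-likelihood.

    Quasi-Newton (BFGS) with the analytic gradient, followed by a Newton
    polish if the gradient tolerance was not reached.  Returns the solution,
    iteration count and a convergence flag (never raises on non-convergence).
    """
    res = minimize(
        fun_grad,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": tol, "maxiter": max_iter},
    )
    x, iters = res.x, int(res.nit)
    _, g = fun_grad(x)
    if np.max(np.abs(g)) >= tol and iters < max_iter:
        x, extra = _newton_polish(fun_grad, x, tol, max_iter - iters)
        iters += extra
        _, g = fun_grad(x)
    converged = bool(np.max(np.abs(g)) < tol)
    return x, iters, converged


@dataclass
class RaschFit:
    """CML fit of the dichotomous Rasch model.

    ``beta`` is sum-zero normalized; the person parameters are integrated out
    by conditioning and are deliberately not estimated.
    """

    beta: np.ndarray
    loglik: float
    n_params: int
    n_effective: int
    n_persons: int
    converged: bool
    iterations: int
    data_checksum: str
    item_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def k(self) -> int:
        return self.beta.size


@dataclass
class LLTMFit:
    """CML fit of the linear logistic test model.

    ``beta_reconstructed = Q eta + c`` with ``c = -mean(Q eta)`` so that the
    reconstructed difficulties are sum-zero like the Rasch estimates.
    ``eta_se`` are observed-information standard errors (inverse Hessian
    diagonal of the conditional log-likelihood at the optimum).
    """

    eta: np.ndarray
    c: float
    beta_reconstructed: np.ndarray
    loglik: float
    n_params: int
    n_effective: int
    n_persons: int
    converged: bool
    iterations: int
    data_checksum: str
    eta_se: np.ndarray = field(default_factory=lambda: np.array([]))
    operation_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def k(self) -> int:
        return self.beta_reconstructed.size


def _check_estimable(stats: _CmlStats) -> None:
    if stats.n_effective == 0:
        raise EstimationError(
            "no conditional information: every person has an extreme raw score"
        )
    bad = np.flatnonzero(
        (stats.item_sums <= 0) | (stats.item_sums >= stats.n_effective)
    )
    if bad.size:
        names = ", ".join(stats.item_ids[i] for i in bad)
        raise EstimationError(
            f"extreme item margin: item(s) {names} answered all-0 or all-1 "
            "by persons with non-extreme scores"
        )


def _start_beta(stats: _CmlStats) -> np.ndarray:
    """Centred logit of item failure rates among non-extreme persons."""
    prop = (stats.item_sums + 0.5) / (stats.n_effective + 1.0)
    b = np.log((1.0 - prop) / prop)
    return b - b.mean()


def fit_rasch(
    responses: ResponseMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RaschFit:
    """Fit the Rasch model by conditional maximum likelihood.

    Parameters
    ----------
    responses : ResponseMatrix (or 0/1 array)
    tol : gradient max-norm convergence tolerance.
    max_iter : iteration budget; on exhaustion the fit is returned with
        ``converged=False`` rather than raising.

    Raises
    ------
    EstimationError
        If an item is answered all-0 or all-1 by the persons contributing to
        the conditional likelihood, or if every person has an extreme score.
    ValidationError
        For non-binary data.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(data=np.asarray(responses))
    stats = _CmlStats.from_responses(responses)
    _check_estimable(stats)
    k = stats.k

    def fg(x: np.ndarray) -> tuple[float, np.ndarray]:
        beta = np.append(x, 0.0)
        f, g = _neg_loglik_grad(beta, stats)
        return f, g[:-1]

    b0 = _start_beta(stats)
    x0 = b0[:-1] - b0[-1]
    x, iters, converged = _maximize(fg, x0, tol, max_iter)
    beta = np.append(x, 0.0)
    beta -= beta.mean()
    loglik = -_neg_loglik_grad(beta, stats)[0]
    if not converged:
        logger.warning("Rasch CML fit did not converge in %d iterations", max_iter)
    return RaschFit(
        beta=beta,
        loglik=float(loglik),
        n_params=k - 1,
        n_effective=stats.n_effective,
        n_persons=stats.n_persons,
        converged=converged,
        iterations=iters,
        data_checksum=stats.checksum,
        item_ids=stats.item_ids,
    )


def reconstruct_item_parameters(eta, Q: WeightMatrix) -> np.ndarray:
    """Item difficulties implied by basic parameters: ``Q eta + c``.

    The normalization constant ``c = -mean(Q eta)`` makes the result sum to
    zero, matching the Rasch-fit normalization.

    Raises
    ------
    ValidationError
        If ``eta`` length does not match the number of operations.
    """
    W = Q.weights if isinstance(Q, WeightMatrix) else np.asarray(Q)
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (W.shape[1],):
        raise ValidationError(
            f"eta has length {eta.size} but the weight matrix has {W.shape[1]} operations"
        )
    qe = W.astype(float) @ eta
    return qe - qe.mean()


def fit_lltm(
    responses: ResponseMatrix,
    Q: WeightMatrix,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LLTMFit:
    """Fit the LLTM by conditional maximum likelihood.

    The difficulties are constrained to ``beta = Q eta`` during optimization
    (the intercept is not identified under conditioning and is restored
    afterwards as ``c = -mean(Q eta)``).

    Raises
    ------
    IdentifiabilityError
        If ``[Q | 1]`` is rank deficient (scenario loops convert this into a
        non-convergent replicate).
    ValidationError
        If the weight matrix row count does not match the item count.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(data=np.asarray(responses))
    if not isinstance(Q, WeightMatrix):
        Q = WeightMatrix(weights=np.asarray(Q))
    stats = _CmlStats.from_responses(responses)
    if Q.n_items != stats.k:
        raise ValidationError(
            f"weight matrix has {Q.n_items} rows but responses have {stats.k} items"
        )
    if not Q.is_identifiable:
        raise IdentifiabilityError(
            "[Q | 1] is rank deficient: basic parameters are not identified"
        )
    if stats.n_effective == 0:
        raise EstimationError(
            "no conditional information: every person has an extreme raw score"
        )
    W = Q.weights.astype(float)
    p = Q.n_operations

    def fg(eta: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = _neg_loglik_grad(W @ eta, stats)
        return f, W.T @ g

    b0 = _start_beta(stats)
    design = np.column_stack([W, np.ones(stats.k)])
    x0 = np.linalg.lstsq(design, b0, rcond=None)[0][:p]
    eta, iters, converged = _maximize(fg, x0, tol, max_iter)
    loglik = -fg(eta)[0]
    beta_rec = reconstruct_item_parameters(eta, Q)
    c = float(-(W @ eta).mean())
    eta_se = _eta_standard_errors(fg, eta)
    if not converged:
        logger.warning("LLTM CML fit did not converge in %d iterations", max_iter)
    return LLTMFit(
        eta=eta,
        c=c,
        beta_reconstructed=beta_rec,
        loglik=float(loglik),
        n_params=p,
        n_effective=stats.n_effective,
        n_persons=stats.n_persons,
        converged=converged,
        iterations=iters,
        data_checksum=stats.checksum,
        eta_se=eta_se,
        operation_ids=tuple(Q.operation_ids),
    )


def _eta_standard_errors(fg, eta: np.ndarray) -> np.ndarray:
    """Observed-information SEs from the Hessian of the negative loglik."""
    _, g = fg(eta)
    H = _fd_hessian(fg, eta, g)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            return np.full(eta.size, np.nan)
        return np.sqrt(diag)
    except np.linalg.LinAlgError:
        return np.full(eta.size, np.nan)
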