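"""Elementary symmetric functions and conditional-likelihood primitives.

Conditional maximum likelihood (CML) estimation of Rasch-family models
eliminates the person parameters by conditioning on each person's raw score
``r``.  The normalizing constant of the score-``r`` response-pattern
distribution is the elementary symmetric function (ESF) of order ``r`` of the
item easiness parameters ``eps_i = exp(-beta_i)``::

    gamma_r(eps) = sum over all r-subsets S of items of prod_{i in S} eps_i

This module computes the full ESF vector ``gamma_0 .. gamma_k`` together with
its first partial derivatives, using the *summation* recursion (items folded
in one at a time), which is numerically stable at any test length this
package targets.  To guard against overflow the easiness vector is rescaled
by its geometric mean — equivalently the difficulties are centred — and the
scale is restored afterwards (in log space for the likelihood).

The conditional log-likelihood of a binary response matrix given item
difficulties is also provided here; persons with extreme raw scores (0 or k)
have a degenerate conditional pattern distribution and contribute exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import ValidationError

__all__ = ["EsfTable", "elementary_symmetric", "conditional_loglik"]


def _validate_eps(eps) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if eps.ndim != 1:
        raise ValidationError("easiness vector must be one-dimensional")
    if eps.size < 2:
        raise ValidationError("at least two items are required (k >= 2)")
    if not np.all(np.isfinite(eps)):
        raise ValidationError("easiness values must be finite")
    if np.any(eps <= 0.0):
        raise ValidationError("easiness values must be strictly positive")
    return eps


@dataclass(frozen=True)
class EsfTable:
    """Elementary symmetric functions of an easiness vector.

    Attributes
    ----------
    gamma : ndarray, shape (k + 1,)
        ``gamma[r]`` is the ESF of order ``r``; ``gamma[0] == 1``.
    d_gamma : ndarray, shape (k, k + 1)
        ``d_gamma[i, r]`` is the partial derivative of ``gamma[r]`` with
        respect to ``eps[i]``, i.e. the order ``r - 1`` ESF of the easiness
        vector with item ``i`` removed (zero for ``r == 0``).
    """

    gamma: np.ndarray
    d_gamma: np.ndarray

    @property
    def k(self) -> int:
        return self.d_gamma.shape[0]


def _prefix_suffix(es: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix/suffix ESF tables by the summation recursion.

    ``prefix[m, r]`` is the order-``r`` ESF of ``es[:m]`` and
    ``suffix[m, r]`` the order-``r`` ESF of ``es[m:]``.
    """
    k = es.size
    prefix = np.zeros((k + 1, k + 1))
    prefix[0, 0] = 1.0
    for i in range(k):
        prefix[i + 1, : i + 2] = prefix[i, : i + 2]
        prefix[i + 1, 1 : i + 2] += es[i] * prefix[i, : i + 1]
    suffix = np.zeros((k + 1, k + 1))
    suffix[k, 0] = 1.0
    for i in range(k - 1, -1, -1):
        m = k - i
        suffix[i, : m + 1] = suffix[i + 1, : m + 1]
        suffix[i, 1 : m + 1] += es[i] * suffix[i + 1, :m]
    return prefix, suffix


def elementary_symmetric(eps) -> EsfTable:
    """Compute all ESFs of ``eps`` and their first partial derivatives.

    Parameters
    ----------
    eps : array-like, shape (k,)
        Strictly positive, finite item easiness values, ``k >= 2``.

    Returns
    -------
    EsfTable

    Raises
    ------
    ValidationError
        If ``eps`` is not a vector of at least two strictly positive,
        finite values.
    """
    eps = _validate_eps(eps)
    k = eps.size
    scale = float(np.exp(np.mean(np.log(eps))))
    es = eps / scale
    prefix, suffix = _prefix_suffix(es)
    gamma_scaled = prefix[k]
    d_scaled = np.zeros((k, k + 1))
    for i in range(k):
        # ESF of es without item i: convolve prefix of es[:i] with suffix of es[i+1:]
        gi = np.convolve(prefix[i, : i + 1], suffix[i + 1, : k - i])
        d_scaled[i, 1:] = gi
    orders = np.arange(k + 1)
    gamma = gamma_scaled * scale**orders
    d_gamma = d_scaled * scale ** (orders - 1.0)
    d_gamma[:, 0] = 0.0
    return EsfTable(gamma=gamma, d_gamma=d_gamma)


def _log_convolve(la: np.ndarray, lb: np.ndarray) -> np.ndarray:
    """Convolution of two sequences given in log space."""
    na, nb = la.size, lb.size
    out = np.full(na + nb - 1, -np.inf)
    for r in range(na + nb - 1):
        lo = max(0, r - nb + 1)
        hi = min(na - 1, r)
        idx = np.arange(lo, hi + 1)
        out[r] = logsumexp(la[idx] + lb[r - idx])
    return out


def _cond_tables_log(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-space fallback for :func:`_cond_tables` under extreme spreads."""
    k = beta.size
    bbar = float(beta.mean())
    logeps = -(beta - bbar)
    lp = np.full((k + 1, k + 1), -np.inf)
    lp[0, 0] = 0.0
    for i in range(k):
        lp[i + 1, : i + 2] = lp[i, : i + 2]
        lp[i + 1, 1 : i + 2] = np.logaddexp(lp[i + 1, 1 : i + 2], logeps[i] + lp[i, : i + 1])
    ls = np.full((k + 1, k + 1), -np.inf)
    ls[k, 0] = 0.0
    for i in range(k - 1, -1, -1):
        m = k - i
        ls[i, : m + 1] = ls[i + 1, : m + 1]
        ls[i, 1 : m + 1] = np.logaddexp(ls[i, 1 : m + 1], logeps[i] + ls[i + 1, :m])
    lgamma_scaled = lp[k]
    loggamma = lgamma_scaled - np.arange(k + 1) * bbar
    pi = np.zeros((k, k + 1))
    for i in range(k):
        lgi = _log_convolve(lp[i, : i + 1], ls[i + 1, : k - i])
        pi[i, 1:] = np.exp(logeps[i] + lgi - lgamma_scaled[1:])
    return loggamma, pi


def _cond_tables(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-ESFs and conditional item margins for difficulty vector ``beta``.

    Returns
    -------
    loggamma : ndarray, shape (k + 1,)
        ``log gamma_r(exp(-beta))``.
    pi : ndarray, shape (k, k + 1)
        ``pi[i, r] = P(X_i = 1 | raw score r)``, the conditional margin of
        item ``i`` among persons with raw score ``r``.
    """
    beta = np.asarray(beta, dtype=float)
    k = beta.size
    bbar = float(beta.mean())
    es = np.exp(-(beta - bbar))
    prefix, suffix = _prefix_suffix(es)
    gamma_scaled = prefix[k]
    if not np.all(np.isfinite(gamma_scaled)) or np.any(gamma_scaled <= 0.0):
        return _cond_tables_log(beta)
    loggamma = np.log(gamma_scaled) - np.arange(k + 1) * bbar
    pi = np.zeros((k, k + 1))
    for i in range(k):
        gi = np.convolve(prefix[i, : i + 1], suffix[i + 1, : k - i])
        pi[i, 1:] = es[i] * gi / gamma_scaled[1:]
    return loggamma, pi


def _response_array(responses) -> np.ndarray:
    """Coerce a ResponseMatrix or array-like to a validated 0/1 array."""
    data = getattr(responses, "data", responses)
    X = np.asarray(data)
    if X.ndim != 2:
        raise ValidationError("responses must be a persons x items matrix")
    if X.shape[1] < 2 or X.shape[0] < 1:
        raise ValidationError("responses need at least one person and two items")
    vals = np.unique(X)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError("responses must contain only 0 and 1")
    return X.astype(np.int64)


def conditional_loglik(beta, responses) -> float:
    """Conditional log-likelihood of ``responses`` at difficulties ``beta``.

    Sums, over persons with non-extreme raw score ``0 < r < k``,
    ``-sum_i x_i beta_i - log gamma_r``.  Persons with extreme scores
    contribute exactly zero: their conditional pattern probability is one.

    Raises
    ------
    ValidationError
        On a dimension mismatch or non-binary responses.
    """
    X = _response_array(responses)
    k = X.shape[1]
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (k,):
        raise ValidationError(
            f"beta has length {beta.size} but responses have {k} items"
        )
    scores = X.sum(axis=1)
    interior = (scores > 0) & (scores < k)
    if not interior.any():
        return 0.0
    s = X[interior].sum(axis=0).astype(float)
    counts = np.bincount(scores[interior], minlength=k + 1).astype(float)
    loggamma, _ = _cond_tables(beta)
    return float(-(s @ beta) - counts[1:k] @ loggamma[1:k])
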