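"""Independent brute-force oracles used to verify the ESF/CML implementation.

Everything here is deliberately naive — subset enumeration and full response
pattern enumeration — and shares no code with the package's summation
recursion or gradient-based fitting, so agreement is a genuine cross-check.
Only usable at small k.
"""

from itertools import combinations, product

import numpy as np
from scipy.optimize import minimize


def esf_bruteforce(eps):
    """gamma_r as an explicit sum over all r-subsets of items."""
    eps = np.asarray(eps, dtype=float)
    k = eps.size
    gamma = np.empty(k + 1)
    for r in range(k + 1):
        gamma[r] = sum(np.prod(eps[list(S)]) for S in combinations(range(k), r))
    return gamma


def esf_derivative_bruteforce(eps):
    """d gamma_r / d eps_i: order r-1 ESF of eps with item i removed."""
    eps = np.asarray(eps, dtype=float)
    k = eps.size
    d = np.zeros((k, k + 1))
    for i in range(k):
        rest = np.delete(eps, i)
        d[i, 1:] = esf_bruteforce(rest) if rest.size else [1.0]
    return d


def cond_loglik_bruteforce(beta, X):
    """Conditional log-likelihood by enumerating every response pattern.

    For each person with non-extreme score r, the conditional probability of
    the observed pattern is exp(-x.beta) normalized over all patterns with
    the same score.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X)
    k = X.shape[1]
    patterns = np.array(list(product((0, 1), repeat=k)))
    weights = np.exp(-(patterns @ beta))
    score_norm = {
        r: weights[patterns.sum(axis=1) == r].sum() for r in range(k + 1)
    }
    total = 0.0
    for x in X:
        r = int(x.sum())
        if r == 0 or r == k:
            continue
        total += -float(x @ beta) - np.log(score_norm[r])
    return total


def cml_fit_bruteforce(X):
    """Sum-zero Rasch difficulties maximizing the enumeration likelihood.

    Independent estimation route: enumeration-based objective, numerical
    gradients, Nelder-Mead refinement over a mean-centred parametrization.
    """
    X = np.asarray(X)
    k = X.shape[1]

    def neg(free):
        beta = np.append(free, -free.sum())
        return -cond_loglik_bruteforce(beta, X)

    res = minimize(neg, np.zeros(k - 1), method="BFGS")
    res = minimize(neg, res.x, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    beta = np.append(res.x, -res.x.sum())
    return beta - beta.mean()
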