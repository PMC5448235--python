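"""Likelihood-ratio test and information criteria for LLTM vs Rasch model.

The LLTM is nested in the Rasch model, so the deviance difference

    D = -2 (logL_LLTM - logL_RM)

is asymptotically chi-square with ``df = (k - 1) - p`` degrees of freedom
(the RM estimates ``k - 1`` identified difficulties, the LLTM ``p`` basic
parameters).  AIC and BIC use the conditional deviances:

    AIC = deviance + 2 * n_params
    BIC = deviance + n_params * ln(n)

where ``n`` defaults to the number of persons contributing to the
conditional likelihood (non-extreme raw scores) and can be overridden.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import chi2

from .estimation import LLTMFit, RaschFit
from .exceptions import NotConvergedError, ValidationError

__all__ = ["ComparisonResult", "lr_test", "information_criteria", "aic_bic"]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of comparing an LLTM against the Rasch model on one dataset."""

    lr_statistic: float
    df: int
    p_value: float
    aic_rm: float
    bic_rm: float
    aic_lltm: float
    bic_lltm: float
    n_for_bic: int
    favors_lltm_aic: bool
    favors_lltm_bic: bool

    def to_dict(self) -> dict:
        return asdict(self)


def aic_bic(deviance: float, n_params: int, n_for_bic: int) -> tuple[float, float]:
    """AIC and BIC from a deviance and parameter count."""
    if n_for_bic < 1:
        raise ValidationError("n_for_bic must be at least 1")
    aic = deviance + 2.0 * n_params
    bic = deviance + n_params * np.log(n_for_bic)
    return float(aic), float(bic)


def information_criteria(fit, n_for_bic: int | None = None) -> tuple[float, float]:
    """AIC and BIC of a converged Rasch or LLTM fit.

    ``n_for_bic`` defaults to the fit's effective sample size (persons with
    non-extreme raw scores).

    Raises
    ------
    NotConvergedError
        If the fit did not converge.
    """
    if not fit.converged:
        raise NotConvergedError(
            "information criteria of a non-converged fit are meaningless; "
            "exclude this replicate"
        )
    n = fit.n_effective if n_for_bic is None else n_for_bic
    return aic_bic(fit.deviance, fit.n_params, n)


def lr_test(rm: RaschFit, lltm: LLTMFit, n_for_bic: int | None = None) -> ComparisonResult:
    """Chi-square likelihood-ratio test of the LLTM against the Rasch model.

    Both fits must come from the same data (verified by fingerprint) and be
    converged.  The statistic is one-sided by construction, so only the
    upper chi-square tail is used; a tiny negative D (convergence noise) is
    clamped to zero for the p-value.

    Raises
    ------
    ValidationError
        If the fits are not from the same data.
    NotConvergedError
        If either fit is non-converged (scenario loops record the replicate
        as non-convergent instead of failing).
    """
    if rm.data_checksum != lltm.data_checksum or rm.n_effective != lltm.n_effective:
        raise ValidationError("fits do not come from the same response data")
    if rm.k != lltm.k:
        raise ValidationError("fits disagree on the number of items")
    if not (rm.converged and lltm.converged):
        raise NotConvergedError(
            "LR test requires converged fits; exclude this replicate"
        )
    D = lltm.deviance - rm.deviance
    df = (rm.k - 1) - lltm.n_params
    if df == 0:
        # saturated Q: chi-square with 0 df is a point mass at zero
        p_value = 1.0 if D <= 1e-8 else 0.0
    else:
        p_value = float(chi2.sf(max(D, 0.0), df))
    n = rm.n_effective if n_for_bic is None else n_for_bic
    aic_rm, bic_rm = aic_bic(rm.deviance, rm.n_params, n)
    aic_lltm, bic_lltm = aic_bic(lltm.deviance, lltm.n_params, n)
    return ComparisonResult(
        lr_statistic=float(D),
        df=df,
        p_value=p_value,
        aic_rm=aic_rm,
        bic_rm=bic_rm,
        aic_lltm=aic_lltm,
        bic_lltm=bic_lltm,
        n_for_bic=n,
        # ties favor the more parsimonious reading: LLTM must be strictly smaller
        favors_lltm_aic=bool(aic_lltm < aic_rm),
        favors_lltm_bic=bool(bic_lltm < bic_rm),
    )
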