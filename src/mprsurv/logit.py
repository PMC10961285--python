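"""Logistic treatment-allocation model.

Models the probability that a subject receives curative-intent therapy,
Pr(Y=1) = exp(x'β) / (1 + exp(x'β)), on dummy-coded cohort factors.
Fitting delegates to statsmodels' Newton/IRLS maximum-likelihood machinery;
the factor coding, forward selection and prediction surfaces live here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .design import DesignSpec, build_design


@dataclass(frozen=True)
class LogitFit:
    """Fitted allocation model: Wald-type s.e. and two-sided z p-values."""

    coefs: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    loglik: float
    aic: float
    fitted_probs: np.ndarray
    design_spec: DesignSpec
    converged: bool
    outcome: str = "treated"
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "coefs": self.coefs,
            "se": self.se,
            "p_values": self.p_values,
            "loglik": self.loglik,
            "aic": self.aic,
            "factors": list(self.design_spec.factors),
            "reference_levels": dict(self.design_spec.reference),
            "converged": self.converged,
            "outcome": self.outcome,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def logit_fit(cohort: pd.DataFrame, factors=(), outcome: str = "treated") -> LogitFit:
    """ML fit of the allocation model on the named cohort factors."""
    y = cohort[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model not estimable")
    X, spec = build_design(cohort, tuple(factors), require_occupied=True)

    converged = True
    message = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as err:  # perfect separation raises in statsmodels
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
            converged = False
            message = f"flagged: {err}"
    params = np.asarray(res.params, dtype=float)
    try:
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
    except Exception:
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    if not np.all(np.isfinite(bse)):
        converged = False
        message = message or "flagged: non-finite standard errors (separation?)"
    if not converged and not message:
        message = "flagged: ML iteration did not converge (possible separation)"

    eta = X @ params
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    k = params.size
    return LogitFit(
        coefs=dict(zip(spec.columns, map(float, params))),
        se=dict(zip(spec.columns, map(float, bse))),
        p_values=dict(zip(spec.columns, map(float, pvals))),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        fitted_probs=expit(eta),
        design_spec=spec,
        converged=converged,
        outcome=outcome,
        message=message,
    )


def logit_stepwise(
    cohort: pd.DataFrame,
    candidate_factors,
    outcome: str = "treated",
    *,
    trace: list | None = None,
) -> LogitFit:
    """Forward selection over whole factors by AIC decrease."""
    candidates = list(candidate_factors)
    if not candidates:
        raise ValueError("at least one candidate factor is required")
    selected: list[str] = []
    current = logit_fit(cohort, selected, outcome)
    while True:
        best: tuple[float, str, LogitFit] | None = None
        for factor in candidates:
            if factor in selected:
                continue
            fit = logit_fit(cohort, selected + [factor], outcome)
            if best is None or fit.aic < best[0]:
                best = (fit.aic, factor, fit)
        if best is None or best[0] >= current.aic - 1e-9:
            break
        _, factor, current = best
        selected.append(factor)
        if trace is not None:
            trace.append((factor, current.aic))
    return current


def predict_prob(fit: LogitFit, cohort: pd.DataFrame) -> np.ndarray:
    """Allocation probability for each cohort row under the fitted model."""
    X, _ = build_design(cohort, fit.design_spec.factors)
    beta = np.array([fit.coefs[c] for c in fit.design_spec.columns])
    return expit(X @ beta)
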