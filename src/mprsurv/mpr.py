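"""Weibull multi-parameter regression (MPR) survival model.

The hazard is λ(t) = λγt^{γ−1} with *both* Weibull parameters regressed on
covariates through log links,

    λ_i = exp(x_i'β)   (scale),      γ_i = exp(z_i'α)   (shape),

so covariates in the shape predictor make hazard ratios time-dependent: the
model is non-proportional-hazards unless the shape design is intercept-only,
in which case it collapses to the standard Weibull PH model.  With survival
time t_i and death indicator δ_i the right-censored log-likelihood is

    ℓ(β, α) = Σ_i [ δ_i (x_i'β + z_i'α + (e^{z_i'α} − 1) log t_i)
                    − e^{x_i'β} t_i^{e^{z_i'α}} ],

maximised jointly over (β, α) by quasi-Newton iteration with the analytic
gradient; the log links make the problem unconstrained.  Standard errors
come from the inverse of the numerically differentiated observed
information at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .design import DesignSpec, build_design

GRAD_TOL = 1e-8  # optimizer target on the gradient norm
CONVERGED_TOL = 1e-5  # acceptance threshold for flagging convergence


class MPRNumericalError(FloatingPointError):
    """Non-finite linear predictor or likelihood during evaluation."""


def mpr_loglik(beta, alpha, scale_design, shape_design, times, events) -> float:
    """Right-censored Weibull MPR log-likelihood at (β, α)."""
    beta = np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    X = np.asarray(scale_design, dtype=float)
    Z = np.asarray(shape_design, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=float)
    if X.shape[0] != t.size or Z.shape[0] != t.size or d.size != t.size:
        raise ValueError("design rows must match the number of subjects")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    eta = X @ beta
    nu = Z @ alpha
    if not (np.all(np.isfinite(eta)) and np.all(np.isfinite(nu))):
        raise MPRNumericalError(
            "non-finite linear predictor: max|x'β|="
            f"{np.nanmax(np.abs(eta)):.3g}, max|z'α|={np.nanmax(np.abs(nu)):.3g}"
        )
    gamma = np.exp(nu)
    logt = np.log(t)
    ll = np.sum(d * (eta + nu + (gamma - 1.0) * logt) - np.exp(eta + gamma * logt))
    if not np.isfinite(ll):
        raise MPRNumericalError("log-likelihood overflowed; predictors too extreme")
    return float(ll)


def _nll_and_grad(theta, X, Z, t_log, d, p):
    """Guarded negative log-likelihood and gradient for the optimizer.

    Exponents are clipped far outside the plausible region so that line
    searches recover from wild trial steps instead of overflowing.
    """
    beta, alpha = theta[:p], theta[p:]
    with np.errstate(over="ignore", invalid="ignore"):
        eta = X @ beta
        nu = np.minimum(Z @ alpha, 20.0)
        gamma = np.exp(nu)
        w = np.minimum(eta + gamma * t_log, 400.0)
        H = np.exp(w)
        ll = np.sum(d * (eta + nu + (gamma - 1.0) * t_log) - H)
        resid = d - H
        g_beta = X.T @ resid
        g_alpha = Z.T @ (d + gamma * t_log * resid)
    if not np.isfinite(ll):
        ll = -np.inf
    grad = np.concatenate([g_beta, g_alpha])
    return -ll, -np.nan_to_num(grad, posinf=1e12, neginf=-1e12)


@dataclass(frozen=True)
class MPRFit:
    """A fitted Weibull MPR model.

    Coefficients and standard errors are keyed by dummy-column name;
    reference levels carry an implicit 0.  ``scale_design_means`` /
    ``shape_design_means`` are the cohort means of each design column
    (the dummy proportions), kept for covariate-averaged prediction.
    """

    scale_coefs: dict[str, float]
    shape_coefs: dict[str, float]
    se_scale: dict[str, float]
    se_shape: dict[str, float]
    loglik: float
    aic: float
    n: int
    n_events: int
    converged: bool
    scale_spec: DesignSpec
    shape_spec: DesignSpec
    scale_design_means: np.ndarray
    shape_design_means: np.ndarray
    grad_norm: float
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.scale_coefs) + len(self.shape_coefs)

    def beta(self) -> np.ndarray:
        return np.array([self.scale_coefs[c] for c in self.scale_spec.columns])

    def alpha(self) -> np.ndarray:
        return np.array([self.shape_coefs[c] for c in self.shape_spec.columns])

    def z_table(self) -> pd.DataFrame:
        """Coefficients, s.e. and |z| = |mle/s.e.| for both components.

        An effect is conventionally reported as significant when |z| ≥ 2.
        """
        rows = []
        for comp, coefs, ses in (
            ("scale", self.scale_coefs, self.se_scale),
            ("shape", self.shape_coefs, self.se_shape),
        ):
            for name, value in coefs.items():
                se = ses[name]
                rows.append(
                    {
                        "component": comp,
                        "term": name,
                        "mle": value,
                        "se": se,
                        "z": value / se if se > 0 else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scale_coefs": self.scale_coefs,
            "shape_coefs": self.shape_coefs,
            "se_scale": self.se_scale,
            "se_shape": self.se_shape,
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
            "scale_factors": list(self.scale_spec.factors),
            "shape_factors": list(self.shape_spec.factors),
            "reference_levels": {
                **self.scale_spec.reference,
                **self.shape_spec.reference,
            },
            "grad_norm": self.grad_norm,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _newton_polish(theta, args, max_iter: int = 20):
    """Damped Newton refinement after the quasi-Newton run.

    BFGS line searches can stall from floating-point precision loss a few
    orders of magnitude short of the gradient target; a handful of Newton
    steps on the observed information finishes the job when the optimum is
    regular.  On degenerate ridges (unbounded likelihood directions) the
    polish simply fails to reach the target and the fit is flagged.
    """
    X, Z, t_log, d, p = args
    f, g = _nll_and_grad(theta, *args)
    for _ in range(max_iter):
        gnorm = np.linalg.norm(g, np.inf)
        if gnorm < GRAD_TOL:
            break
        info = _observed_information(theta, X, Z, t_log, d, p)
        try:
            step = np.linalg.solve(info, -g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        improved = False
        for _ in range(25):
            cand = theta + scale * step
            f_new, g_new = _nll_and_grad(cand, *args)
            if f_new <= f + 1e-12:
                theta, f, g = cand, f_new, g_new
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    return theta, float(np.linalg.norm(g, np.inf))


def _observed_information(theta, X, Z, t_log, d, p):
    """Numerically differentiated observed information (central differences
    of the analytic gradient)."""
    k = theta.size
    info = np.zeros((k, k))
    for j in range(k):
        h = 1e-5 * max(1.0, abs(theta[j]))
        up = theta.copy()
        up[j] += h
        dn = theta.copy()
        dn[j] -= h
        _, g_up = _nll_and_grad(up, X, Z, t_log, d, p)
        _, g_dn = _nll_and_grad(dn, X, Z, t_log, d, p)
        info[:, j] = (g_up - g_dn) / (2.0 * h)
    return 0.5 * (info + info.T)


def mpr_fit(
    cohort: pd.DataFrame,
    scale_factors=(),
    shape_factors=(),
    *,
    start: tuple[dict[str, float], dict[str, float]] | None = None,
) -> MPRFit:
    """Maximum-likelihood fit of the Weibull MPR model.

    ``scale_factors`` / ``shape_factors`` name the cohort factors entering
    each component; empty tuples give the intercept-only predictor (an
    intercept-only shape is exactly the Weibull PH special case).  ``start``
    optionally warm-starts named coefficients; everything else begins at the
    exponential-model starting point (scale intercept log(Σδ/Σt), rest 0).
    """
    t = cohort["time"].to_numpy(dtype=float)
    d = cohort["event"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    if d.sum() < 1:
        raise ValueError("at least one event is required to fit the model")
    X, scale_spec = build_design(cohort, tuple(scale_factors), require_occupied=True)
    Z, shape_spec = build_design(cohort, tuple(shape_factors), require_occupied=True)
    p, q = X.shape[1], Z.shape[1]
    t_log = np.log(t)

    x0 = np.zeros(p + q)
    x0[0] = np.log(d.sum() / t.sum())
    if start is not None:
        start_scale, start_shape = start
        for j, col in enumerate(scale_spec.columns):
            if col in start_scale:
                x0[j] = start_scale[col]
        for j, col in enumerate(shape_spec.columns):
            if col in start_shape:
                x0[p + j] = start_shape[col]

    args = (X, Z, t_log, d, p)
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=args,
        jac=True,
        method="BFGS",
        options={"gtol": GRAD_TOL, "maxiter": 1000},
    )
    # BFGS can stop on line-search precision loss short of the target; a
    # restart from the current point usually finishes the job
    if np.linalg.norm(res.jac, np.inf) >= CONVERGED_TOL:
        res = optimize.minimize(
            _nll_and_grad,
            res.x,
            args=args,
            jac=True,
            method="BFGS",
            options={"gtol": GRAD_TOL, "maxiter": 1000},
        )

    theta, grad_norm = _newton_polish(res.x, args)
    converged = grad_norm < CONVERGED_TOL

    info = _observed_information(theta, X, Z, t_log, d, p)
    se = np.full(p + q, np.nan)
    message = res.message
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            converged = False
            message = f"{message}; observed information not positive definite"
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.where(diag > 0, diag, np.nan))
    except np.linalg.LinAlgError:
        converged = False
        message = f"{message}; singular observed information"

    loglik = -float(res.fun)
    k = p + q
    return MPRFit(
        scale_coefs=dict(zip(scale_spec.columns, map(float, theta[:p]))),
        shape_coefs=dict(zip(shape_spec.columns, map(float, theta[p:]))),
        se_scale=dict(zip(scale_spec.columns, map(float, se[:p]))),
        se_shape=dict(zip(shape_spec.columns, map(float, se[p:]))),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n=len(cohort),
        n_events=int(d.sum()),
        converged=converged,
        scale_spec=scale_spec,
        shape_spec=shape_spec,
        scale_design_means=X.mean(axis=0),
        shape_design_means=Z.mean(axis=0),
        grad_norm=grad_norm,
        message=str(message),
    )


def mpr_aic_compare(fit_ph: MPRFit, fit_mpr: MPRFit) -> float:
    """AIC(PH) − AIC(MPR); positive favours the non-PH model."""
    if fit_ph.n != fit_mpr.n or fit_ph.n_events != fit_mpr.n_events:
        raise ValueError("AIC comparison requires fits on the same cohort")
    return fit_ph.aic - fit_mpr.aic


def mpr_stepwise(
    cohort: pd.DataFrame,
    candidate_factors,
    *,
    trace: list | None = None,
) -> MPRFit:
    """Forward selection over whole factors into the scale or the shape.

    Starting from intercept-only predictors, each step considers adding one
    remaining factor to either component and accepts the single move with
    the largest AIC decrease, stopping when no move lowers the AIC.  A
    factor can end up in the scale only, the shape only, or both.
    """
    candidates = list(candidate_factors)
    if not candidates:
        raise ValueError("at least one candidate factor is required")
    scale_factors: list[str] = []
    shape_factors: list[str] = []
    current = mpr_fit(cohort, scale_factors, shape_factors)
    while True:
        warm = (current.scale_coefs, current.shape_coefs)
        best: tuple[float, str, str, MPRFit] | None = None
        for factor in candidates:
            moves = []
            if factor not in scale_factors:
                moves.append(("scale", scale_factors + [factor], shape_factors))
            if factor not in shape_factors:
                moves.append(("shape", scale_factors, shape_factors + [factor]))
            for component, sc, sh in moves:
                fit = mpr_fit(cohort, sc, sh, start=warm)
                # a flagged fit signals a flat or unbounded likelihood
                # direction (e.g. a tiny factor level); never select it
                if not fit.converged:
                    continue
                if best is None or fit.aic < best[0]:
                    best = (fit.aic, factor, component, fit)
        if best is None or best[0] >= current.aic - 1e-9:
            break
        _, factor, component, current = best
        if component == "scale":
            scale_factors.append(factor)
        else:
            shape_factors.append(factor)
        if trace is not None:
            trace.append((factor, component, current.aic))
    return current


def survival_function(lam: float, gamma: float, times) -> np.ndarray:
    """S(t) = exp(−λ t^γ) for scalar Weibull parameters."""
    t = np.asarray(times, dtype=float)
    if lam <= 0 or gamma <= 0:
        raise ValueError("Weibull parameters must be positive")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    return np.exp(-lam * t**gamma)


def mpr_predict_survival(fit: MPRFit, covariate_profile: dict[str, str], times) -> np.ndarray:
    """Predicted survival for a covariate profile; factors omitted from the
    profile sit at their reference level."""
    x = fit.scale_spec.row(covariate_profile)
    z = fit.shape_spec.row(covariate_profile)
    lam = float(np.exp(x @ fit.beta()))
    gamma = float(np.exp(z @ fit.alpha()))
    return survival_function(lam, gamma, times)


def adjusted_tracks(
    fit: MPRFit, treatment_factor: str, times
) -> dict[str, np.ndarray]:
    """Covariate-averaged survival track per treatment level.

    Each track evaluates the fitted model at a design vector whose treatment
    dummies are set to one level and whose every other column sits at its
    cohort mean — survival for a subject on that treatment who is average
    with respect to all other modelled covariates.  When treatment is the
    only factor in the fit, the tracks equal the plain predicted tracks.
    """
    from .design import FACTOR_LEVELS, DesignError, column_name

    in_scale = treatment_factor in fit.scale_spec.factors
    in_shape = treatment_factor in fit.shape_spec.factors
    if not (in_scale or in_shape):
        raise DesignError(f"factor {treatment_factor!r} is not in the fitted model")
    tracks: dict[str, np.ndarray] = {}
    for level in FACTOR_LEVELS[treatment_factor]:
        x = fit.scale_design_means.copy()
        z = fit.shape_design_means.copy()
        x[0] = 1.0
        z[0] = 1.0
        for spec, vec in ((fit.scale_spec, x), (fit.shape_spec, z)):
            if treatment_factor not in spec.factors:
                continue
            for other in FACTOR_LEVELS[treatment_factor][1:]:
                j = spec.columns.index(column_name(treatment_factor, other))
                vec[j] = 1.0 if other == level else 0.0
        lam = float(np.exp(x @ fit.beta()))
        gamma = float(np.exp(z @ fit.alpha()))
        tracks[level] = survival_function(lam, gamma, times)
    return tracks
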