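"""End-to-end analysis pipeline over a cohort CSV.

Stages, in the order the analysis is staged: overall and per-treatment
Kaplan–Meier curves with the log-rank test; the treatment-only Weibull MPR
fit and its PH comparison; stepwise MPR over the nine candidate factors;
stepwise logistic allocation model; allocation probabilities; the screening
table with its metrics; survival by screening cell and by probability
quartile; and covariate-averaged treatment tracks.  Everything in the
report is recomputable from the cohort CSV and the configuration alone —
the pipeline itself consumes no randomness.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd

from . import tables
from .cohort import read_cohort, validate_cohort
from .km import KMCurve, km_estimate, logrank_test
from .logit import logit_stepwise, predict_prob
from .mpr import adjusted_tracks, mpr_aic_compare, mpr_fit, mpr_stepwise
from .screening import (
    assign_cells,
    build_screening_table,
    screening_metrics,
    survival_by_cell,
    survival_by_quartile,
)

logger = logging.getLogger("mprsurv.pipeline")

DEFAULT_CONFIG = {
    "cutoff": 0.5,
    "level": 0.95,
    "survival_candidates": list(tables.SURVIVAL_CANDIDATE_FACTORS),
    "allocation_candidates": list(tables.ALLOCATION_FACTORS),
    "track_months": 12.0,
}


def _km_summary(curve: KMCurve, at: float) -> dict:
    s = float(curve.survival_at(at)) if curve.event_times.size else 1.0
    idx = np.searchsorted(curve.event_times, at, side="right") - 1
    lo = float(curve.ci_lower[idx]) if idx >= 0 else 1.0
    hi = float(curve.ci_upper[idx]) if idx >= 0 else 1.0
    return {
        "median": curve.median,
        "survival_at": at,
        "survival": s,
        "ci_lower": lo,
        "ci_upper": hi,
        "n": int(curve.at_risk[0]) if curve.at_risk.size else None,
    }


def run_pipeline(cohort: pd.DataFrame | str, config: dict | None = None) -> dict:
    """Run every analysis stage and return the report as a plain dict."""
    if isinstance(cohort, (str, bytes)) or hasattr(cohort, "__fspath__"):
        cohort = read_cohort(cohort)
    else:
        validate_cohort(cohort)
    cohort = cohort.reset_index(drop=True)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    at = float(cfg["track_months"])
    level = float(cfg["level"])
    n = len(cohort)
    logger.info("cohort loaded: %d subjects, %d events", n, int(cohort["event"].sum()))

    times = cohort["time"].to_numpy()
    events = cohort["event"].to_numpy()
    treatment = cohort["treatment"].to_numpy()

    km_overall = km_estimate(times, events, level)
    km_by_treatment = {
        lvl: _km_summary(km_estimate(times[treatment == lvl], events[treatment == lvl], level), at)
        for lvl in pd.unique(treatment)
    }
    chi2, df, p = logrank_test(times, events, treatment)
    logger.info("KM/log-rank done: chi2=%.3f df=%d", chi2, df)

    fit_mpr = mpr_fit(cohort, ["treatment"], ["treatment"])
    fit_ph = mpr_fit(cohort, ["treatment"], [])
    aic_diff = mpr_aic_compare(fit_ph, fit_mpr)
    logger.info("treatment-only MPR done: AIC(PH)-AIC(MPR)=%.2f", aic_diff)

    step_trace: list = []
    fit_step = mpr_stepwise(cohort, cfg["survival_candidates"], trace=step_trace)
    logger.info(
        "stepwise MPR done: scale=%s shape=%s",
        fit_step.scale_spec.factors,
        fit_step.shape_spec.factors,
    )

    logit_trace: list = []
    fit_logit = logit_stepwise(cohort, cfg["allocation_candidates"], trace=logit_trace)
    probs = predict_prob(fit_logit, cohort)
    logger.info("allocation model done: factors=%s", fit_logit.design_spec.factors)

    treated = cohort["treated"].to_numpy()
    table = build_screening_table(probs, treated, cfg["cutoff"])
    metrics = screening_metrics(table)
    cells = assign_cells(probs, treated, cfg["cutoff"])
    cell_curves = survival_by_cell(cohort, cells, level)
    quartile_curves = survival_by_quartile(cohort, probs, level)
    logger.info("screening done: table=%s", table.to_dict())

    months = np.arange(0.0, tables.MAX_FOLLOWUP_MONTHS + 0.5, 0.5)
    tracks = adjusted_tracks(fit_step, "treatment", months)
    unadjusted = adjusted_tracks(fit_mpr, "treatment", months)

    try:
        pkg_version = version("mprsurv")
    except PackageNotFoundError:
        pkg_version = "unknown"

    report = {
        "provenance": {"version": pkg_version, "n": n, "config": cfg},
        "km_overall": _km_summary(km_overall, at),
        "km_by_treatment": km_by_treatment,
        "logrank": {"chi_square": chi2, "df": df, "p_value": p},
        "mpr_treatment_fit": fit_mpr.to_dict(),
        "mpr_ph_fit": fit_ph.to_dict(),
        "aic_comparison": aic_diff,
        "mpr_stepwise_fit": fit_step.to_dict(),
        "mpr_stepwise_trace": [list(s) for s in step_trace],
        "logit_fit": fit_logit.to_dict(),
        "logit_trace": [list(s) for s in logit_trace],
        "screening": {"table": table.to_dict(), "metrics": metrics},
        "cell_summaries": {c: _km_summary(k, at) for c, k in cell_curves.items()},
        "quartile_summaries": {str(q): _km_summary(k, at) for q, k in quartile_curves.items()},
        "adjusted_tracks_months": {
            lvl: float(np.interp(at, months, s)) for lvl, s in tracks.items()
        },
        "unadjusted_tracks_months": {
            lvl: float(np.interp(at, months, s)) for lvl, s in unadjusted.items()
        },
    }
    return report


def save_report(report: dict, path) -> None:
    """Write the report deterministically (sorted keys, fixed float repr)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
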