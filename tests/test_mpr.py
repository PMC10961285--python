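"""Weibull MPR model: likelihood oracles, gradient and grid checks,
selection behaviour, prediction and covariate-averaged tracks."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cohort
from mprsurv import tables
from mprsurv.cohort import default_treatment_only_config, generate_cohort, sample_weibull
from mprsurv.design import DesignError, build_design
from mprsurv.mpr import (
    MPRFit,
    adjusted_tracks,
    mpr_aic_compare,
    mpr_fit,
    mpr_loglik,
    mpr_predict_survival,
    mpr_stepwise,
    survival_function,
    _nll_and_grad,
)

# frozen oracle: exp(−e^{−1.280−3.909} · 12^{e^{−0.194+0.593}}) evaluated
# independently as a scalar
SURGERY_ONE_YEAR = 0.7974366524


def published_treatment_fit(cohort: pd.DataFrame) -> MPRFit:
    """MPRFit carrying the published treatment-only coefficients (synthetic
    fit object: everything but the coefficients is taken from ``cohort``)."""
    X, scale_spec = build_design(cohort, ("treatment",))
    Z, shape_spec = build_design(cohort, ("treatment",))
    beta = {c: tables.TREATMENT_ONLY_SCALE[c] for c in scale_spec.columns}
    alpha = {c: tables.TREATMENT_ONLY_SHAPE[c] for c in shape_spec.columns}
    return MPRFit(
        scale_coefs=beta,
        shape_coefs=alpha,
        se_scale={c: np.nan for c in scale_spec.columns},
        se_shape={c: np.nan for c in shape_spec.columns},
        loglik=np.nan,
        aic=np.nan,
        n=len(cohort),
        n_events=int(cohort["event"].sum()),
        converged=True,
        scale_spec=scale_spec,
        shape_spec=shape_spec,
        scale_design_means=X.mean(axis=0),
        shape_design_means=Z.mean(axis=0),
        grad_norm=0.0,
    )


class TestLoglik:
    def test_single_event_at_unit_time(self):
        # δ=1, t=1, β=α=0: log λ + log γ + 0 − λ = −1
        ll = mpr_loglik([0.0], [0.0], [[1.0]], [[1.0]], [1.0], [1])
        assert ll == pytest.approx(-1.0)

    def test_single_censored_subject(self):
        # δ=0, t=2, λ=0.5, γ=1: −λt = −1
        ll = mpr_loglik([np.log(0.5)], [0.0], [[1.0]], [[1.0]], [2.0], [0])
        assert ll == pytest.approx(-1.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            mpr_loglik([0.0], [0.0], [[1.0]], [[1.0]], [0.0], [1])

    def test_nonfinite_predictor_raises_diagnostic(self):
        with pytest.raises(FloatingPointError):
            mpr_loglik([np.inf], [0.0], [[1.0]], [[1.0]], [1.0], [1])

    def test_shape_zero_nests_ph_weibull(self, treatment_cohort):
        # α ≡ (α0, 0, ...) on the MPR design equals the PH likelihood at α0
        Xs, _ = build_design(treatment_cohort, ("treatment",))
        Zi, _ = build_design(treatment_cohort, ())
        Zm, _ = build_design(treatment_cohort, ("treatment",))
        t = treatment_cohort["time"]
        d = treatment_cohort["event"]
        beta = np.array([-1.2, -3.0, -0.5, -1.0, -3.5])
        for a0 in (-0.2, 0.0, 0.3):
            ph = mpr_loglik(beta, [a0], Xs, Zi, t, d)
            mpr = mpr_loglik(beta, [a0, 0, 0, 0, 0], Xs, Zm, t, d)
            assert mpr == pytest.approx(ph, rel=1e-12)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(8)
        n = 30
        frame = make_cohort(
            rng.uniform(0.2, 10, n),
            rng.integers(0, 2, n),
            treatment=rng.choice(["palliative", "surgery"], n),
            sex=rng.choice(["male", "female"], n),
        )
        X, _ = build_design(frame, ("treatment", "sex"))
        Z, _ = build_design(frame, ("sex",))
        t_log = np.log(frame["time"].to_numpy())
        d = frame["event"].to_numpy(dtype=float)
        p = X.shape[1]
        theta = rng.normal(scale=0.4, size=p + Z.shape[1])
        _, grad = _nll_and_grad(theta, X, Z, t_log, d, p)
        for j in range(theta.size):
            h = 1e-6 * max(1.0, abs(theta[j]))
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            f_up, _ = _nll_and_grad(up, X, Z, t_log, d, p)
            f_dn, _ = _nll_and_grad(dn, X, Z, t_log, d, p)
            fd = (f_up - f_dn) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestFit:
    def test_exponential_closed_form(self):
        rng = np.random.default_rng(5)
        n = 3000
        t_true = rng.exponential(scale=2.0, size=n)
        censor = rng.uniform(1, 8, size=n)
        frame = make_cohort(np.minimum(t_true, censor), (t_true <= censor).astype(int))
        fit = mpr_fit(frame)
        d, t = frame["event"].sum(), frame["time"].sum()
        assert fit.shape_coefs["intercept"] == pytest.approx(0.0, abs=0.05)
        assert fit.scale_coefs["intercept"] == pytest.approx(np.log(d / t), abs=0.05)

    def test_grid_search_cannot_beat_optimum(self):
        # 12-subject toy cohort, one binary covariate in the scale
        times = [0.4, 0.9, 1.3, 2.2, 3.1, 4.0, 0.6, 1.8, 2.5, 3.3, 5.1, 6.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1]
        sex = ["male"] * 6 + ["female"] * 6
        frame = make_cohort(times, events, sex=sex)
        fit = mpr_fit(frame, ("sex",), ())
        X, _ = build_design(frame, ("sex",))
        Z, _ = build_design(frame, ())
        best_grid = -np.inf
        for b0 in np.linspace(-3, 1, 21):
            for b1 in np.linspace(-2, 2, 21):
                for a0 in np.linspace(-1, 1, 21):
                    best_grid = max(
                        best_grid,
                        mpr_loglik([b0, b1], [a0], X, Z, times, events),
                    )
        assert fit.loglik >= best_grid - 1e-9
        assert fit.converged

    def test_aic_definition_and_se_positive(self, treatment_cohort):
        fit = mpr_fit(treatment_cohort, ("treatment",), ("treatment",))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.converged
        assert all(np.isfinite(v) and v > 0 for v in fit.se_scale.values())
        assert all(np.isfinite(v) and v > 0 for v in fit.se_shape.values())

    def test_row_and_factor_order_invariance(self, treatment_cohort):
        base = mpr_fit(treatment_cohort, ("treatment", "sex"), ("treatment",))
        shuffled = treatment_cohort.sample(frac=1.0, random_state=1)
        perm = mpr_fit(shuffled, ("sex", "treatment"), ("treatment",))
        for name, value in base.scale_coefs.items():
            assert perm.scale_coefs[name] == pytest.approx(value, abs=1e-5)
        assert perm.loglik == pytest.approx(base.loglik, abs=1e-6)

    def test_nested_model_likelihood_monotone(self, treatment_cohort):
        small = mpr_fit(treatment_cohort, ("treatment",), ())
        large = mpr_fit(treatment_cohort, ("treatment",), ("treatment",))
        assert large.loglik >= small.loglik - 1e-8

    def test_no_events_rejected(self):
        frame = make_cohort([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            mpr_fit(frame)

    def test_empty_factor_level_rejected(self):
        frame = make_cohort([1.0, 2.0, 3.0], [1, 1, 1], sex=["male"] * 3)
        with pytest.raises(DesignError):
            mpr_fit(frame, ("sex",), ())

    def test_bias_shrinks_with_sample_size(self):
        # parameter recovery: radiotherapy effects at n and 4n
        def mean_estimates(n, seeds):
            sc, sh = [], []
            for s in seeds:
                frame = generate_cohort(default_treatment_only_config(n=n, seed=s))
                fit = mpr_fit(frame, ("treatment",), ("treatment",))
                sc.append(fit.scale_coefs["treatment:radiotherapy"])
                sh.append(fit.shape_coefs["treatment:radiotherapy"])
            return np.mean(sc), np.mean(sh)

        seeds = range(300, 330)
        sc_small, sh_small = mean_estimates(855, seeds)
        sc_large, sh_large = mean_estimates(4 * 855, seeds)
        truth_sc = tables.TREATMENT_ONLY_SCALE["treatment:radiotherapy"]
        truth_sh = tables.TREATMENT_ONLY_SHAPE["treatment:radiotherapy"]
        assert abs(sc_large - truth_sc) < abs(sc_small - truth_sc) + 0.02
        assert abs(sh_large - truth_sh) < abs(sh_small - truth_sh) + 0.01
        assert sc_large == pytest.approx(truth_sc, abs=0.1)
        assert sh_large == pytest.approx(truth_sh, abs=0.05)


class TestAICCompare:
    def test_identical_specs_give_zero(self, treatment_cohort):
        a = mpr_fit(treatment_cohort, ("treatment",), ())
        b = mpr_fit(treatment_cohort, ("treatment",), ())
        assert mpr_aic_compare(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_different_cohorts_rejected(self, treatment_cohort):
        a = mpr_fit(treatment_cohort, ("treatment",), ())
        b = mpr_fit(treatment_cohort.iloc[:400], ("treatment",), ())
        with pytest.raises(ValueError):
            mpr_aic_compare(a, b)

    def test_non_ph_favoured_on_mpr_generated_data(self):
        # shape effects are real in the generator, so the AIC comparison
        # should favour the non-PH model in (nearly) every replicate
        wins = 0
        for s in (101, 102, 103, 104, 105):
            frame = generate_cohort(default_treatment_only_config(seed=s))
            ph = mpr_fit(frame, ("treatment",), ())
            full = mpr_fit(frame, ("treatment",), ("treatment",))
            wins += mpr_aic_compare(ph, full) > 0
        assert wins >= 4


class TestStepwise:
    def test_noise_candidates_rejected(self):
        rng = np.random.default_rng(12)
        n = 400
        t = sample_weibull(rng, np.full(n, 0.2), np.full(n, 1.0))
        frame = make_cohort(
            np.minimum(t, 15.0),
            (t <= 15.0).astype(int),
            sex=rng.choice(["male", "female"], n),
            smoking=rng.choice(["never", "current", "ex", "unknown"], n),
        )
        fit = mpr_stepwise(frame, ("sex", "smoking"))
        assert fit.scale_spec.factors == ()
        assert fit.shape_spec.factors == ()

    def test_strong_scale_factor_lands_in_scale(self):
        rng = np.random.default_rng(13)
        n = 600
        sex = rng.choice(["male", "female"], n)
        lam = np.exp(-1.0 + 1.2 * (sex == "female"))
        t = sample_weibull(rng, lam, np.ones(n))
        frame = make_cohort(
            np.minimum(t, 15.0), (t <= 15.0).astype(int),
            sex=sex, smoking=rng.choice(["never", "current", "ex", "unknown"], n),
        )
        fit = mpr_stepwise(frame, ("sex", "smoking"))
        assert "sex" in fit.scale_spec.factors
        assert "sex" not in fit.shape_spec.factors

    def test_stepwise_never_worse_than_null(self, treatment_cohort):
        null = mpr_fit(treatment_cohort)
        fit = mpr_stepwise(treatment_cohort, ("treatment", "sex"))
        assert fit.aic <= null.aic + 1e-9


class TestPrediction:
    def test_zero_coefficients_give_unit_exponential(self):
        t = np.array([0.0, 0.5, 1.0, 2.0])
        np.testing.assert_allclose(survival_function(1.0, 1.0, t), np.exp(-t))

    def test_surgery_profile_one_year(self, treatment_cohort):
        fit = published_treatment_fit(treatment_cohort)
        s = mpr_predict_survival(fit, {"treatment": "surgery"}, [12.0])
        assert s[0] == pytest.approx(SURGERY_ONE_YEAR, abs=1e-6)

    def test_prediction_consistent_with_km_surgery(self, treatment_cohort):
        # model-based surgical 1-year survival sits near the KM estimate of
        # the generated surgical subgroup (consistency, not equality)
        from mprsurv.km import km_estimate

        mask = treatment_cohort["treatment"] == "surgery"
        km = km_estimate(
            treatment_cohort.loc[mask, "time"], treatment_cohort.loc[mask, "event"]
        )
        assert abs(km.survival_at(12.0) - SURGERY_ONE_YEAR) < 0.15

    def test_survival_curve_shape_properties(self, treatment_cohort):
        fit = mpr_fit(treatment_cohort, ("treatment",), ("treatment",))
        t = np.linspace(0, 200, 400)
        s = mpr_predict_survival(fit, {"treatment": "radiotherapy"}, t)
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()
        assert s[-1] < 0.01

    def test_unknown_level_rejected(self, treatment_cohort):
        fit = mpr_fit(treatment_cohort, ("treatment",), ())
        with pytest.raises(DesignError):
            mpr_predict_survival(fit, {"treatment": "homeopathy"}, [1.0])


class TestAdjustedTracks:
    def test_treatment_only_tracks_equal_plain_prediction(self, treatment_cohort):
        fit = mpr_fit(treatment_cohort, ("treatment",), ("treatment",))
        t = np.linspace(0.5, 18, 12)
        tracks = adjusted_tracks(fit, "treatment", t)
        for level in ("palliative", "surgery", "radiotherapy"):
            np.testing.assert_allclose(
                tracks[level],
                mpr_predict_survival(fit, {"treatment": level}, t),
                rtol=1e-12,
            )

    def test_tracks_equal_hand_evaluation_at_mean_design(self, full_cohort):
        fit = mpr_fit(full_cohort, ("treatment", "metastases"), ("treatment",))
        t = np.array([6.0, 12.0])
        tracks = adjusted_tracks(fit, "treatment", t)
        # by-hand linear predictors at the mean metastases dummies
        present = (full_cohort["metastases"] == "present").mean()
        unknown = (full_cohort["metastases"] == "unknown").mean()
        b = fit.scale_coefs
        eta = (
            b["intercept"]
            + b["treatment:surgery"]
            + b["metastases:present"] * present
            + b["metastases:unknown"] * unknown
        )
        nu = fit.shape_coefs["intercept"] + fit.shape_coefs["treatment:surgery"]
        expected = np.exp(-np.exp(eta) * t ** np.exp(nu))
        np.testing.assert_allclose(tracks["surgery"], expected, rtol=1e-12)

    def test_adjustment_shrinks_surgery_benefit(self, full_cohort):
        # case-mix adjustment should attribute part of the crude surgical
        # advantage to covariates
        crude = mpr_fit(full_cohort, ("treatment",), ("treatment",))
        adjusted = mpr_stepwise(full_cohort, tables.SURVIVAL_CANDIDATE_FACTORS)
        t = np.array([12.0])
        sep_crude = (
            adjusted_tracks(crude, "treatment", t)["surgery"]
            - adjusted_tracks(crude, "treatment", t)["palliative"]
        )
        sep_adj = (
            adjusted_tracks(adjusted, "treatment", t)["surgery"]
            - adjusted_tracks(adjusted, "treatment", t)["palliative"]
        )
        assert sep_adj[0] < sep_crude[0]

    def test_missing_factor_rejected(self, treatment_cohort):
        fit = mpr_fit(treatment_cohort, ("treatment",), ())
        with pytest.raises(DesignError):
            adjusted_tracks(fit, "sodium", [1.0])
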