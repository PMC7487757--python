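"""Weibull frailty regression: likelihood pieces, estimation and reporting."""

import dataclasses
import math

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.integrate import quad
from scipy.optimize import approx_fprime
from scipy.special import gamma as gamma_fn

from conftest import mc_marginal_loglik
from sleeptrends.cohort_data import CensorInterval
from sleeptrends.synthetic_cohort import SyntheticConfig, default_truth, generate
from sleeptrends.weibull_frailty import (
    FitResult,
    ModelData,
    WeibullFrailtyParams,
    _nll_and_grad,
    _pack,
    fit,
    hazard_ratios,
    marginal_loglik,
    mean_duration,
    obs_loglik_conditional,
    predict_survival,
    survival,
)

HR_LEVELS = [("birth_cohort", "1900-1919"), ("birth_cohort", "1920-1939"),
             ("birth_cohort", "1940-1957"), ("age_group", "35-54"),
             ("age_group", "55+"), ("gender", "male")]


def weibull_density(t, linpred, k):
    return k * t ** (k - 1) * math.exp(linpred) * math.exp(-t**k * math.exp(linpred))


class TestSurvival:
    def test_exponential_special_case(self):
        assert survival(1.0, 0.0, 1.0) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_starts_at_one(self):
        assert survival(0.0, -3.7, 4.2) == 1.0

    def test_matches_density_integration(self):
        # S(t) equals the integral of the density from t to infinity
        val = survival(7.5, -15.0, 7.0)
        oracle, err = quad(weibull_density, 7.5, np.inf, args=(-15.0, 7.0),
                           limit=200)
        assert abs(val - oracle) < max(1e-8, 10 * err)

    def test_nonincreasing(self):
        t = np.linspace(0, 15, 200)
        s = survival(t, -13.0, 6.0)
        assert np.all(np.diff(s) <= 1e-15)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            survival(1.0, math.nan, 2.0)


class TestConditionalLoglik:
    def test_whole_support_is_certain(self):
        iv = CensorInterval(0.0, math.inf, "left_censored") if False else \
            CensorInterval(1e-9, math.inf, "right_censored")
        # an interval covering (essentially) the whole support has probability ~1
        assert obs_loglik_conditional(iv, 0.0, 1.0) == pytest.approx(-1e-9)

    def test_exponential_right_censored_closed_form(self):
        for L in (0.5, 2.0, 9.75):
            iv = CensorInterval(L, math.inf, "right_censored")
            assert obs_loglik_conditional(iv, 0.0, 1.0) == pytest.approx(-L, abs=1e-14)

    def test_interval_matches_density_integration(self):
        iv = CensorInterval(6.75, 7.25)
        linpred, k = -13.4, 6.8
        val = obs_loglik_conditional(iv, linpred, k)
        mass, err = quad(weibull_density, 6.75, 7.25, args=(linpred, k), limit=200)
        assert val == pytest.approx(math.log(mass), abs=max(1e-8, 10 * err))

    def test_never_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            l = rng.uniform(0, 9)
            iv = CensorInterval(l, l + rng.uniform(0.1, 3))
            assert obs_loglik_conditional(iv, rng.normal(-15, 5), rng.uniform(0.5, 12)) <= 0


class TestMarginalLoglik:
    def test_zero_frailty_reduces_to_fixed_effects(self, truth_params):
        obs, _ = generate(SyntheticConfig(n_pairs=20, seed=2))
        p0 = dataclasses.replace(truth_params, sigma_pair=0.0, sigma_ind=0.0)
        ll = marginal_loglik(obs, p0, quad_order=25)
        md = ModelData(obs)
        lin = p0.beta0 + md.X @ np.asarray(p0.beta)
        direct = sum(
            obs_loglik_conditional(CensorInterval(l, r, k_), float(li), p0.shape)
            for l, r, k_, li in zip(md.left, md.right,
                                    np.where(np.isfinite(md.right),
                                             "interval", "right_censored"),
                                    lin)
        )
        assert ll == pytest.approx(direct, abs=1e-10)

    def test_matches_monte_carlo_oracle(self, truth_params):
        obs, _ = generate(SyntheticConfig(n_pairs=8, seed=4))
        p = dataclasses.replace(truth_params, sigma_pair=0.3, sigma_ind=0.2)
        ll = marginal_loglik(obs, p, quad_order=25)
        mc, se = mc_marginal_loglik(obs, p, n_draws=200_000, seed=99)
        assert abs(ll - mc) < 3 * se

    def test_single_uninformative_observation(self, truth_params):
        obs, _ = generate(SyntheticConfig(n_pairs=1, seed=1))
        one = [dataclasses.replace(obs[0],
                                   interval=CensorInterval(1e-12, math.inf,
                                                           "right_censored"))]
        assert marginal_loglik(one, truth_params, 15) == pytest.approx(0.0, abs=1e-8)

    def test_time_unit_invariance(self, truth_params):
        """Hours -> minutes with beta0 shifted by -k ln 60 leaves the ll unchanged."""
        obs, _ = generate(SyntheticConfig(n_pairs=25, seed=6))
        ll_hours = marginal_loglik(obs, truth_params, 15)
        scaled = [
            dataclasses.replace(
                o, interval=CensorInterval(o.interval.left * 60.0,
                                           o.interval.right * 60.0,
                                           o.interval.kind))
            for o in obs
        ]
        p_min = dataclasses.replace(
            truth_params,
            beta0=truth_params.beta0 - truth_params.shape * math.log(60.0))
        ll_minutes = marginal_loglik(scaled, p_min, 15)
        assert ll_minutes == pytest.approx(ll_hours, abs=1e-8)

    def test_rejects_low_quadrature_order(self, truth_params, small_cohort):
        with pytest.raises(ValueError):
            marginal_loglik(small_cohort[0], truth_params, quad_order=2)


def test_analytic_gradient_matches_finite_differences(truth_params):
    obs, _ = generate(SyntheticConfig(n_pairs=40, seed=3))
    md = ModelData(obs)
    free, fixed, kept = (True, True), (0.0, 0.0), np.arange(6)
    theta = _pack(truth_params, free) + 0.04
    args = (md, free, fixed, 9, kept)
    _, g = _nll_and_grad(theta, *args)
    g_fd = approx_fprime(theta, lambda th: _nll_and_grad(th, *args)[0], 1e-6)
    assert np.max(np.abs(g - g_fd) / (1 + np.abs(g_fd))) < 1e-4


class TestFit:
    def test_recovers_generating_parameters_roughly(self):
        obs, truth = generate(SyntheticConfig(n_pairs=400, seed=21))
        res = fit(obs, quad_order=9)
        assert res.converged
        p_true = WeibullFrailtyParams(**{**truth["params"],
                                         "beta": tuple(truth["params"]["beta"])})
        # the MLE cannot be worse than the generating truth on its own data
        assert res.loglik >= marginal_loglik(obs, p_true, 9) - 1e-6
        assert np.allclose(np.exp(res.params.beta),
                           np.exp(p_true.beta), atol=0.35)
        assert res.n_pairs == 400 and res.n_obs == len(obs)

    def test_quadrature_stability(self):
        obs, _ = generate(SyntheticConfig(n_pairs=150, seed=8))
        r15 = fit(obs, quad_order=15)
        r35 = fit(obs, quad_order=35, init=r15.params)
        diff = np.max(np.abs(np.asarray(r15.params.beta) - np.asarray(r35.params.beta)))
        assert diff < 1e-3

    def test_degenerate_single_category_flagged_not_crash(self):
        obs, _ = generate(SyntheticConfig(n_pairs=15, seed=9))
        degenerate = [
            dataclasses.replace(o, response_category="10 h or more",
                                interval=CensorInterval(9.75, math.inf,
                                                        "right_censored"),
                                gender="female", birth_year=1880,
                                age_group="", birth_cohort="", age_at_survey=-1,
                                wave_year=1975)
            for o in obs if o.wave_year == 1975
        ]
        with pytest.warns(UserWarning):
            res = fit(degenerate, quad_order=9)
        assert not res.converged
        assert "identifiab" in res.message or "boundary" in res.message

    def test_vcov_symmetric_positive_semidefinite(self):
        obs, _ = generate(SyntheticConfig(n_pairs=200, seed=13))
        res = fit(obs, quad_order=9)
        v = res.vcov
        assert v is not None
        assert np.allclose(v, v.T)
        assert np.all(np.linalg.eigvalsh(v) > -1e-10)


class TestHazardRatios:
    def _fit_with(self, beta, se):
        names = ["log_shape", "beta0"] + [f"beta_{f}:{lv}" for f, lv in HR_LEVELS] \
            + ["log_sigma_pair", "log_sigma_ind"]
        vcov = np.diag(np.full(len(names), 1e-4))
        i = names.index("beta_birth_cohort:1940-1957")
        vcov[i, i] = se**2
        params = WeibullFrailtyParams(10.0, -21.0, beta, 0.2, 0.2)
        return FitResult(params=params, loglik=0.0, vcov=vcov, param_names=names,
                         converged=True, message="", n_obs=1, n_subjects=1,
                         n_pairs=1, quad_nodes=15)

    def test_wald_interval_worked_example(self):
        beta = [0.0] * 6
        beta[2] = math.log(1.62)
        table = hazard_ratios(self._fit_with(tuple(beta), 0.0765))
        row = table[(table.level == "1940-1957")].iloc[0]
        assert row.hr == pytest.approx(1.62, abs=1e-12)
        assert row.ci_low == pytest.approx(1.40, abs=0.01)
        assert row.ci_high == pytest.approx(1.88, abs=0.01)

    def test_null_effect_ci_contains_one(self):
        table = hazard_ratios(self._fit_with((0.0,) * 6, 0.05))
        for _, row in table[~table.is_reference].iterrows():
            assert row.ci_low < 1.0 < row.ci_high
            assert row.hr == pytest.approx(1.0)

    def test_reference_rows(self):
        table = hazard_ratios(self._fit_with((0.0,) * 6, 0.05))
        refs = table[table.is_reference]
        assert len(refs) == 3  # one per factor
        assert (refs.hr == 1.0).all()
        assert refs.ci_low.isna().all()

    def test_ci_ordering(self):
        table = hazard_ratios(self._fit_with(tuple([0.3] * 6), 0.1))
        sub = table[~table.is_reference]
        assert ((sub.ci_low <= sub.hr) & (sub.hr <= sub.ci_high)).all()


class TestPredictSurvival:
    COVS = {"birth_cohort": "1940-1957", "age_group": "35-54", "gender": "male"}

    def test_starts_at_one(self, truth_params):
        curve = predict_survival(truth_params, self.COVS, np.array([0.0, 7.0]))
        assert curve.surv[0] == 1.0

    def test_zero_sigma_marginal_equals_conditional(self, truth_params):
        p0 = dataclasses.replace(truth_params, sigma_pair=0.0, sigma_ind=0.0)
        t = np.linspace(0, 14, 57)
        zero = predict_survival(p0, self.COVS, t, frailty="zero")
        marg = predict_survival(p0, self.COVS, t, frailty="marginal")
        assert np.allclose(zero.surv, marg.surv, atol=1e-12)

    def test_marginal_matches_monte_carlo(self, truth_params):
        t = np.linspace(4, 10, 13)
        curve = predict_survival(truth_params, self.COVS, t, frailty="marginal",
                                 quad_order=40)
        rng = np.random.default_rng(17)
        n = 100_000
        u = (rng.normal(0, truth_params.sigma_pair, n)
             + rng.normal(0, truth_params.sigma_ind, n))
        lin = truth_params.beta0 + math.log(1.62) + math.log(1.24) + math.log(1.13)
        draws = np.exp(-t[:, None] ** truth_params.shape * np.exp(lin + u)[None, :])
        mc = draws.mean(axis=1)
        se = draws.std(axis=1) / math.sqrt(n)
        assert np.all(np.abs(curve.surv - mc) < 3 * np.maximum(se, 1e-9))

    def test_monotone_nonincreasing(self, truth_params):
        t = np.linspace(0, 16, 101)
        curve = predict_survival(truth_params, self.COVS, t, frailty="marginal")
        assert np.all(np.diff(curve.surv) <= 1e-15)

    def test_unknown_frailty_mode(self, truth_params):
        with pytest.raises(ValueError):
            predict_survival(truth_params, self.COVS, np.array([1.0]), "bogus")


class TestMeanDuration:
    def test_exponential_mean(self):
        assert mean_duration(WeibullFrailtyParams(1.0, 0.0), {}) == pytest.approx(1.0)

    def test_closed_form_k2(self):
        assert mean_duration(WeibullFrailtyParams(2.0, 0.0), {}) == \
            pytest.approx(gamma_fn(1.5), abs=1e-12)

    def test_matches_survival_integral(self, truth_params):
        covs = {"gender": "male", "age_group": "55+"}
        m = mean_duration(truth_params, covs)
        lin = truth_params.beta0 + math.log(1.23) + math.log(1.13)
        oracle, err = quad(lambda t: survival(t, lin, truth_params.shape),
                           0, np.inf, limit=300)
        assert m == pytest.approx(oracle, abs=max(1e-6, 10 * err))

    def test_higher_hazard_means_shorter_sleep(self, truth_params):
        ref = mean_duration(truth_params, {})
        for factor, level in HR_LEVELS:
            assert mean_duration(truth_params, {factor: level}) < ref


def test_nested_model_collapses_to_pair_frailty_on_single_wave(truth_params):
    """With sigma_ind = 0 and one response per subject, the nested likelihood
    equals a pair-level-only frailty model computed directly."""
    obs, _ = generate(SyntheticConfig(
        n_pairs=40, seed=5,
        wave_specs=(dataclasses.replace(
            SyntheticConfig().wave_specs[1]),)))
    p = dataclasses.replace(truth_params, sigma_ind=0.0)
    ll_nested = marginal_loglik(obs, p, 25)

    # direct pair-only Gauss-Hermite oracle
    x, w = hermgauss(25)
    md = ModelData(obs)
    lin = p.beta0 + md.X @ np.asarray(p.beta)
    total = 0.0
    for ip in range(md.n_pairs):
        s_lo = md.pair_starts[ip]
        s_hi = md.pair_starts[ip + 1] if ip + 1 < md.n_pairs else md.n_subjects
        rows = np.isin(md.obs_subject, np.arange(s_lo, s_hi))
        vals = np.zeros(len(x))
        for j, xx in enumerate(x):
            u = math.sqrt(2) * p.sigma_pair * xx
            vals[j] = sum(
                obs_loglik_conditional(
                    CensorInterval(md.left[i], md.right[i],
                                   "interval" if np.isfinite(md.right[i])
                                   else "right_censored"),
                    float(lin[i] + u), p.shape)
                for i in np.where(rows)[0]
            )
        m = vals.max()
        total += m + math.log(np.sum(w / math.sqrt(math.pi) * np.exp(vals - m)))
    assert ll_nested == pytest.approx(total, abs=1e-6)
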