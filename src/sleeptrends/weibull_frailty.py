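"""Interval-censored Weibull proportional-hazards regression with nested frailty.

Model
-----
The latent sleep duration T of subject *s* in twin pair *p* follows a Weibull
proportional-hazards model

    h(t | x, u) = k t^(k-1) exp(beta0 + x'beta + u_pair + u_ind)
    S(t | x, u) = exp(-t^k exp(beta0 + x'beta + u_pair + u_ind))

with shape k, fixed effects beta for birth cohort, age group and gender, and
mean-zero normal random intercepts on the log-hazard scale: u_pair shared by a
twin pair, u_ind shared by one individual's repeated responses across survey
waves (a nested log-normal frailty).  exp(beta_j) is the hazard ratio of level
j versus its reference: a ratio above 1 means a higher rate of the duration
ending, i.e. shorter sleep.

Each ordinal response contributes S(L) - S(R) for its censoring interval
[L, R); the marginal likelihood integrates the frailties out pair by pair with
nested Gauss-Hermite quadrature.  Estimation is quasi-Newton on the
unconstrained scale (log k, beta, log sigmas) with an analytic gradient;
standard errors come from the inverse numerical Hessian at the optimum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq, minimize
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

from .cohort_data import Observation
from .turnbull import SurvivalCurve

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_PI = 0.5 * math.log(math.pi)

#: Penalised log-probability for intervals whose probability underflows; keeps
#: line searches finite instead of returning -inf.
LOGP_FLOOR = -1e10

#: Non-reference covariate levels, in the fixed design-matrix column order.
#: Reference levels (birth cohort <1900, age 18-34, female) carry no
#: coefficient.
COVARIATE_LEVELS: tuple[tuple[str, str], ...] = (
    ("birth_cohort", "1900-1919"),
    ("birth_cohort", "1920-1939"),
    ("birth_cohort", "1940-1957"),
    ("age_group", "35-54"),
    ("age_group", "55+"),
    ("gender", "male"),
)

REFERENCE_LEVELS: Mapping[str, str] = {
    "birth_cohort": "<1900",
    "age_group": "18-34",
    "gender": "female",
}


class ModelSpecificationError(ValueError):
    """Raised for rank-deficient designs or otherwise unfittable data."""


@dataclass(frozen=True)
class WeibullFrailtyParams:
    """Parameters of the Weibull frailty model.

    ``beta`` is ordered as :data:`COVARIATE_LEVELS` (three birth-cohort
    contrasts, two age-group contrasts, male gender); entries are log hazard
    ratios.  ``sigma_pair`` / ``sigma_ind`` are the standard deviations of the
    pair- and individual-level random intercepts.
    """

    shape: float
    beta0: float
    beta: tuple[float, ...] = (0.0,) * len(COVARIATE_LEVELS)
    sigma_pair: float = 0.0
    sigma_ind: float = 0.0

    def __post_init__(self) -> None:
        if not (self.shape > 0):
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if self.sigma_pair < 0 or self.sigma_ind < 0:
            raise ValueError("frailty standard deviations must be >= 0")
        object.__setattr__(self, "beta", tuple(float(b) for b in self.beta))

    def beta_for(self, factor: str, level: str) -> float:
        if REFERENCE_LEVELS.get(factor) == level:
            return 0.0
        return self.beta[COVARIATE_LEVELS.index((factor, level))]


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, uncertainty and diagnostics.

    ``vcov`` is the covariance of the estimated parameter vector on the
    unconstrained internal scale (log shape, beta0, beta, log sigmas), with
    rows/columns named by ``param_names``.
    """

    params: WeibullFrailtyParams
    loglik: float
    vcov: np.ndarray | None
    param_names: list[str]
    converged: bool
    message: str
    n_obs: int
    n_subjects: int
    n_pairs: int
    quad_nodes: int
    theta: np.ndarray = field(default=None, repr=False)

    def se(self, name: str) -> float:
        if self.vcov is None:
            raise ValueError("fit has no covariance matrix")
        i = self.param_names.index(name)
        return float(np.sqrt(self.vcov[i, i]))


# ---------------------------------------------------------------------------
# data preparation


def design_matrix(observations: Sequence[Observation]) -> np.ndarray:
    """Indicator design matrix with one column per non-reference level."""
    X = np.zeros((len(observations), len(COVARIATE_LEVELS)))
    for j, (factor, level) in enumerate(COVARIATE_LEVELS):
        X[:, j] = [getattr(o, factor) == level for o in observations]
    return X


def covariate_vector(covariates: Mapping[str, str]) -> np.ndarray:
    """Design row for a single covariate pattern given as factor -> level."""
    x = np.zeros(len(COVARIATE_LEVELS))
    for factor, level in covariates.items():
        if REFERENCE_LEVELS.get(factor) == level:
            continue
        try:
            x[COVARIATE_LEVELS.index((factor, level))] = 1.0
        except ValueError:
            raise KeyError(f"unknown level {level!r} for factor {factor!r}")
    return x


class ModelData:
    """Observations rearranged for the nested likelihood.

    Rows are sorted by (pair, subject) so per-subject and per-pair sums reduce
    to contiguous ``np.add.reduceat`` segments.
    """

    def __init__(self, observations: Sequence[Observation]):
        if not observations:
            raise ModelSpecificationError("no observations")
        order = sorted(
            range(len(observations)),
            key=lambda i: (observations[i].pair_id, observations[i].subject_id),
        )
        obs = [observations[i] for i in order]
        self.left = np.array([o.interval.left for o in obs])
        self.right = np.array([o.interval.right for o in obs])
        self.X = design_matrix(obs)
        subj_keys = [(o.pair_id, o.subject_id) for o in obs]
        self.obs_subject = np.zeros(len(obs), dtype=np.intp)
        subj_starts = [0]
        pair_of_subj = []
        for i in range(1, len(obs)):
            if subj_keys[i] != subj_keys[i - 1]:
                subj_starts.append(i)
        self.subj_starts = np.array(subj_starts, dtype=np.intp)
        sidx = np.zeros(len(obs), dtype=np.intp)
        for s, start in enumerate(subj_starts):
            end = subj_starts[s + 1] if s + 1 < len(subj_starts) else len(obs)
            sidx[start:end] = s
            pair_of_subj.append(obs[start].pair_id)
        self.obs_subject = sidx
        pair_starts = [0]
        for s in range(1, len(pair_of_subj)):
            if pair_of_subj[s] != pair_of_subj[s - 1]:
                pair_starts.append(s)
        self.pair_starts = np.array(pair_starts, dtype=np.intp)
        self.subj_pair = np.zeros(len(pair_of_subj), dtype=np.intp)
        for p, start in enumerate(pair_starts):
            end = pair_starts[p + 1] if p + 1 < len(pair_starts) else len(pair_of_subj)
            self.subj_pair[start:end] = p
        self.n_obs = len(obs)
        self.n_subjects = len(subj_starts)
        self.n_pairs = len(pair_starts)
        # precompute logs of the interval bounds; left == 0 and right == inf
        # are masked out of the k-derivative terms
        with np.errstate(divide="ignore"):
            self.log_left = np.where(self.left > 0, np.log(np.maximum(self.left, 1e-300)), 0.0)
            self.finite_right = np.isfinite(self.right)
            self.log_right = np.where(self.finite_right, np.log(np.maximum(self.right, 1e-300)), 0.0)
        self.left_is_zero = self.left == 0.0
        # observations collapse to a few hundred unique (covariates, interval)
        # combinations; the quadrature-grid probabilities are computed once per
        # unique combination and gathered back per observation
        combo = np.column_stack([self.X, self.left, np.nan_to_num(self.right, posinf=-1.0)])
        uniq, self.uid = np.unique(combo, axis=0, return_inverse=True)
        self.uX = uniq[:, : self.X.shape[1]]
        u_left = uniq[:, -2]
        u_right = np.where(uniq[:, -1] < 0, np.inf, uniq[:, -1])
        with np.errstate(divide="ignore"):
            self.u_log_left = np.where(u_left > 0, np.log(np.maximum(u_left, 1e-300)), 0.0)
            self.u_finite_right = np.isfinite(u_right)
            self.u_log_right = np.where(self.u_finite_right,
                                        np.log(np.maximum(u_right, 1e-300)), 0.0)
        self.u_left_zero = u_left == 0.0


def _as_model_data(data) -> ModelData:
    return data if isinstance(data, ModelData) else ModelData(list(data))


# ---------------------------------------------------------------------------
# elementary likelihood pieces


def survival(t, linpred, k):
    """Weibull survival S(t) = exp(-t^k exp(linpred)); vectorised."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(np.asarray(linpred))) or not np.isfinite(k) or k <= 0:
        raise ValueError("linpred must be finite and k > 0")
    out = np.exp(-np.power(t, k) * np.exp(linpred))
    return out if out.shape else float(out)


def obs_loglik_conditional(obs, linpred: float, k: float) -> float:
    """log[S(L) - S(R)] for one response's interval, given the linear predictor.

    Always <= 0; returns :data:`LOGP_FLOOR` when the interval probability
    underflows (the caller decides how to treat that).
    """
    interval = obs.interval if isinstance(obs, Observation) else obs
    left, right = interval.left, interval.right
    a = 0.0 if left == 0 else math.exp(min(k * math.log(left) + linpred, 700.0))
    if math.isinf(right):
        return -a
    b = math.exp(min(k * math.log(right) + linpred, 700.0))
    if b <= a:
        return LOGP_FLOOR
    val = -a + math.log1p(-math.exp(a - b)) if a - b < -1e-17 else LOGP_FLOOR
    return max(val, LOGP_FLOOR)


def _interval_logprob(logL, logR, lzero, rfin, eta: np.ndarray, k: float,
                      want_grad: bool):
    """Vectorised log interval probability and its eta/k derivatives.

    ``eta`` broadcasts over trailing quadrature axes; the bound arrays index
    the first axis.
    """
    extra = (1,) * (eta.ndim - 1)
    logL = logL.reshape(-1, *extra)
    logR = logR.reshape(-1, *extra)
    lzero = lzero.reshape(-1, *extra)
    rfin = rfin.reshape(-1, *extra)

    a = np.where(lzero, 0.0, np.exp(np.minimum(k * logL + eta, 700.0)))
    b = np.where(rfin, np.exp(np.minimum(k * logR + eta, 700.0)), np.inf)
    amb = np.where(rfin, a - b, -np.inf)
    e = np.exp(amb)  # in [0, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = -a + np.log1p(-e)
    bad = ~np.isfinite(logP) | (logP < LOGP_FLOOR)
    logP = np.where(bad, LOGP_FLOOR, logP)
    if not want_grad:
        return logP, None, None
    be = np.where(rfin, b, 0.0) * e
    denom = 1.0 - e
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (-a + be) / denom                      # d logP / d eta
        h = (-a * logL + be * logR) / denom        # d logP / d k
    g = np.where(bad, 0.0, g)
    h = np.where(bad, 0.0, h)
    return logP, g, h


def _segment_sum(arr: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(arr, starts, axis=0)


def _logsumexp_w(logf: np.ndarray, logw: np.ndarray, axis: int) -> np.ndarray:
    shifted = logf + np.reshape(logw, (1,) * axis + (-1,) + (1,) * (logf.ndim - axis - 1))
    m = np.max(shifted, axis=axis, keepdims=True)
    out = m[..., 0] if axis == logf.ndim - 1 else np.squeeze(m, axis=axis)
    return out + np.log(np.sum(np.exp(shifted - m), axis=axis))


def _loglik_core(md: ModelData, k: float, beta0: float, beta: np.ndarray,
                 sigma_pair: float, sigma_ind: float, quad_order: int,
                 want_grad: bool):
    """Marginal log-likelihood (and gradient pieces) by nested Gauss-Hermite.

    Inner level integrates the individual frailty per subject, outer level the
    pair frailty per pair; both use ``quad_order`` nodes.  With both sigmas 0
    every node collapses to u = 0 and the result equals the fixed-effects
    log-likelihood exactly.
    """
    x_nodes, w_nodes = hermgauss(quad_order)
    logw = np.log(w_nodes) - _LOG_SQRT_PI
    up = _SQRT2 * sigma_pair * x_nodes           # (Qp,)
    ui = _SQRT2 * sigma_ind * x_nodes            # (Qi,)
    ulin = beta0 + md.uX @ beta                  # (U,) unique combinations
    ueta = ulin[:, None, None] + up[None, :, None] + ui[None, None, :]
    ulogP, ug, uh = _interval_logprob(md.u_log_left, md.u_log_right,
                                      md.u_left_zero, md.u_finite_right,
                                      ueta, k, want_grad)
    logP = ulogP[md.uid]
    if want_grad:
        g, h = ug[md.uid], uh[md.uid]

    C = _segment_sum(logP, md.subj_starts)       # (S, Qp, Qi)
    A = _logsumexp_w(C, logw, axis=2)            # (S, Qp)
    B = _segment_sum(A, md.pair_starts)          # (P, Qp)
    llp = _logsumexp_w(B, logw, axis=1)          # (P,)
    ll = float(np.sum(llp))
    if not want_grad:
        return ll, None

    # posterior node weights: outer (pair) and inner (subject | pair node)
    pi = np.exp(B + logw[None, :] - llp[:, None])          # (P, Qp)
    rho = np.exp(C + logw[None, None, :] - A[:, :, None])  # (S, Qp, Qi)
    W = pi[md.subj_pair][md.obs_subject][:, :, None] * rho[md.obs_subject]
    Wg = W * g
    Wh = W * h
    grad = {
        "beta0": float(np.sum(Wg)),
        "beta": md.X.T @ np.sum(Wg, axis=(1, 2)),
        "k": float(np.sum(Wh)),
        "sigma_pair": float(_SQRT2 * np.sum(np.sum(Wg, axis=2) * x_nodes[None, :])),
        "sigma_ind": float(_SQRT2 * np.sum(Wg * x_nodes[None, None, :])),
    }
    return ll, grad


def marginal_loglik(data, params: WeibullFrailtyParams, quad_order: int = 25) -> float:
    """Marginal log-likelihood of the data under the nested frailty model.

    ``data`` is a sequence of :class:`Observation` (or a prebuilt
    :class:`ModelData`).  ``quad_order`` is the number of Gauss-Hermite nodes
    per frailty level (>= 3).
    """
    if quad_order < 3:
        raise ValueError("quad_order must be >= 3")
    md = _as_model_data(data)
    ll, _ = _loglik_core(md, params.shape, params.beta0, np.asarray(params.beta),
                         params.sigma_pair, params.sigma_ind, quad_order, False)
    return ll


# ---------------------------------------------------------------------------
# estimation


def _moment_init_shape(md: ModelData) -> tuple[float, float]:
    """Censoring-ignorant moment fit of (k, beta0) from interval midpoints."""
    mid = np.where(md.finite_right, 0.5 * (md.left + md.right), md.left + 0.5)
    mid = np.maximum(mid, 0.25)
    m, s = float(np.mean(mid)), float(np.std(mid))
    if not (s > 1e-6 * m):
        k = 5.0
    else:
        cv = s / m

        def f(k):
            g1 = gamma_fn(1 + 1 / k)
            g2 = gamma_fn(1 + 2 / k)
            return math.sqrt(max(g2 / g1**2 - 1.0, 1e-12)) - cv

        try:
            k = brentq(f, 0.2, 150.0)
        except ValueError:
            k = 1.0 if cv > 1.0 else 20.0
    lam = m / gamma_fn(1 + 1 / k)
    beta0 = -k * math.log(lam)
    return k, beta0


def _pack(params: WeibullFrailtyParams, free_sigmas: tuple[bool, bool]) -> np.ndarray:
    theta = [math.log(params.shape), params.beta0, *params.beta]
    if free_sigmas[0]:
        theta.append(math.log(max(params.sigma_pair, 1e-8)))
    if free_sigmas[1]:
        theta.append(math.log(max(params.sigma_ind, 1e-8)))
    return np.array(theta)


def _unpack(theta: np.ndarray, free_sigmas: tuple[bool, bool],
            fixed: tuple[float, float], n_beta: int) -> WeibullFrailtyParams:
    k = math.exp(theta[0])
    beta0 = theta[1]
    beta = tuple(theta[2:2 + n_beta])
    i = 2 + n_beta
    sp = math.exp(theta[i]) if free_sigmas[0] else fixed[0]
    if free_sigmas[0]:
        i += 1
    si = math.exp(theta[i]) if free_sigmas[1] else fixed[1]
    return WeibullFrailtyParams(k, beta0, beta, sp, si)


def _param_names(free_sigmas: tuple[bool, bool]) -> list[str]:
    names = ["log_shape", "beta0"]
    names += [f"beta_{f}:{lv}" for f, lv in COVARIATE_LEVELS]
    if free_sigmas[0]:
        names.append("log_sigma_pair")
    if free_sigmas[1]:
        names.append("log_sigma_ind")
    return names


def _nll_and_grad(theta, md, free_sigmas, fixed, quad_order, kept_cols):
    n_beta = len(COVARIATE_LEVELS)
    p = _unpack(theta, free_sigmas, fixed, n_beta)
    ll, grad = _loglik_core(md, p.shape, p.beta0, np.asarray(p.beta),
                            p.sigma_pair, p.sigma_ind, quad_order, True)
    gvec = [p.shape * grad["k"], grad["beta0"], *grad["beta"]]
    if free_sigmas[0]:
        gvec.append(p.sigma_pair * grad["sigma_pair"])
    if free_sigmas[1]:
        gvec.append(p.sigma_ind * grad["sigma_ind"])
    g = np.array(gvec)
    # dropped (all-zero) design columns stay pinned at zero
    for j in kept_cols_complement(kept_cols):
        g[2 + j] = 0.0
    return -ll, -g


def kept_cols_complement(kept_cols: np.ndarray) -> np.ndarray:
    all_cols = np.arange(len(COVARIATE_LEVELS))
    return np.setdiff1d(all_cols, kept_cols)


def fit(data, init: WeibullFrailtyParams | None = None, quad_order: int = 25,
        tol: float = 1e-6, max_iter: int = 500,
        fix_sigma_pair: float | None = None,
        fix_sigma_ind: float | None = None) -> FitResult:
    """Maximise the marginal likelihood; deterministic given data and settings.

    Optimisation is quasi-Newton (L-BFGS-B) on the unconstrained scale
    (log k, beta, log sigmas) with the analytic gradient; ``tol`` is the
    projected-gradient tolerance.  ``fix_sigma_pair`` / ``fix_sigma_ind`` pin a
    frailty standard deviation (e.g. to 0) instead of estimating it.  The
    covariance of the estimates is the inverse numerical Hessian at the
    optimum.  Non-convergence and boundary/non-identifiable outcomes are
    flagged in the result, never silently ignored.
    """
    md = _as_model_data(data)
    col_sums = md.X.sum(axis=0)
    # absent levels and levels shared by every observation are inestimable
    kept_cols = np.where((col_sums > 0) & (col_sums < md.n_obs))[0]
    dropped = [COVARIATE_LEVELS[j] for j in np.where((col_sums == 0) | (col_sums == md.n_obs))[0]]
    if dropped:
        warnings.warn(f"covariate levels absent or constant in data, "
                      f"coefficients pinned at 0: {dropped}")
    Xk = np.column_stack([np.ones(md.n_obs), md.X[:, kept_cols]])
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ModelSpecificationError(
            "design matrix is rank deficient (confounded factor levels)"
        )
    n_patterns = len({tuple(r) for r in md.X})
    boundary_note = ""
    if n_patterns < 2 and len(kept_cols) > 0:
        raise ModelSpecificationError("fewer than 2 covariate patterns")
    free_sigmas = (fix_sigma_pair is None, fix_sigma_ind is None)
    fixed = (fix_sigma_pair or 0.0, fix_sigma_ind or 0.0)
    if init is None:
        k0, b00 = _moment_init_shape(md)
        init = WeibullFrailtyParams(k0, b00, (0.0,) * len(COVARIATE_LEVELS),
                                    0.1 if free_sigmas[0] else fixed[0],
                                    0.1 if free_sigmas[1] else fixed[1])
    if len(np.unique(md.uid)) == 1 and len(kept_cols) == 0:
        # every response in one category with no covariate contrasts: the
        # scale parameter runs to the boundary; flag instead of chasing it
        return FitResult(
            params=init, loglik=marginal_loglik(md, init, quad_order),
            vcov=None, param_names=_param_names(free_sigmas), converged=False,
            message="non-identifiable: all responses share one category and "
                    "no covariates vary (boundary maximum)",
            n_obs=md.n_obs, n_subjects=md.n_subjects, n_pairs=md.n_pairs,
            quad_nodes=quad_order, theta=_pack(init, free_sigmas),
        )
    theta0 = _pack(init, free_sigmas)
    args = (md, free_sigmas, fixed, quad_order, kept_cols)
    if quad_order > 7:
        # cheap warm start at low quadrature order, then refine at full order
        coarse_args = (md, free_sigmas, fixed, 5, kept_cols)
        coarse = minimize(_nll_and_grad, theta0, args=coarse_args, jac=True,
                          method="L-BFGS-B",
                          options={"maxiter": max_iter, "gtol": tol * 100,
                                   "ftol": 1e-10, "maxcor": 25})
        theta0 = coarse.x
    res = minimize(_nll_and_grad, theta0, args=args, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12,
                            "maxcor": 25})
    converged = bool(res.success)
    if not converged:
        # L-BFGS-B line searches can give up within rounding error of the
        # optimum; polish with plain BFGS and re-assess the gradient
        polish = minimize(_nll_and_grad, res.x, args=args, jac=True,
                          method="BFGS", options={"maxiter": 100, "gtol": tol})
        if polish.fun <= res.fun:
            res = polish
        converged = bool(res.success)
    theta = res.x
    n_beta = len(COVARIATE_LEVELS)
    params = _unpack(theta, free_sigmas, fixed, n_beta)
    loglik = -float(res.fun)
    names = _param_names(free_sigmas)

    message = str(res.message)
    if not converged:
        nll_f, grad_f = _nll_and_grad(theta, *args)
        if float(np.max(np.abs(grad_f))) <= max(1e-3, 1e-4 * abs(nll_f)):
            converged = True
            message += " (accepted: gradient within relative tolerance)"
    if abs(params.beta0) > 50 or params.shape > 500:
        converged = False
        boundary_note = "; parameter at boundary (possibly non-identifiable data)"
    # exact re-evaluation at the reported optimum (line-search floors aside)
    loglik = marginal_loglik(md, params, quad_order)

    vcov = None
    free_idx = [i for i in range(len(theta))
                if not (2 <= i < 2 + n_beta and (i - 2) in kept_cols_complement(kept_cols))]
    try:
        H = _numerical_hessian(theta, args, free_idx)
        vcov_free = np.linalg.inv(H)
        vcov = np.full((len(theta), len(theta)), np.nan)
        vcov[np.ix_(free_idx, free_idx)] = 0.5 * (vcov_free + vcov_free.T)
    except np.linalg.LinAlgError:
        converged = False
        boundary_note += "; Hessian not invertible"

    return FitResult(
        params=params, loglik=loglik, vcov=vcov, param_names=names,
        converged=converged, message=message + boundary_note,
        n_obs=md.n_obs, n_subjects=md.n_subjects, n_pairs=md.n_pairs,
        quad_nodes=quad_order, theta=theta,
    )


def _numerical_hessian(theta: np.ndarray, args, free_idx) -> np.ndarray:
    """Central finite differences of the analytic gradient of the negative ll."""
    p = len(free_idx)
    H = np.zeros((p, p))
    for a, i in enumerate(free_idx):
        h = 1e-5 * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = _nll_and_grad(tp, *args)
        _, gm = _nll_and_grad(tm, *args)
        H[a, :] = (gp[free_idx] - gm[free_idx]) / (2 * h)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# reporting


def hazard_ratios(fit_result: FitResult, level: float = 0.95):
    """Wald hazard-ratio table with reference rows (hr = 1.00, no CI).

    hr = exp(beta); CI = exp(beta +/- z se) with se from the fit covariance.
    """
    import pandas as pd

    if fit_result.vcov is None:
        raise ValueError("fit has no covariance matrix; cannot form CIs")
    z = norm.ppf(0.5 + level / 2)
    rows = []
    factors: dict[str, list[str]] = {}
    for factor, lv in COVARIATE_LEVELS:
        factors.setdefault(factor, []).append(lv)
    for factor, levels in factors.items():
        rows.append({"factor": factor, "level": REFERENCE_LEVELS[factor],
                     "hr": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                     "is_reference": True})
        for lv in levels:
            b = fit_result.params.beta_for(factor, lv)
            se = fit_result.se(f"beta_{factor}:{lv}")
            rows.append({"factor": factor, "level": lv, "hr": math.exp(b),
                         "ci_low": math.exp(b - z * se),
                         "ci_high": math.exp(b + z * se),
                         "is_reference": False})
    return pd.DataFrame(rows)


def predict_survival(fit_result, covariates: Mapping[str, str],
                     t_grid: np.ndarray, frailty: str = "zero",
                     quad_order: int = 25) -> SurvivalCurve:
    """Model-implied survival curve for one covariate pattern.

    ``frailty="zero"`` plugs in u = 0; ``"marginal"`` integrates the curve over
    both frailty distributions by Gauss-Hermite quadrature (the population
    average curve).
    """
    params = fit_result.params if isinstance(fit_result, FitResult) else fit_result
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be sorted")
    lin = params.beta0 + covariate_vector(covariates) @ np.asarray(params.beta)
    if frailty == "zero":
        s = np.exp(-np.power(t, params.shape) * np.exp(lin))
    elif frailty == "marginal":
        x_nodes, w_nodes = hermgauss(quad_order)
        w = w_nodes / math.sqrt(math.pi)
        u = (_SQRT2 * params.sigma_pair * x_nodes[:, None]
             + _SQRT2 * params.sigma_ind * x_nodes[None, :])
        ww = w[:, None] * w[None, :]
        s = np.einsum(
            "jm,tjm->t", ww,
            np.exp(-np.power(t, params.shape)[:, None, None] * np.exp(lin + u)[None, :, :]),
        )
    else:
        raise ValueError(f"unknown frailty mode {frailty!r}")
    return SurvivalCurve(support=t, surv=s, method=f"weibull_{frailty}")


def mean_duration(params: WeibullFrailtyParams, covariates: Mapping[str, str],
                  frailty: str = "zero") -> float:
    """Model-implied mean duration E[T] = Gamma(1 + 1/k) exp(-linpred/k).

    With ``frailty="zero"`` the frailties are plugged in at 0; ``"marginal"``
    multiplies by the log-normal moment exp((sigma_p^2 + sigma_i^2)/(2 k^2)).
    """
    lin = params.beta0 + covariate_vector(covariates) @ np.asarray(params.beta)
    k = params.shape
    mean = gamma_fn(1 + 1 / k) * math.exp(-lin / k)
    if frailty == "marginal":
        mean *= math.exp((params.sigma_pair**2 + params.sigma_ind**2) / (2 * k**2))
    elif frailty != "zero":
        raise ValueError(f"unknown frailty mode {frailty!r}")
    return float(mean)
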