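"""Nonparametric survival estimation for interval-censored durations.

Two estimators for wave-level survival curves of reported sleep duration:

* :func:`npmle` — the Turnbull nonparametric maximum-likelihood estimator,
  computed by the self-consistency EM algorithm.  Probability mass can only
  live on the "innermost" intervals (maximal intersections of the observation
  intervals); within an innermost interval the NPMLE is undefined and the
  curve is rendered flat-then-drop at the right endpoint.
* :func:`km_midpoint` — the ordinary Kaplan-Meier product-limit estimator
  after reducing finite intervals to their midpoints (right-censored
  categories keep their left bound as a censoring time).

All intervals follow the package-wide half-open [left, right) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .cohort_data import CensorInterval


@dataclass
class SurvivalCurve:
    """A nonincreasing step (or smooth) survival function over duration.

    ``surv[i]`` is the survival probability at ``support[i]`` hours; curves
    start at S(0) = 1.
    """

    support: np.ndarray
    surv: np.ndarray
    method: str
    masses: np.ndarray | None = field(default=None)
    mass_intervals: list[tuple[float, float]] | None = field(default=None)
    converged: bool = True
    n_iter: int = 0
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.support.shape != self.surv.shape:
            raise ValueError("support and surv must have equal length")

    def evaluate(self, t) -> np.ndarray:
        """Step-function evaluation: S(t) = surv at the last support point <= t."""
        idx = np.searchsorted(self.support, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return s if s.shape else float(s)


def _as_bounds(intervals: Iterable[CensorInterval]) -> tuple[np.ndarray, np.ndarray]:
    ivs = list(intervals)
    if not ivs:
        raise ValueError("need at least one interval")
    return (np.array([iv.left for iv in ivs]),
            np.array([iv.right for iv in ivs]))


def turnbull_sets(intervals: Sequence[CensorInterval]) -> list[tuple[float, float]]:
    """Innermost (Turnbull) intervals of a collection of censoring intervals.

    An innermost interval [p, q) takes its left endpoint from some
    observation's left bound, its right endpoint from some observation's right
    bound, and contains no other observation endpoint in its interior.  The
    NPMLE concentrates all probability mass on these sets.
    """
    lefts, rights = _as_bounds(intervals)
    L = np.unique(lefts)
    R = np.unique(rights)
    endpoints = np.unique(np.concatenate([L, R]))
    sets = []
    for p in L:
        # smallest right endpoint strictly above p
        above = R[R > p]
        if above.size == 0:
            continue
        q = above[0]
        inner = endpoints[(endpoints > p) & (endpoints < q)]
        if inner.size == 0:
            sets.append((float(p), float(q)))
    return sorted(set(sets))


def _membership(lefts, rights, sets) -> np.ndarray:
    """alpha[i, k] = 1 if innermost set k is contained in observation i's interval."""
    p = np.array([s[0] for s in sets])
    q = np.array([s[1] for s in sets])
    return ((lefts[:, None] <= p[None, :]) & (q[None, :] <= rights[:, None])).astype(float)


def npmle(intervals: Sequence[CensorInterval], tol: float = 1e-8,
          max_iter: int = 10000) -> SurvivalCurve:
    """Turnbull NPMLE of the survival function by self-consistency EM.

    Starts from uniform mass over the innermost sets; every EM step is
    guaranteed not to decrease the log-likelihood, and the returned masses sum
    to 1.  If ``max_iter`` is reached before the mass change drops below
    ``tol`` the curve is returned with ``converged=False``.
    """
    lefts, rights = _as_bounds(intervals)
    # collapse duplicate observation intervals to weighted uniques
    bounds = np.column_stack([lefts, rights])
    uniq, counts = np.unique(bounds, axis=0, return_counts=True)
    lefts_u, rights_u = uniq[:, 0], uniq[:, 1]
    n = counts.sum()

    sets = turnbull_sets(intervals)
    alpha = _membership(lefts_u, rights_u, sets)  # (I, K)
    K = len(sets)
    p = np.full(K, 1.0 / K)
    converged = False
    loglik = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        denom = alpha @ p                       # (I,)
        loglik = float(counts @ np.log(denom))
        expected = alpha * p[None, :] / denom[:, None]  # E-step memberships
        p_new = counts @ expected / n           # M-step
        if float(np.max(np.abs(p_new - p))) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    loglik = float(counts @ np.log(alpha @ p))

    # survival steps: flat within an innermost set, drop at its right endpoint
    drop_at = np.array([s[1] for s in sets])
    support = np.concatenate([[0.0], drop_at])
    surv = np.concatenate([[1.0], 1.0 - np.cumsum(p)])
    surv = np.clip(surv, 0.0, 1.0)
    finite = np.isfinite(support)
    return SurvivalCurve(
        support=support[finite], surv=surv[finite], method="turnbull",
        masses=p, mass_intervals=sets, converged=converged, n_iter=it,
        loglik=loglik,
    )


def km_midpoint(intervals: Sequence[CensorInterval]) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) curve on midpoint-reduced data.

    Finite intervals (including the left-censored lowest category) are
    replaced by their midpoints as exact event times; right-censored
    observations enter as censored at their left bound.
    """
    from lifelines import KaplanMeierFitter

    lefts, rights = _as_bounds(intervals)
    finite = np.isfinite(rights)
    durations = np.where(finite, 0.5 * (lefts + rights), lefts)
    observed = finite.astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    support = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if support[0] != 0.0:
        support = np.concatenate([[0.0], support])
        surv = np.concatenate([[1.0], surv])
    return SurvivalCurve(support=support, surv=surv, method="km_midpoint")
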