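"""Centralized Cox proportional hazards fit (Breslow ties) and comparison metrics.

This is the baseline every federated fit is compared against, so the tie
convention (Breslow), the initialization (beta = 0) and the stopping rule
(gradient max-norm) are pinned down here rather than delegated: the federated
coefficient updates are derived from the Breslow-form partial likelihood and
the equivalence checks are only exact if the baseline matches it.

The negative log partial likelihood minimized here is

    l(beta) = - sum_t [ sum_{n in E_t} x_n' beta  -  d_t log sum_{m in R_t} exp(x_m' beta) ]

with E_t / R_t the event and risk sets of :class:`~fedcox.datasets.EventStructure`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .datasets import EventStructure, SurvivalDataset, build_event_structure

__all__ = [
    "CoxFit",
    "breslow_objective",
    "fit_cox_newton_raphson",
    "concordance_index",
    "coefficient_metrics",
    "BreslowCoxPH",
    "SeparationError",
    "check_survival_y",
]

_SEPARATION_BOUND = 50.0


class SeparationError(RuntimeError):
    """Monotone partial likelihood: no finite maximizer (separated data)."""


@dataclass(frozen=True)
class CoxFit:
    """Result of a centralized Newton–Raphson Cox fit."""

    beta: np.ndarray
    neg_log_partial_likelihood: float
    iterations: int
    converged: bool
    gradient_norm: float
    standard_errors: np.ndarray


def breslow_objective(beta: np.ndarray, ds: SurvivalDataset,
                      es: EventStructure) -> tuple[float, np.ndarray, np.ndarray]:
    """Negative Breslow log partial likelihood with exact gradient and Hessian.

    Returns ``(value, gradient, hessian)``; the Hessian is symmetric positive
    semidefinite. Overflow is guarded by subtracting the max linear predictor
    inside the log-sum-exp.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(~np.isfinite(beta)):
        raise ValueError("beta must be finite")
    X = ds.covariates
    eta = X @ beta
    shift = eta.max()
    e = np.exp(eta - shift)

    # Risk sets are nested (R_t = {time >= t}), so all log-sum-exp terms are
    # suffix sums in ascending-time order: O(N M^2) instead of O(T N M^2).
    order = np.argsort(ds.times, kind="stable")
    ta = ds.times[order]
    Xa = X[order]
    ea = e[order]
    suf_e = np.cumsum(ea[::-1])[::-1]
    suf_ex = np.cumsum((ea[:, None] * Xa)[::-1], axis=0)[::-1]
    suf_exx = np.cumsum((ea[:, None, None] * Xa[:, :, None] * Xa[:, None, :])[::-1],
                        axis=0)[::-1]
    idx = np.searchsorted(ta, es.distinct_times, side="left")
    d = es.event_counts.astype(float)
    S0 = suf_e[idx]
    S1 = suf_ex[idx]
    S2 = suf_exx[idx]
    mu = S1 / S0[:, None]

    ev = es.event_sets.any(axis=0)
    value = -(eta[ev].sum() - d @ (np.log(S0) + shift))
    grad = -(X[ev].sum(axis=0) - d @ mu)
    hess = (np.einsum("t,tij->ij", d / S0, S2)
            - np.einsum("t,ti,tj->ij", d, mu, mu))
    return float(value), grad, hess


def fit_cox_newton_raphson(ds: SurvivalDataset, tol: float = 1e-5,
                           max_iter: int = 100) -> CoxFit:
    """Newton–Raphson with step-halving from beta = 0.

    Stops when the gradient max-norm drops to ``tol`` (default reproduces the
    conventional 1e-5 precision) or after ``max_iter`` Newton steps.

    Raises
    ------
    ValueError
        No events, or a constant covariate column.
    SeparationError
        The coefficient norm runs away (monotone likelihood).
    np.linalg.LinAlgError
        Singular Hessian (collinear features).
    """
    es = build_event_structure(ds)
    if np.any(ds.covariates.std(axis=0) == 0):
        raise ValueError("constant covariate column: coefficient not identifiable")
    beta = np.zeros(ds.n_features)
    value, grad, hess = breslow_objective(beta, ds, es)
    it = 0
    while it < max_iter and np.abs(grad).max() > tol:
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular Hessian (collinear features?): {exc}") from exc
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            new_value, new_grad, new_hess = breslow_objective(cand, ds, es)
            # tiny slack keeps full Newton steps acceptable at float resolution
            if new_value <= value + 1e-12 * (1.0 + abs(value)):
                break
            scale *= 0.5
        beta, value, grad, hess = cand, new_value, new_grad, new_hess
        it += 1
        if np.abs(beta).max() > _SEPARATION_BOUND:
            raise SeparationError(
                "coefficients exceed the separation guard: the partial likelihood "
                "appears monotone (separated data), no finite maximizer")
    gnorm = float(np.abs(grad).max())
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return CoxFit(beta=beta, neg_log_partial_likelihood=value, iterations=it,
                  converged=gnorm <= tol, gradient_norm=gnorm, standard_errors=se)


def concordance_index(risk: np.ndarray, times: np.ndarray,
                      events: np.ndarray) -> float:
    """Harrell's c-index for right-censored data.

    A pair is comparable when the earlier observed time is an event and the two
    times differ; it is concordant when the subject with the earlier event has
    the higher risk score; tied risk scores count 0.5. Returns 0.5 when no pair
    is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if not (risk.shape == times.shape == events.shape):
        raise ValueError("risk, times and events must have equal length")
    if risk.size < 2:
        raise ValueError("need at least two subjects")
    # comparable[i, j]: t_i < t_j and subject i had an event
    comparable = (times[:, None] < times[None, :]) & (events[:, None] == 1)
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    n_comp = comparable.sum()
    if n_comp == 0:
        return 0.5
    score = (comparable & higher).sum() + 0.5 * (comparable & tied).sum()
    return float(score / n_comp)


def coefficient_metrics(beta_a: np.ndarray, beta_b: np.ndarray) -> tuple[float, float, float]:
    """Return (mse, sad, mad) between two coefficient vectors.

    mse = mean squared difference, sad = sum of absolute differences,
    mad = maximum absolute difference.
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coefficient vectors must have equal length")
    d = a - b
    return float(np.mean(d ** 2)), float(np.abs(d).sum()), float(np.abs(d).max())


def check_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a survival outcome to (times, events).

    Accepts a structured array with event/time fields (scikit-survival style),
    a (times, events) tuple, or an (N, 2) array with columns [time, event].
    """
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        tname = next(n for n in names if "time" in n.lower())
        ename = next(n for n in names if n != tname)
        return np.asarray(y[tname], dtype=float), np.asarray(y[ename]).astype(np.int8)
    if isinstance(y, tuple) and len(y) == 2:
        return (np.asarray(y[0], dtype=float),
                np.asarray(y[1]).astype(np.int8))
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1].astype(np.int8)
    raise ValueError("y must be a structured array, a (times, events) tuple, "
                     "or an (N, 2) array of [time, event]")


class BreslowCoxPH(BaseEstimator):
    """Cox proportional hazards regression with Breslow tie handling.

    Plain Newton–Raphson maximum partial likelihood; used as the centralized
    baseline for federated equivalence experiments.

    Parameters
    ----------
    tol : float, default=1e-5
        Convergence threshold on the gradient max-norm.
    max_iter : int, default=100
        Newton iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (M,)
        Fitted log hazard ratios.
    standard_errors_ : ndarray of shape (M,)
        From the inverse observed information.
    n_iter_ : int
    converged_ : bool
    neg_log_likelihood_ : float
    """

    def __init__(self, tol: float = 1e-5, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        times, events = check_survival_y(y)
        ds = SurvivalDataset(times=times, events=events, covariates=X,
                             feature_names=tuple(f"x{j + 1}" for j in range(X.shape[1])))
        res = fit_cox_newton_raphson(ds, tol=self.tol, max_iter=self.max_iter)
        self.coef_ = res.beta
        self.standard_errors_ = res.standard_errors
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.neg_log_likelihood_ = res.neg_log_partial_likelihood
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear predictor (risk score) x' beta."""
        return np.asarray(X, dtype=float) @ self.coef_

    def score(self, X, y):
        """Harrell's c-index of the fitted risk scores on (X, y)."""
        times, events = check_survival_y(y)
        return concordance_index(self.predict(X), times, events)
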