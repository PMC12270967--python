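"""Federated Cox solver: consensus ADMM over vertically partitioned covariates.

Each party k holds a covariate block X_k and a coefficient block beta_k; the
aggregator holds the outcome. Writing sigma_nk = x_nk' beta_k, the Breslow
partial likelihood couples parties only through the total linear predictor
sum_k sigma_nk, so the problem decomposes with consensus copies z_nk and duals
gamma_nk under penalty rho:

* party update (closed form, exact minimizer of the local quadratic subproblem):

      beta_k = [rho sum_n x_nk x_nk']^-1 [ sum_n (rho z_nk - gamma_nk) x_nk + sum_t u_kt ]

  where u_kt = sum_{n in E_t} x_nk is the per-event-time covariate sum. The
  event sets E_t live only at the aggregator, so u_kt is obtained through the
  secure masked-sum protocol once at preparation and cached — it never changes
  across iterations, so no protocol traffic occurs after preparation.

* aggregator update: with sigma_bar/gamma_bar the per-record means over
  parties, the consensus mean z_bar minimizes

      F(z_bar) = sum_t d_t log sum_{m in R_t} exp(K z_bar_m)
                 + (K rho / 2) sum_n (z_bar_n - sigma_bar_n - gamma_bar_n / rho)^2

  by damped Newton-Raphson on the N x N system, then per-party copies are

      z_nk = z_bar_n + (sigma_nk - sigma_bar_n) + (gamma_nk - gamma_bar_n) / rho

  (eliminating the per-party variables from the exact z-subproblem).

* dual ascent, mirrored at party and aggregator:  gamma_nk += rho (sigma_nk - z_nk).

At a fixed point sigma_nk = z_nk for all (n, k) and the concatenated beta is a
stationary point of the centralized Breslow partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .central import breslow_objective, check_survival_y, concordance_index
from .datasets import (EventStructure, SurvivalDataset, VerticalSplit,
                       build_event_structure, partition_vertically)
from .secure import (DEFAULT_MASK_RANGE, FixedPointCodec,
                     secure_masked_sum_with_transcript)

__all__ = [
    "PartyState",
    "AggregatorState",
    "FederatedFit",
    "make_party",
    "make_aggregator",
    "prepare_u",
    "party_beta_update",
    "party_sigma",
    "server_z_update",
    "distribute_z",
    "dual_update",
    "run_vertical_cox",
    "predict_linear_predictor",
    "VerticalFederatedCoxPH",
]

_GRAM_COND_LIMIT = 1e12


@dataclass
class PartyState:
    """One institution: its covariate block and ADMM variables. Holds no outcome."""

    index: int
    X: np.ndarray                      # (N, M_k)
    rho: float
    beta: np.ndarray                   # (M_k,)
    z: np.ndarray                      # (N,) consensus copies z_nk
    gamma: np.ndarray                  # (N,) duals gamma_nk
    gram_inverse: np.ndarray           # (rho * X'X)^-1
    u: np.ndarray | None = None        # (T, M_k), cached at preparation
    sum_u: np.ndarray | None = None    # (M_k,)
    prepared: bool = False

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def make_party(index: int, X: np.ndarray, rho: float) -> PartyState:
    """Initialize a party with beta = z = gamma = 0 and a cached Gram inverse."""
    X = np.asarray(X, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be positive")
    gram = X.T @ X
    if X.shape[1] > 0 and np.linalg.cond(gram) > _GRAM_COND_LIMIT:
        raise ValueError(
            f"party {index}: local Gram matrix is singular or near-singular "
            "(collinear or constant features)")
    return PartyState(index=index, X=X, rho=rho,
                      beta=np.zeros(X.shape[1]), z=np.zeros(X.shape[0]),
                      gamma=np.zeros(X.shape[0]),
                      gram_inverse=np.linalg.inv(rho * gram))


@dataclass
class AggregatorState:
    """The outcome-holding server: event structure, consensus state, dual mirror."""

    es: EventStructure
    times: np.ndarray
    events: np.ndarray
    rho: float
    n_parties: int
    sigma: np.ndarray                  # (N, K) reported sigma_nk
    gamma: np.ndarray                  # (N, K) server mirror of duals
    z_bar: np.ndarray                  # (N,)
    # sorted-order helpers for the nested-risk-set Newton solve
    _order: np.ndarray = field(repr=False, default=None)
    _idx: np.ndarray = field(repr=False, default=None)

    @property
    def sigma_bar(self) -> np.ndarray:
        return self.sigma.mean(axis=1)

    @property
    def gamma_bar(self) -> np.ndarray:
        return self.gamma.mean(axis=1)


def make_aggregator(times: np.ndarray, events: np.ndarray, n_parties: int,
                    rho: float) -> AggregatorState:
    ds_min = SurvivalDataset(times=times, events=events,
                             covariates=np.zeros((len(times), 1)),
                             feature_names=("_",))
    es = build_event_structure(ds_min)
    n = len(times)
    order = np.argsort(times, kind="stable")
    idx = np.searchsorted(times[order], es.distinct_times, side="left")
    return AggregatorState(es=es, times=np.asarray(times, float),
                           events=np.asarray(events), rho=rho, n_parties=n_parties,
                           sigma=np.zeros((n, n_parties)),
                           gamma=np.zeros((n, n_parties)), z_bar=np.zeros(n),
                           _order=order, _idx=idx)


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def prepare_u(party: PartyState, agg: AggregatorState, codec: FixedPointCodec,
              commodity_seed: int = 0, mask_range: int = DEFAULT_MASK_RANGE,
              bus=None, commodity_role: str = "commodity") -> PartyState:
    """One-time secure preparation of u_kt for every event time t and local feature j.

    The party plays Alice (its encoded covariate column), the aggregator plays
    Bob (the raw Boolean event vector E_t), and another institution plays the
    commodity server. Exactly T * M_k protocol runs occur, each moving 4N
    vector elements; the aggregator reveals its share V_2 (a scalar) so the
    party can reconstruct u_ktj. Calling this twice on the same party raises:
    u_k is computed once and frozen.
    """
    if party.prepared:
        raise RuntimeError(
            f"party {party.index}: u_k already prepared; it is computed once "
            "and stays constant over iterations")
    T = agg.es.n_times
    mk = party.n_features
    n = party.X.shape[0]
    u = np.empty((T, mk))
    party_role = f"party-{party.index}"
    for t in range(T):
        e_t = agg.es.event_sets[t].astype(np.int64)
        for j in range(mk):
            run_seed = _derive_seed(commodity_seed, party.index, t, j)
            value, transcript = secure_masked_sum_with_transcript(
                party.X[:, j], e_t, codec, commodity_seed=run_seed,
                mask_range=mask_range)
            u[t, j] = value
            if bus is not None:
                bus.record(commodity_role, party_role, n, "vector", "preparation")
                bus.record(commodity_role, "aggregator", n, "vector", "preparation")
                bus.record(party_role, "aggregator", n, "vector", "preparation")
                bus.record("aggregator", party_role, n, "vector", "preparation")
                # Standalone scalars (r_a, r_b, Bob's combined message, revealed
                # V_2) are logged but excluded from the vector-element accounting.
                bus.record(commodity_role, party_role, 1, "scalar", "preparation")
                bus.record(commodity_role, "aggregator", 1, "scalar", "preparation")
                bus.record("aggregator", party_role, 2, "scalar", "preparation")
    party.u = u
    party.sum_u = u.sum(axis=0)
    party.prepared = True
    return party


def party_beta_update(party: PartyState, rho: float) -> np.ndarray:
    """Closed-form minimizer of the local ADMM subproblem (see module docstring)."""
    if party.sum_u is None:
        raise RuntimeError("prepare_u must run before beta updates")
    rhs = party.X.T @ (rho * party.z - party.gamma) + party.sum_u
    beta = party.gram_inverse @ rhs
    if np.any(~np.isfinite(beta)):
        raise FloatingPointError("non-finite beta in party update")
    party.beta = beta
    return beta


def party_sigma(party: PartyState) -> np.ndarray:
    """Per-record local linear predictor sigma_nk = x_nk' beta_k."""
    return party.X @ party.beta


def _f_pieces(agg: AggregatorState, z_bar: np.ndarray, v: np.ndarray,
              want_hessian: bool):
    """Value, gradient and (optionally) Hessian of F at z_bar, via suffix sums."""
    K = agg.n_parties
    rho = agg.rho
    order = agg._order
    idx = agg._idx
    d = agg.es.event_counts.astype(float)
    s = K * z_bar
    shift = s.max()
    ea = np.exp(s[order] - shift)
    suf = np.cumsum(ea[::-1])[::-1]
    S0 = suf[idx]
    resid = z_bar - v
    value = float(d @ (np.log(S0) + shift) + 0.5 * K * rho * (resid @ resid))

    n = z_bar.size
    contrib = np.zeros(n)
    contrib[idx] += d / S0
    r = np.cumsum(contrib)
    grad_sorted = K * ea * r
    grad = np.empty(n)
    grad[order] = grad_sorted
    grad += K * rho * resid
    if not want_hessian:
        return value, grad, None

    contrib2 = np.zeros(n)
    contrib2[idx] += d / S0 ** 2
    c2 = np.cumsum(contrib2)
    # H_sorted = K^2 [diag(ea * r) - (ea ea') * min(c2_p, c2_q)] + K rho I
    H = -(K * K) * np.outer(ea, ea) * np.minimum.outer(c2, c2)
    diag = H.ravel()[:: n + 1]
    diag += (K * K) * ea * r + K * rho
    return value, grad, (H, order)


def server_z_update(agg: AggregatorState, tol: float = 1e-5,
                    max_inner: int = 100) -> tuple[np.ndarray, dict]:
    """Damped Newton-Raphson minimization of F(z_bar), warm-started.

    Returns the minimizer and diagnostics (inner iterations, gradient norm,
    convergence flag). The Hessian is the exact N x N second derivative,
    assembled in O(N^2) via the nested-risk-set structure.
    """
    v = agg.sigma_bar + agg.gamma_bar / agg.rho
    z_bar = agg.z_bar.copy()
    value, grad, hess = _f_pieces(agg, z_bar, v, want_hessian=True)
    inner = 0
    # At least one Newton step per call: the warm start may already satisfy
    # the tolerance, but a single quadratic-convergence step from there drives
    # the consensus point far deeper, which the outer loop needs to close the
    # primal residual below the inner tolerance.
    while inner < max_inner and (inner == 0 or np.abs(grad).max() > tol):
        H, order = hess
        step_sorted = np.linalg.solve(H, grad[order])
        step = np.empty_like(step_sorted)
        step[order] = step_sorted
        scale = 1.0
        for _ in range(30):
            cand = z_bar - scale * step
            new_value, new_grad, new_hess = _f_pieces(agg, cand, v, want_hessian=True)
            if np.isfinite(new_value) and new_value <= value + 1e-12 * (1.0 + abs(value)):
                break
            scale *= 0.5
        z_bar, value, grad, hess = cand, new_value, new_grad, new_hess
        inner += 1
    if np.any(~np.isfinite(z_bar)):
        raise FloatingPointError("non-finite consensus update")
    gnorm = float(np.abs(grad).max())
    agg.z_bar = z_bar
    return z_bar, {"inner_iterations": inner, "gradient_norm": gnorm,
                   "converged": gnorm <= tol}


def distribute_z(agg: AggregatorState, z_bar: np.ndarray) -> np.ndarray:
    """Per-party consensus copies z_nk; their mean over k equals z_bar exactly."""
    if agg.rho <= 0:
        raise ValueError("rho must be positive")
    dev_sigma = agg.sigma - agg.sigma_bar[:, None]
    dev_gamma = (agg.gamma - agg.gamma_bar[:, None]) / agg.rho
    return z_bar[:, None] + dev_sigma + dev_gamma


def dual_update(gamma: np.ndarray, sigma: np.ndarray, z: np.ndarray,
                rho: float) -> np.ndarray:
    """Dual ascent gamma += rho (sigma - z), identical at party and aggregator."""
    gamma = np.asarray(gamma, float)
    sigma = np.asarray(sigma, float)
    z = np.asarray(z, float)
    if not (gamma.shape == sigma.shape == z.shape):
        raise ValueError("gamma, sigma, z must have equal shape")
    return gamma + rho * (sigma - z)


@dataclass
class FederatedFit:
    """Result of a federated run: concatenated coefficients plus diagnostics."""

    beta: np.ndarray                   # party blocks concatenated in split order
    block_sizes: tuple[int, ...]
    column_order: np.ndarray           # original column index per beta position
    iterations_run: int
    primal_residual: float
    trajectory: list[dict]
    parties: list[PartyState] = field(repr=False, default_factory=list)
    aggregator: AggregatorState | None = field(repr=False, default=None)

    @property
    def beta_original_order(self) -> np.ndarray:
        out = np.empty_like(self.beta)
        out[self.column_order] = self.beta
        return out

    def beta_blocks(self) -> list[np.ndarray]:
        out, start = [], 0
        for size in self.block_sizes:
            out.append(self.beta[start:start + size])
            start += size
        return out


def _commodity_for(k: int, n_parties: int) -> str:
    """Role rotation: the next institution serves as the commodity server.

    With a single party no other institution exists, so a dedicated neutral
    commodity process stands in (flagged in the role name).
    """
    if n_parties >= 2:
        return f"party-{(k + 1) % n_parties}"
    return "commodity-neutral"


def run_vertical_cox(split: VerticalSplit, rho: float = 0.25,
                     max_iter: int = 500, inner_tol: float = 1e-5,
                     precision: int = 5, seed: int = 0,
                     stop_tol: float | None = None,
                     mask_range: int = DEFAULT_MASK_RANGE,
                     bus=None, record_objective: bool = True) -> FederatedFit:
    """Run the full federated solve on an in-process simulation of all roles.

    Preparation (secure u_kt for every party, commodity roles rotating) is
    followed by ``max_iter`` ADMM iterations: beta updates -> sigma reports ->
    consensus Newton solve -> z/gamma_bar/sigma_bar distribution -> mirrored
    dual updates. Stops early only if ``stop_tol`` is set and the primal
    residual max|sigma_nk - z_nk| falls below it.
    """
    times, events = split.outcome_view
    K = split.n_parties
    codec = FixedPointCodec(precision=precision)
    agg = make_aggregator(times, events, K, rho)
    parties = [make_party(k, split.party_matrices[k], rho) for k in range(K)]
    for k, party in enumerate(parties):
        prepare_u(party, agg, codec, commodity_seed=seed, mask_range=mask_range,
                  bus=bus, commodity_role=_commodity_for(k, K))

    full_ds = None
    es_full = None
    if record_objective:
        X_full = np.concatenate(split.party_matrices, axis=1)
        full_ds = SurvivalDataset(times=times, events=events, covariates=X_full,
                                  feature_names=tuple(f"c{j}" for j in range(X_full.shape[1])))
        es_full = build_event_structure(full_ds)

    n = len(times)
    trajectory: list[dict] = []
    primal_residual = float("inf")
    it = 0
    for it in range(1, max_iter + 1):
        for k, party in enumerate(parties):
            party_beta_update(party, rho)
            sig = party_sigma(party)
            agg.sigma[:, k] = sig                       # party -> aggregator
            if bus is not None:
                bus.record(f"party-{k}", "aggregator", n, "vector", "iteration")
        z_bar, info = server_z_update(agg, tol=inner_tol)
        z_parts = distribute_z(agg, z_bar)
        gamma_bar = agg.gamma_bar
        sigma_bar = agg.sigma_bar
        for k, party in enumerate(parties):             # aggregator -> party
            party.z = z_parts[:, k]
            if bus is not None:
                bus.record("aggregator", f"party-{k}", n, "vector", "iteration")  # z_nk
                bus.record("aggregator", f"party-{k}", n, "vector", "iteration")  # gamma_bar
                bus.record("aggregator", f"party-{k}", n, "vector", "iteration")  # sigma_bar
            party.gamma = dual_update(party.gamma, agg.sigma[:, k], party.z, rho)
        agg.gamma = dual_update(agg.gamma, agg.sigma, z_parts, rho)

        primal_residual = float(np.abs(agg.sigma - z_parts).max())
        entry = {"iteration": it, "primal_residual": primal_residual, **info}
        if record_objective:
            beta_cat = np.concatenate([p.beta for p in parties])
            entry["objective"] = breslow_objective(beta_cat, full_ds, es_full)[0]
        trajectory.append(entry)
        if stop_tol is not None and primal_residual <= stop_tol:
            break

    beta = np.concatenate([p.beta for p in parties])
    return FederatedFit(beta=beta, block_sizes=split.block_sizes,
                        column_order=split.column_order,
                        iterations_run=it if max_iter > 0 else 0,
                        primal_residual=primal_residual if max_iter > 0 else 0.0,
                        trajectory=trajectory, parties=parties, aggregator=agg)


def predict_linear_predictor(fit: FederatedFit,
                             party_rows: Sequence[np.ndarray]) -> float:
    """Cox risk score sum_k x_k' beta_k for one subject split across parties."""
    blocks = fit.beta_blocks()
    if len(party_rows) != len(blocks):
        raise ValueError("expected one feature block per party")
    total = 0.0
    for x_k, b_k in zip(party_rows, blocks):
        x_k = np.asarray(x_k, dtype=float)
        if x_k.shape != b_k.shape:
            raise ValueError(
                f"feature block of shape {x_k.shape} does not match "
                f"coefficient block of shape {b_k.shape}")
        total += float(x_k @ b_k)
    return total


class VerticalFederatedCoxPH(BaseEstimator):
    """Cox proportional hazards fit over vertically partitioned covariates.

    Simulates all federation roles in one process: covariate columns are split
    into per-party blocks, the outcome is held only by the aggregator role, and
    the per-event-time covariate sums the party updates need are obtained
    through the secure fixed-point scalar-product protocol at preparation.
    Converges to the centralized Breslow Cox solution as iterations grow.

    Parameters
    ----------
    n_parties : int, default=2
        Number of institutions (ignored when ``feature_blocks`` is given).
    feature_blocks : sequence of sequences of int, optional
        Explicit column indices per party; default is round-robin.
    rho : float, default=0.25
        ADMM penalty parameter.
    max_iter : int, default=500
        Outer ADMM iterations (the conventional fixed budget).
    inner_tol : float, default=1e-5
        Gradient tolerance of the aggregator's Newton solve.
    precision : int, default=5
        Decimal digits of the fixed-point protocol encoding.
    stop_tol : float or None, default=None
        Optional early stop on the primal residual.
    random_state : int, default=0
        Seeds all protocol randomness.

    Attributes
    ----------
    coef_ : ndarray of shape (M,)
        Coefficients in the original column order.
    n_iter_ : int
    primal_residual_ : float
    history_ : list of dict
        Per-iteration diagnostics.
    fit_result_ : FederatedFit
    """

    def __init__(self, n_parties: int = 2, feature_blocks=None, rho: float = 0.25,
                 max_iter: int = 500, inner_tol: float = 1e-5, precision: int = 5,
                 stop_tol: float | None = None, mask_range: int = DEFAULT_MASK_RANGE,
                 random_state: int = 0):
        self.n_parties = n_parties
        self.feature_blocks = feature_blocks
        self.rho = rho
        self.max_iter = max_iter
        self.inner_tol = inner_tol
        self.precision = precision
        self.stop_tol = stop_tol
        self.mask_range = mask_range
        self.random_state = random_state

    def fit(self, X, y, bus=None):
        X = np.asarray(X, dtype=float)
        times, events = check_survival_y(y)
        ds = SurvivalDataset(times=times, events=events, covariates=X,
                             feature_names=tuple(f"x{j + 1}" for j in range(X.shape[1])))
        k = len(self.feature_blocks) if self.feature_blocks is not None else self.n_parties
        split = partition_vertically(ds, k, blocks=self.feature_blocks)
        fit = run_vertical_cox(split, rho=self.rho, max_iter=self.max_iter,
                               inner_tol=self.inner_tol, precision=self.precision,
                               seed=self.random_state, stop_tol=self.stop_tol,
                               mask_range=self.mask_range, bus=bus)
        self.fit_result_ = fit
        self.coef_ = fit.beta_original_order
        self.n_iter_ = fit.iterations_run
        self.primal_residual_ = fit.primal_residual
        self.history_ = fit.trajectory
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Linear predictor (risk score) x' beta in original column order."""
        return np.asarray(X, dtype=float) @ self.coef_

    def score(self, X, y):
        """Harrell's c-index of the federated risk scores on (X, y)."""
        times, events = check_survival_y(y)
        return concordance_index(self.predict(X), times, events)
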