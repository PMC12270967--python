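"""Survival data containers, synthetic generation, vertical partitioning and CSV I/O.

The survival outcome is a pair (observed time, event indicator) per subject; the
covariates form an N x M matrix. For federated experiments the covariate columns
are split into per-party blocks while the outcome stays with the aggregator role
(:class:`VerticalSplit`). :class:`EventStructure` pre-computes, for every distinct
event time, the event set E_t (subjects with an observed event exactly at t) and
the risk set R_t (subjects still under observation at t), which together define
the Breslow partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SurvivalDataset",
    "EventStructure",
    "VerticalSplit",
    "generate_synthetic_survival",
    "build_event_structure",
    "event_boolean_vector",
    "partition_vertically",
    "read_dataset_csv",
    "write_dataset_csv",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data for N subjects and M covariates.

    Attributes
    ----------
    times : ndarray of shape (N,)
        Observed time per subject (event or censoring time); strictly positive.
    events : ndarray of shape (N,)
        Event indicator, 1 = observed event, 0 = right-censored.
    covariates : ndarray of shape (N, M)
        Covariate matrix, no missing entries.
    feature_names : tuple of str
        Column labels, length M.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        cov = np.asarray(self.covariates, dtype=float)
        if times.ndim != 1 or times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            raise ValueError("all observed times must be finite and > 0")
        if events.shape != times.shape:
            raise ValueError("events and times must have the same length")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if cov.ndim != 2 or cov.shape[0] != times.size:
            raise ValueError("covariates must be an (N, M) matrix")
        if np.any(~np.isfinite(cov)):
            raise ValueError("covariates must not contain missing/non-finite entries")
        if len(self.feature_names) != cov.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events.astype(np.int8))
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_subjects(self) -> int:
        return self.times.size

    @property
    def n_features(self) -> int:
        return self.covariates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=list(self.feature_names))
        df.insert(0, "event", self.events.astype(int))
        df.insert(0, "time", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalDataset":
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValueError(f"missing mandatory column '{col}'")
        feats = [c for c in df.columns if c not in ("time", "event")]
        try:
            cov = df[feats].to_numpy(dtype=float)
            times = df["time"].to_numpy(dtype=float)
            events = df["event"].to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in table: {exc}") from exc
        if not np.isin(events, (0.0, 1.0)).all():
            bad = sorted(set(events) - {0.0, 1.0})
            raise ValueError(f"event values must be 0 or 1, found {bad}")
        return cls(times=times, events=events.astype(np.int8), covariates=cov,
                   feature_names=tuple(feats))


@dataclass(frozen=True)
class EventStructure:
    """Distinct event times with their event sets E_t and risk sets R_t.

    ``event_sets[t]`` is the Boolean vector over subjects marking observed events
    exactly at ``distinct_times[t]``; ``risk_sets[t]`` marks subjects with observed
    time >= ``distinct_times[t]`` (the standard convention: a subject is at risk at
    its own event time). Tied event times are grouped into one E_t (Breslow style).
    """

    distinct_times: np.ndarray          # (T,), strictly increasing
    event_sets: np.ndarray              # (T, N) bool
    event_counts: np.ndarray            # (T,)  d_t = |E_t|
    risk_sets: np.ndarray               # (T, N) bool

    @property
    def n_times(self) -> int:
        return self.distinct_times.size

    @property
    def n_subjects(self) -> int:
        return self.event_sets.shape[1]


def build_event_structure(ds: SurvivalDataset) -> EventStructure:
    """Derive the event/risk-set structure from a dataset.

    Raises
    ------
    ValueError
        If the dataset contains no observed events (degenerate likelihood).
    """
    events = ds.events.astype(bool)
    if not events.any():
        raise ValueError("dataset has zero observed events: partial likelihood is degenerate")
    distinct = np.unique(ds.times[events])
    event_sets = (ds.times[None, :] == distinct[:, None]) & events[None, :]
    risk_sets = ds.times[None, :] >= distinct[:, None]
    counts = event_sets.sum(axis=1)
    return EventStructure(distinct_times=distinct, event_sets=event_sets,
                          event_counts=counts, risk_sets=risk_sets)


def event_boolean_vector(es: EventStructure, t_index: int) -> np.ndarray:
    """Return E_t as a 0/1 integer vector (protocol-ready, unscaled).

    ``t_index`` is zero-based into ``es.distinct_times``.
    """
    if not 0 <= t_index < es.n_times:
        raise IndexError(
            f"t_index {t_index} out of range for {es.n_times} distinct event times")
    return es.event_sets[t_index].astype(np.int64)


@dataclass(frozen=True)
class VerticalSplit:
    """Vertical partition: per-party covariate blocks plus an aggregator-only outcome.

    ``blocks[k]`` lists the original column indices held by party k; the party
    matrices share row order (implicit record linkage). The outcome (times,
    events) lives only in ``outcome_view`` — party roles never receive it.
    """

    blocks: tuple[tuple[int, ...], ...]
    party_matrices: tuple[np.ndarray, ...]
    outcome_view: tuple[np.ndarray, np.ndarray]   # (times, events)
    feature_names: tuple[tuple[str, ...], ...] = field(default=())

    @property
    def n_parties(self) -> int:
        return len(self.blocks)

    @property
    def n_subjects(self) -> int:
        return self.party_matrices[0].shape[0]

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    @property
    def column_order(self) -> np.ndarray:
        """Original column index for each position of the concatenated coefficient vector."""
        return np.concatenate([np.asarray(b, dtype=int) for b in self.blocks])


def partition_vertically(ds: SurvivalDataset, k: int,
                         blocks: Sequence[Sequence[int]] | None = None) -> VerticalSplit:
    """Split covariate columns over ``k`` parties; outcome stays with the aggregator.

    The default assignment is round-robin by column order (column j goes to party
    j mod k). Explicit ``blocks`` must partition the column indices exactly.
    With k > M some parties hold no features; they still participate in the
    consensus rounds but run no protocol.
    """
    m = ds.n_features
    if k < 1:
        raise ValueError(f"party count k={k} must be >= 1")
    if blocks is None:
        blocks = [tuple(range(j, m, k)) for j in range(k)]
    else:
        blocks = [tuple(int(i) for i in b) for b in blocks]
        flat = [i for b in blocks for i in b]
        if sorted(flat) != list(range(m)):
            raise ValueError(
                "explicit blocks must partition the column indices "
                f"0..{m - 1} without overlap or omission, got {blocks}")
    mats = tuple(ds.covariates[:, list(b)].copy() for b in blocks)
    names = tuple(tuple(ds.feature_names[i] for i in b) for b in blocks)
    outcome = (ds.times.copy(), ds.events.copy())
    return VerticalSplit(blocks=tuple(blocks), party_matrices=mats,
                         outcome_view=outcome, feature_names=names)


def _solve_censoring_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+lambda_i) = censor_rate."""
    def frac(log_c: float) -> float:
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = -40.0, 40.0
    # bracket: frac(-inf) -> -censor_rate < 0, frac(+inf) -> 1-censor_rate > 0
    return float(np.exp(brentq(frac, lo, hi, xtol=1e-12)))


def generate_synthetic_survival(n: int, m: int, beta_true: Sequence[float],
                                baseline_rate: float = 0.1,
                                censor_rate: float = 0.3,
                                integer_coded: bool = True,
                                seed: int = 0) -> SurvivalDataset:
    """Generate proportional-hazards survival data with independent censoring.

    Event times are exponential with hazard ``baseline_rate * exp(x' beta_true)``.
    Censoring times are exponential with a rate solved numerically so that the
    expected censored fraction equals ``censor_rate`` for the realized hazards.
    With ``integer_coded=True`` covariates are registry-style integer codes drawn
    uniformly from {0, ..., 9} (within two digits); otherwise standard normal.
    Times are rounded to 6 decimals, which creates controlled ties.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 subjects and m >= 1 features")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError(f"censor_rate must lie in [0, 1), got {censor_rate}")
    beta_true = np.asarray(beta_true, dtype=float)
    if beta_true.shape != (m,) or np.any(~np.isfinite(beta_true)):
        raise ValueError("beta_true must be a finite vector of length m")

    rng = np.random.default_rng(seed)
    if integer_coded:
        cov = rng.integers(0, 10, size=(n, m)).astype(float)
    else:
        cov = rng.standard_normal((n, m))
    hazards = baseline_rate * np.exp(cov @ beta_true)
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        times, events = event_times, np.ones(n, dtype=np.int8)
    else:
        c = _solve_censoring_rate(hazards, censor_rate)
        censor_times = rng.exponential(1.0 / c, size=n)
        events = (event_times <= censor_times).astype(np.int8)
        times = np.minimum(event_times, censor_times)
    times = np.maximum(np.round(times, 6), 1e-6)
    names = tuple(f"x{j + 1}" for j in range(m))
    return SurvivalDataset(times=times, events=events, covariates=cov,
                           feature_names=names)


def write_dataset_csv(ds: SurvivalDataset, path: str | Path) -> None:
    """Write the dataset as comma-separated text: time,event,<features>."""
    ds.to_frame().to_csv(path, index=False)


def read_dataset_csv(path: str | Path) -> SurvivalDataset:
    """Read a dataset written by :func:`write_dataset_csv` (full-precision round trip)."""
    df = pd.read_csv(path)
    return SurvivalDataset.from_frame(df)
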