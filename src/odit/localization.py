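"""Anomaly localization: which dimensions carry the detected anomaly.

With squared Euclidean distances the total distance decomposes additively
over dimensions,

    L_t = sum_i delta_t^i,   delta_t^i = sum_{n=k-s+1}^{k} (x_t^i - y_n^i)^2,

so each dimension's contribution to the detection statistic can be tracked
separately.  After an alarm at time T, the onset is estimated as the last
time the statistic was zero (tau_hat), and a one-sided Student t-test
compares the post-onset contribution mean of each dimension over S samples
against its nominal training mean mu_i:

    (dbar_i - mu_i) / (eta_i / sqrt(S)) >= theta  =>  dimension i anomalous,

with theta the upper (1-beta) quantile of t with S-1 degrees of freedom.
Contributions always use the squared form even when detection runs with
gamma != 2: the additive per-dimension decomposition only holds for squared
distances, and the t-test needs that additivity.  The test is one-sided;
anomalously *small* contributions are never flagged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detector import (DetectorState, NominalModel, cusum_recursion,
                       evidence_trace)
from .errors import InputFormatError, InvalidConfigurationError


@dataclass
class LocalizationReport:
    """Result of the per-dimension t-test after one alarm."""
    tau_hat: int
    S: int
    t_stats: np.ndarray
    theta: float
    flagged: frozenset
    beta: float

    def __post_init__(self):
        self.flagged = frozenset(self.flagged)


def per_dim_contributions(x, neighbors) -> np.ndarray:
    """delta_i = sum_n (x_i - y_{n,i})^2 over the given neighbor rows."""
    x = np.asarray(x, dtype=np.float64).ravel()
    Y = np.atleast_2d(np.asarray(neighbors, dtype=np.float64))
    if Y.shape[1] != x.size:
        raise InputFormatError(
            f"neighbors have {Y.shape[1]} dimensions, observation has {x.size}")
    return ((x[None, :] - Y) ** 2).sum(axis=0)


def estimate_onset(statistic_trace, T: int | None = None) -> int:
    """Onset estimate tau_hat = max{t < T : Delta_t = 0}, or 0 if the
    statistic never touched zero before T.  The trace is 1-based: entry i
    holds Delta_{i+1}."""
    trace = np.asarray(statistic_trace, dtype=np.float64)
    if T is None:
        T = trace.size
    zeros = np.flatnonzero(trace[:T - 1] == 0.0)
    return int(zeros[-1] + 1) if zeros.size else 0


def t_threshold(beta: float, S: int) -> float:
    """Upper (1-beta) quantile of Student's t with S-1 degrees of freedom."""
    if S < 2:
        raise InvalidConfigurationError(
            f"localization needs S >= 2 samples (got S={S}) for >= 1 degree "
            "of freedom")
    if not (0.0 < beta < 1.0):
        raise InvalidConfigurationError(f"beta must be in (0,1), got {beta}")
    return float(stats.t.ppf(1.0 - beta, df=S - 1))


def _t_statistics(Q: np.ndarray, mu: np.ndarray) -> np.ndarray:
    S = Q.shape[0]
    dbar = Q.mean(axis=0)
    eta = Q.std(axis=0, ddof=1)
    t = np.empty(mu.shape[0])
    nz = eta > 0.0
    t[nz] = (dbar[nz] - mu[nz]) / (eta[nz] / np.sqrt(S))
    # degenerate variance: flag iff the mean contribution exceeds nominal
    t[~nz] = np.where(dbar[~nz] > mu[~nz], np.inf, -np.inf)
    return t


def localize(contributions, tau_hat: int, model: NominalModel, S: int = 10,
             beta: float = 0.05) -> LocalizationReport:
    """t-test the S post-onset contribution vectors against the nominal
    per-dimension means.

    `contributions` is the (n, d) matrix for stream times 1..n; samples at
    times tau_hat+1 .. tau_hat+S are used (these may extend past the alarm
    time T).  If fewer than S rows remain, all available rows are used
    provided at least 2 exist.
    """
    C = np.atleast_2d(np.asarray(contributions, dtype=np.float64))
    if C.shape[1] != model.d:
        raise InputFormatError(
            f"contributions have {C.shape[1]} dimensions, model expects {model.d}")
    Q = C[tau_hat:tau_hat + S]
    S_used = Q.shape[0]
    if S_used < 2:
        raise InvalidConfigurationError(
            f"only {S_used} post-onset sample(s) available; need >= 2")
    t = _t_statistics(Q, model.mu)
    theta = t_threshold(beta, S_used)
    flagged = frozenset(int(i) for i in np.flatnonzero(t >= theta))
    return LocalizationReport(tau_hat=tau_hat, S=S_used, t_stats=t,
                              theta=theta, flagged=flagged, beta=beta)


def localize_state(state: DetectorState, model: NominalModel, S: int = 10,
                   beta: float = 0.05) -> LocalizationReport:
    """Online variant: consume the first S entries of the stepping state's
    contribution buffer (times last_zero+1 .. last_zero+S).  Keep stepping
    past the alarm until the buffer holds S entries if needed."""
    buf = list(state.contribution_buffer)[:S]
    if len(buf) < 2:
        raise InvalidConfigurationError(
            f"contribution buffer holds {len(buf)} sample(s); need >= 2 "
            "(keep stepping past the alarm to collect S samples)")
    Q = np.asarray(buf)
    t = _t_statistics(Q, model.mu)
    theta = t_threshold(beta, Q.shape[0])
    flagged = frozenset(int(i) for i in np.flatnonzero(t >= theta))
    return LocalizationReport(tau_hat=state.last_zero, S=Q.shape[0], t_stats=t,
                              theta=theta, flagged=flagged, beta=beta)


def localize_stream(stream, model: NominalModel, h: float, S: int = 10,
                    beta: float = 0.05):
    """Detect on a finite stream and localize the first alarm.

    Returns ``(T, report)`` with T the 1-based alarm time, or ``(None, None)``
    if the statistic never reaches h.  Contribution samples may extend past T
    (localization then effectively happens at time tau_hat + S).
    """
    D, C = evidence_trace(stream, model)
    trace = cusum_recursion(D)
    hits = np.flatnonzero(trace >= h)
    if hits.size == 0:
        return None, None
    T = int(hits[0]) + 1
    tau_hat = estimate_onset(trace, T)
    return T, localize(C, tau_hat, model, S=S, beta=beta)
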