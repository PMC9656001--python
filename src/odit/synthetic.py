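"""Simulation designs and trial-based evaluation for the sequential detector.

Two canonical stress tests for multivariate change detection are generated
here, plus a multichannel surrogate stream for demos:

* change in the mean: i.i.d. standard Gaussian rows in d dimensions; at the
  change point a +3-standard-deviation shift is planted in a random 10%
  subset of the dimensions.  Challenging because each shifted coordinate
  still overlaps heavily with its nominal distribution.
* change in the correlation: diagonal-covariance Gaussian rows; after the
  change point a random block of dimensions becomes correlated via a Wishart
  draw rescaled so every marginal variance is preserved exactly — only the
  correlation structure changes.

Evaluation follows the quickest-detection semantics: a trial false-alarms if
its first alarm precedes the change point tau; average detection delay (ADD)
is the mean of (T - tau)+ over trials whose first alarm is at or after tau;
the detection rate counts trials with any alarm at t >= tau within the
horizon (alarm times taken from the threshold-free statistic trace, i.e.
restart-after-false-alarm semantics).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .detector import NominalModel, cusum_recursion, evidence_trace
from .errors import InvalidConfigurationError


@dataclass(frozen=True)
class MeanChangeSpec:
    """Change-in-the-mean design: nominal N(0, I_d); after tau, +shift_sd is
    added to ceil(frac_dims * d) randomly chosen dimensions (per trial)."""
    d: int = 50
    N_train: int = 50_000
    tau: int = 200
    shift_sd: float = 3.0
    frac_dims: float = 0.1
    horizon: int = 400
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.frac_dims <= 1.0):
            raise InvalidConfigurationError("frac_dims must be in [0, 1]")
        if not (0 <= self.tau < self.horizon):
            raise InvalidConfigurationError("need 0 <= tau < horizon")


@dataclass(frozen=True)
class CorrChangeSpec:
    """Change-in-the-correlation design: nominal N(0, diag(sigma_i^2)) with
    log-uniform variances; after tau a random block x block sub-block becomes
    correlated (Wishart draw normalized to a correlation matrix and rescaled
    by the original sigmas, so the diagonal of Sigma1 equals Sigma0's)."""
    d: int = 100
    tau: int = 100
    block: int = 10
    wishart_df: int = 10
    N_train: int = 10_000
    horizon: int = 300
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.block > self.d:
            raise InvalidConfigurationError("block must be <= d")
        if self.block > 0 and self.wishart_df < self.block:
            raise InvalidConfigurationError(
                "wishart_df must be >= block for a positive-definite sample")
        if not (0 <= self.tau < self.horizon):
            raise InvalidConfigurationError("need 0 <= tau < horizon")


def gen_mean_change(spec: MeanChangeSpec):
    """Training matrix, trial streams, and ground-truth shifted-dimension sets.

    Stream rows 1..tau are nominal; rows tau+1..horizon carry the shift.
    """
    rng = np.random.default_rng(spec.seed)
    train = rng.standard_normal((spec.N_train, spec.d))
    n_shift = math.ceil(spec.frac_dims * spec.d)
    streams, dim_sets = [], []
    for _ in range(spec.n_trials):
        stream = rng.standard_normal((spec.horizon, spec.d))
        dims = rng.choice(spec.d, size=n_shift, replace=False)
        stream[spec.tau:, dims] += spec.shift_sd
        streams.append(stream)
        dim_sets.append(frozenset(int(i) for i in dims))
    return train, streams, dim_sets


def gen_nominal_streams(spec: MeanChangeSpec, n_streams: int,
                        length: int | None = None, seed: int | None = None):
    """Nominal-only streams from the same design (for threshold calibration)."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    length = spec.horizon if length is None else length
    return [rng.standard_normal((length, spec.d)) for _ in range(n_streams)]


def _wishart_correlated_block(sigma2: np.ndarray, block_dims: np.ndarray,
                              df: int, rng: np.random.Generator) -> np.ndarray:
    """Sigma1: replace the block_dims x block_dims sub-block of diag(sigma2)
    with a Wishart-derived correlation rescaled by the original sigmas."""
    b = block_dims.size
    W = stats.wishart.rvs(df=df, scale=np.eye(b) / df, random_state=rng)
    W = np.atleast_2d(W)
    dinv = 1.0 / np.sqrt(np.diag(W))
    R = W * dinv[:, None] * dinv[None, :]
    np.fill_diagonal(R, 1.0)  # exact unit diagonal => variances preserved
    sig = np.sqrt(sigma2[block_dims])
    Sigma1 = np.diag(sigma2).astype(np.float64)
    Sigma1[np.ix_(block_dims, block_dims)] = R * sig[:, None] * sig[None, :]
    Sigma1[np.arange(sigma2.size), np.arange(sigma2.size)] = sigma2  # exact
    return Sigma1


def gen_corr_change(spec: CorrChangeSpec):
    """Training matrix, trial streams, and the (Sigma0, Sigma1) pair."""
    rng = np.random.default_rng(spec.seed)
    sigma2 = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=spec.d))
    Sigma0 = np.diag(sigma2)
    if spec.block == 0:
        Sigma1 = Sigma0.copy()
        chol1 = np.sqrt(sigma2)
        block_dims = np.empty(0, dtype=int)
    else:
        block_dims = np.sort(rng.choice(spec.d, size=spec.block, replace=False))
        for attempt in range(10):
            Sigma1 = _wishart_correlated_block(sigma2, block_dims,
                                               spec.wishart_df, rng)
            try:
                chol1 = np.linalg.cholesky(Sigma1)
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover - Wishart draws are PD almost surely
            raise InvalidConfigurationError(
                "could not construct a positive-definite Sigma1")
    sig = np.sqrt(sigma2)
    train = rng.standard_normal((spec.N_train, spec.d)) * sig
    streams = []
    for _ in range(spec.n_trials):
        pre = rng.standard_normal((spec.tau, spec.d)) * sig
        z = rng.standard_normal((spec.horizon - spec.tau, spec.d))
        post = z @ chol1.T if spec.block else z * sig
        streams.append(np.vstack([pre, post]))
    return train, streams, Sigma0, Sigma1


def gen_surrogate_stream(channels: int, horizon: int, onset: int,
                         effect: float, seed: int = 0, ar: float = 0.8):
    """Multichannel AR(1) surrogate stream whose per-channel variance and
    cross-channel coupling both increase after `onset` (a stand-in for
    physiological recordings such as multichannel EEG around a seizure
    onset; synthetic, no real-data statistics).  Returns (stream, onset)."""
    rng = np.random.default_rng(seed)
    x = np.zeros(channels)
    out = np.empty((horizon, channels))
    rho = min(max(effect, 0.0), 0.95)
    for t in range(horizon):
        anomalous = t >= onset and effect > 0
        e = rng.standard_normal(channels)
        if anomalous:
            common = rng.standard_normal()
            innov = (math.sqrt(1 - rho) * e + math.sqrt(rho) * common)
            innov *= (1.0 + effect)
        else:
            innov = e
        x = ar * x + math.sqrt(1 - ar ** 2) * innov
        out[t] = x
    return out, onset


def trial_evidences(model: NominalModel, streams):
    """Evidence sequence and contribution matrix per trial stream (the
    expensive kNN pass, done once; every threshold sweep reuses it)."""
    return [evidence_trace(s, model) for s in streams]


def run_trials(model: NominalModel, streams, tau: int, h_grid,
               evidences=None) -> pd.DataFrame:
    """ADD / FAR / detection-rate table over a threshold grid.

    Per threshold h: FAR is the fraction of trials whose first alarm precedes
    tau; ADD averages (T - tau)+ over trials whose first alarm is at or after
    tau; detection rate is the fraction of trials whose statistic reaches h
    at some t >= tau (i.e. detection even after a reset following an early
    false alarm).
    """
    if evidences is None:
        evidences = trial_evidences(model, streams)
    traces = [cusum_recursion(D) for D, _ in evidences]
    h_grid = np.sort(np.asarray(h_grid, dtype=np.float64))
    rows = []
    for h in h_grid:
        first, post = [], []
        for trace in traces:
            hits = np.flatnonzero(trace >= h)
            first.append(int(hits[0]) + 1 if hits.size else None)
            post_hits = hits[hits >= tau - 1]  # 0-based index tau-1 <=> time tau
            post.append(int(post_hits[0]) + 1 if post_hits.size else None)
        n = len(traces)
        far = sum(1 for T in first if T is not None and T < tau) / n
        detected = [T for T in first if T is not None and T >= tau]
        add = float(np.mean([T - tau for T in detected])) if detected else np.nan
        rate = sum(1 for T in post if T is not None) / n
        rows.append({"h": float(h), "far": far, "add": add,
                     "detection_rate": rate, "n_detected": len(detected)})
    return pd.DataFrame(rows)


def localization_roc(t_stats_list, truth_sets, d: int, theta_grid=None):
    """Pooled ROC of the per-dimension t-statistics against ground truth.

    TPR/FPR are pooled over all trials and dimensions; the curve sweeps the
    flagging threshold theta (default: every distinct pooled t value) and is
    closed with (0,0) and (1,1).  Returns (fpr, tpr, auc) with AUC by the
    trapezoid rule.
    """
    t_all, y_all = [], []
    for t_stats, truth in zip(t_stats_list, truth_sets):
        t_stats = np.asarray(t_stats, dtype=np.float64)
        labels = np.zeros(d, dtype=bool)
        labels[list(truth)] = True
        t_all.append(t_stats)
        y_all.append(labels)
    t_all = np.concatenate(t_all)
    y_all = np.concatenate(y_all)
    n_pos = int(y_all.sum())
    n_neg = int((~y_all).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidConfigurationError("need both anomalous and nominal dimensions")
    if theta_grid is None:
        theta_grid = np.unique(t_all[np.isfinite(t_all)])
    theta_grid = np.sort(np.asarray(theta_grid, dtype=np.float64))
    fpr = [0.0]
    tpr = [0.0]
    for theta in theta_grid[::-1]:
        pred = t_all >= theta
        tpr.append(float((pred & y_all).sum()) / n_pos)
        fpr.append(float((pred & ~y_all).sum()) / n_neg)
    fpr.append(1.0)
    tpr.append(1.0)
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    order = np.argsort(fpr, kind="stable")
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return fpr, tpr, auc


def gaussian_cusum_oracle(stream, mean0, cov0, mean1, cov1, h: float):
    """Exact Gaussian CUSUM: accumulate the true log-likelihood ratio
    log f1(x)/f0(x) with reflection at zero; stop at the first crossing of h.
    Returns (T or None, statistic trace).  Requires the true pre/post-change
    parameters, so it serves as the informed lower bound on detection delay
    for nonparametric detectors in matched simulations.
    """
    stream = np.atleast_2d(np.asarray(stream, dtype=np.float64))
    llr = (stats.multivariate_normal.logpdf(stream, mean=mean1, cov=cov1)
           - stats.multivariate_normal.logpdf(stream, mean=mean0, cov=cov0))
    trace = cusum_recursion(np.atleast_1d(llr))
    hits = np.flatnonzero(trace >= h)
    T = int(hits[0]) + 1 if hits.size else None
    return T, trace
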