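"""Sequential kNN anomaly detector (Online Discrepancy Test).

Training estimates a minimum-volume set (MVS) of the nominal distribution:
the training set is split into a ranked part X1 and a reference part X2, each
X1 point gets a kNN "total distance"

    L_m = sum_{n=k-s+1}^{k} g_n(x_m)^gamma

against X2, and the K = floor(N1 (1 - alpha)) smallest totals define the MVS,
represented by the borderline total distance L_(K).  At test time each
observation x_t yields an anomaly evidence

    D_t = d (log L_t - log L_(K)),

negative inside the MVS and positive outside, which a CUSUM-like recursion
accumulates:  Delta_t = max(Delta_{t-1} + D_t, 0), alarm when Delta_t >= h.
As the reference set grows, D_t converges in probability to the
log-likelihood ratio against a uniform alternative pinned at the density of
the borderline MVS point, so the test inherits the optimality of CUSUM in
that limit.
"""
from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from ._knn import exact_knn
from .approx_knn import KMeansTree
from .errors import InputFormatError, InvalidConfigurationError
from .params import OditParams

#: floor applied to total distances before taking logs, so exact duplicates of
#: training points produce large-negative (not -inf) evidence
LOG_FLOOR = 1e-12


def _as_matrix(X, name: str = "X") -> np.ndarray:
    try:
        X = np.asarray(X, dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise InputFormatError(f"{name} is not numeric: {exc}") from None
    if X.ndim != 2:
        raise InputFormatError(f"{name} must be 2-D, got shape {X.shape}")
    if not np.isfinite(X).all():
        bad = int(np.flatnonzero(~np.isfinite(X).all(axis=1))[0])
        raise InputFormatError(f"{name} has non-finite values (first bad row: {bad})")
    return X


def _as_vector(x, d: int) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size != d:
        raise InputFormatError(f"observation has {x.size} dimensions, expected {d}")
    if not np.isfinite(x).all():
        raise InputFormatError("observation contains non-finite values")
    return x


def partition_training(X: np.ndarray, params: OditParams):
    """Randomly split the nominal training matrix into (X1, X2).

    X1 (size N1 = round(n1_fraction * N)) is ranked by total distance against
    the reference part X2 (size N2 = N - N1).  Deterministic given the seed.
    With ``params.partition`` False both parts are the full training set.
    """
    X = _as_matrix(X)
    N = X.shape[0]
    if N < 2:
        raise InvalidConfigurationError(f"need at least 2 training rows, got {N}")
    if not params.partition:
        if N < params.k + 1:
            raise InvalidConfigurationError(
                "unpartitioned training needs at least k+1 rows "
                f"(self-matches are excluded), got {N}")
        return X, X
    N1 = int(round(params.n1_fraction * N))
    N1 = min(max(N1, 1), N - 1)
    N2 = N - N1
    if N2 < params.k:
        raise InvalidConfigurationError(
            f"reference partition has N2={N2} rows, fewer than k={params.k}")
    rng = np.random.default_rng(params.seed)
    perm = rng.permutation(N)
    return X[perm[:N1]], X[perm[N1:]]


def knn_distances(query: np.ndarray, reference: np.ndarray, k: int):
    """Nondecreasing vector of the k smallest Euclidean distances from
    `query` (a single d-vector) to the rows of `reference`."""
    query = np.asarray(query, dtype=np.float64).ravel()
    dist, _ = exact_knn(query[None, :], reference, k)
    return dist[0]


def total_distance(g, params: OditParams):
    """Total distance L = sum_{n=k-s+1}^{k} g_n^gamma.

    `g` may be a single nondecreasing k-vector or an (n, k) batch; the sum
    runs over the last s entries (the s farthest of the k neighbors).
    """
    g = np.asarray(g, dtype=np.float64)
    tail = g[..., g.shape[-1] - params.s:]
    return (tail ** params.gamma).sum(axis=-1)


def density_estimate(x, reference, k: int):
    """kNN density estimate f0(x) ~= k / (N2 * v_d * g_k(x)^d), with v_d the
    volume of the unit d-ball.  Consistent as the reference set grows."""
    reference = _as_matrix(reference, "reference")
    N2, d = reference.shape
    gk = max(float(knn_distances(x, reference, k)[-1]), LOG_FLOOR)
    v_d = math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)
    return k / (N2 * v_d * gk ** d)


@dataclass
class NominalModel:
    """Fitted reference model for the sequential test.

    `reference` is stored in the (optionally standardized) space actually used
    for distance computations; `center`/`scale` map raw observations into it.
    `sorted_L` holds the N1 ordered training total distances; `L_K` is the
    K-th smallest (the MVS borderline).  `mu` holds per-dimension nominal
    contribution means used by the localization t-test.
    """
    reference: np.ndarray
    d: int
    K: int
    L_K: float
    sorted_L: np.ndarray
    mu: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    params: OditParams
    _tree: KMeansTree | None = field(default=None, repr=False)

    @property
    def N1(self) -> int:
        return int(self.sorted_L.size)

    @property
    def N2(self) -> int:
        return int(self.reference.shape[0])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def _ensure_tree(self) -> KMeansTree:
        if self._tree is None:
            self._tree = KMeansTree(
                self.reference, branching=self.params.branching,
                max_iters=self.params.kmeans_iters,
                leaf_size=self.params.leaf_size, seed=self.params.seed)
        return self._tree

    def query(self, X: np.ndarray):
        """kNN distances and reference indices for raw observation rows."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.d:
            raise InputFormatError(
                f"query has {X.shape[1]} dimensions, model expects {self.d}")
        if not np.isfinite(X).all():
            raise InputFormatError("query contains non-finite values")
        Xs = self.transform(X)
        if self.params.knn_backend == "approximate":
            tree = self._ensure_tree()
            k, B = self.params.k, self.params.search_budget
            dist = np.empty((Xs.shape[0], k))
            idx = np.empty((Xs.shape[0], k), dtype=np.intp)
            for i, row in enumerate(Xs):
                dist[i], idx[i] = tree.search(row, k, B)
            return dist, idx
        return exact_knn(Xs, self.reference, self.params.k)

    def total_distances(self, X: np.ndarray):
        g, _ = self.query(X)
        return total_distance(g, self.params)

    def evidence(self, L):
        """Anomaly evidence D = d * (log L - log L_(K)), with L floored to
        guard log(0)."""
        L = np.maximum(np.asarray(L, dtype=np.float64), LOG_FLOOR)
        return self.d * (np.log(L) - math.log(self.L_K))

    def contributions(self, X: np.ndarray, idx: np.ndarray):
        """Per-dimension squared-difference contributions against the s
        selected neighbors: delta_i = sum_n (x_i - y_{n,i})^2, an (n, d)
        array.  With gamma=2 the row sums equal the total distances."""
        Xs = self.transform(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        sel = idx[:, idx.shape[1] - self.params.s:]
        diff = Xs[:, None, :] - self.reference[sel]
        return (diff ** 2).sum(axis=1)


def fit_nominal(X, params: OditParams) -> NominalModel:
    """Fit the nominal MVS model: partition, rank X1 by total distance
    against X2, take the K-th order statistic as the borderline L_(K), and
    record per-dimension nominal contribution means."""
    X = _as_matrix(X)
    N, d = X.shape
    if params.standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        zero = scale == 0.0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance dimension(s); scale forced to 1",
                RuntimeWarning, stacklevel=2)
            scale = np.where(zero, 1.0, scale)
    else:
        center = np.zeros(d)
        scale = np.ones(d)
    X1, X2 = partition_training(X, params)
    N1 = X1.shape[0]
    K = int(math.floor(N1 * (1.0 - params.alpha)))
    if K < 1:
        raise InvalidConfigurationError(
            f"K = floor(N1*(1-alpha)) = 0 with N1={N1}, alpha={params.alpha}; "
            "alpha too large for this training size")
    model = NominalModel(
        reference=(X2 - center) / scale, d=d, K=K, L_K=np.nan,
        sorted_L=np.empty(0), mu=np.empty(0), center=center, scale=scale,
        params=params)
    if params.partition:
        g, idx = model.query(X1)
    else:
        # query k+1 neighbors and drop each point's self-match
        wide = model.params.replace(k=params.k + 1, s=params.s,
                                    search_budget=max(params.search_budget,
                                                      params.k + 1))
        wide_model = NominalModel(
            reference=model.reference, d=d, K=K, L_K=np.nan,
            sorted_L=np.empty(0), mu=np.empty(0), center=center, scale=scale,
            params=wide)
        g, idx = wide_model.query(X1)
        g, idx = g[:, 1:], idx[:, 1:]
    L = total_distance(g, params)
    sorted_L = np.sort(L)
    L_K = float(sorted_L[K - 1])
    if L_K <= 0.0:
        raise InvalidConfigurationError(
            "borderline total distance L_(K) is zero: training data has "
            "duplicate points at or above rank K; reduce alpha or deduplicate")
    model.sorted_L = sorted_L
    model.L_K = L_K
    model.mu = model.contributions(X1, idx).mean(axis=0)
    return model


def anomaly_evidence(L_t: float, model: NominalModel) -> float:
    """Evidence D_t = d (log L_t - log L_(K)) for a single total distance."""
    return float(model.evidence(L_t))


def mvs_contains(x, model: NominalModel) -> bool:
    """One-shot MVS membership: True iff L(x) <= L_(K).  This is the
    single-sample outlier rule; the sequential test accumulates evidence
    instead of alarming on single excursions."""
    return bool(model.total_distances(np.atleast_2d(x))[0] <= model.L_K)


@dataclass
class DetectorState:
    """Running state of the online test.

    `contribution_buffer` holds per-dimension contribution vectors for times
    last_zero+1 .. t (capped ring buffer), which is what the localization
    t-test consumes after an alarm.
    """
    t: int = 0
    delta: float = 0.0
    last_zero: int = 0
    contribution_buffer: deque = field(default_factory=deque)
    alarmed: bool = False

    @classmethod
    def fresh(cls, cap: int = 10_000) -> "DetectorState":
        return cls(contribution_buffer=deque(maxlen=cap))


@dataclass
class AlarmReport:
    """One alarm: stopping time T, onset estimate tau_hat (the last time the
    statistic was zero before T), and the evidence/statistic traces from the
    start of the stream through T (1-based times; index i holds time i+1)."""
    T: int
    tau_hat: int
    evidence_trace: np.ndarray
    statistic_trace: np.ndarray
    localization: object | None = None


def step(state: DetectorState, x_t, model: NominalModel, h: float | None = None):
    """Advance the online test by one observation.

    Returns ``(state, D_t, alarm)``; the state is updated in place.  The
    statistic follows Delta_t = max(Delta_{t-1} + D_t, 0); last_zero and the
    contribution buffer are refreshed whenever the statistic hits zero.
    """
    if h is None:
        h = model.params.h
    x_t = _as_vector(x_t, model.d)
    g, idx = model.query(x_t[None, :])
    L = float(total_distance(g, model.params)[0])
    D = anomaly_evidence(L, model)
    state.t += 1
    state.delta = max(state.delta + D, 0.0)
    alarm = state.delta >= h
    contrib = model.contributions(x_t[None, :], idx)[0]
    if not alarm and state.delta == 0.0:
        state.last_zero = state.t
        state.contribution_buffer.clear()
    else:
        state.contribution_buffer.append(contrib)
    state.alarmed = state.alarmed or alarm
    return state, D, alarm


def evidence_trace(stream, model: NominalModel):
    """Vectorized per-row evidence for a whole stream.

    Returns ``(D, contributions)``: the evidence sequence (n,) and the
    per-dimension contribution matrix (n, d).
    """
    stream = _as_matrix(stream, "stream")
    g, idx = model.query(stream)
    L = total_distance(g, model.params)
    D = model.evidence(L)
    C = model.contributions(stream, idx)
    return D, C


def cusum_recursion(D: np.ndarray) -> np.ndarray:
    """Delta_t = max(Delta_{t-1} + D_t, 0) over a full evidence sequence,
    without stopping.  Threshold-free, so one pass serves every h."""
    delta = 0.0
    out = np.empty(D.shape[0])
    for i, d_i in enumerate(D):
        delta = max(delta + d_i, 0.0)
        out[i] = delta
    return out


def run_stream(stream, model: NominalModel, h: float, restart: bool = False):
    """Run the sequential test over a finite stream.

    Emits an :class:`AlarmReport` at each alarm.  Without `restart` the test
    stops at the first alarm; with `restart` the statistic resets to zero and
    testing continues (multi-anomaly mode).
    """
    stream = _as_matrix(stream, "stream")
    if stream.shape[0] == 0:
        return []
    if h < 0:
        raise InvalidConfigurationError(f"h must be >= 0, got {h}")
    D, _ = evidence_trace(stream, model)
    reports = []
    delta = 0.0
    last_zero = 0
    deltas = np.empty(D.shape[0])
    for i, d_i in enumerate(D):
        delta = max(delta + d_i, 0.0)
        deltas[i] = delta
        t = i + 1
        if delta >= h:
            reports.append(AlarmReport(
                T=t, tau_hat=last_zero,
                evidence_trace=D[:t].copy(),
                statistic_trace=deltas[:t].copy()))
            if not restart:
                break
            delta = 0.0
            last_zero = t
        elif delta == 0.0:
            last_zero = t
    return reports


def calibrate_threshold(model: NominalModel, nominal_streams, target_far: float,
                        grid=None) -> float:
    """Smallest grid threshold whose empirical false-alarm frequency over the
    given nominal-only streams is <= target_far.

    The statistic trace of each stream is computed once (it does not depend
    on h); a stream false-alarms at threshold h iff its maximum statistic
    reaches h.  The default grid is logarithmic over [1e-2, 1e3] (60 points).
    """
    if not (0.0 < target_far <= 1.0):
        raise InvalidConfigurationError(
            f"target_far must be in (0, 1], got {target_far}")
    streams = list(nominal_streams)
    if not streams:
        raise InvalidConfigurationError("need at least one nominal stream")
    if grid is None:
        grid = np.logspace(-2, 3, 60)
    grid = np.sort(np.asarray(grid, dtype=np.float64))
    maxima = np.array([cusum_recursion(evidence_trace(s, model)[0]).max()
                       for s in streams])
    for h in grid:
        if (maxima >= h).mean() <= target_far:
            return float(h)
    warnings.warn(
        f"target FAR {target_far} not achievable on the grid; returning max "
        "grid threshold", RuntimeWarning, stacklevel=2)
    return float(grid[-1])
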