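"""Tuning parameters for the sequential kNN anomaly detector.

The detector compares each incoming observation's kNN total distance against
the borderline total distance of an estimated minimum-volume set (MVS) of
nominal training data, and accumulates the resulting log evidence in a
CUSUM-like recursion.  All knobs that shape that comparison live here.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

from .errors import InvalidConfigurationError

_BACKENDS = ("exact", "approximate")


@dataclass(frozen=True)
class OditParams:
    """Configuration of the detector.

    Parameters
    ----------
    k : int
        Number of nearest neighbors consulted per query.  Smaller k is more
        sensitive to anomalies but more prone to nominal outliers.
    s : int
        Number of summed neighbors, ``1 <= s <= k``.  The total distance sums
        the distances to neighbors ``k-s+1 .. k``; ``s=1`` uses only the k-th
        neighbor, ``s=k`` sums all k.
    gamma : float
        Exponent applied to each neighbor distance before summing (> 0).
        Larger values emphasize large distances.
    alpha : float
        Significance level of the minimum-volume set, in (0, 1).  The MVS
        estimate keeps the ``K = floor(N1 * (1 - alpha))`` training points
        with the smallest total distances.
    h : float
        Detection threshold on the accumulated statistic (>= 0).  The only
        knob that directly trades detection delay against false alarms; it is
        typically calibrated on nominal validation streams.
    n1_fraction : float
        Fraction of the training set assigned to the ranked partition X1
        (the rest, X2, is the reference set for neighbor queries), in (0, 1).
    seed : int
        Seed for the training partition and, with the approximate backend,
        the k-means tree construction.
    standardize : bool
        If True, z-score every dimension by training statistics before
        computing Euclidean distances.  Off by default: distances are
        scale-sensitive and standardization changes the geometry.
    partition : bool
        If False, skip the random split and rank the training points against
        the full training set itself (self-matches excluded).  Useful for
        small training sets.
    knn_backend : str
        ``"exact"`` or ``"approximate"`` (priority-search k-means tree).
    branching : int
        Branching factor C of the k-means tree (approximate backend).
    search_budget : int
        Maximum number of candidate points B examined per approximate query.
    kmeans_iters : int
        Maximum Lloyd iterations per tree node.
    leaf_size : int
        Nodes with at most this many points become leaves.
    contribution_buffer_cap : int
        Ring-buffer cap for per-dimension contribution history kept by the
        online stepping state; bounds memory over long nominal stretches.
    """

    k: int = 1
    s: int = 1
    gamma: float = 1.0
    alpha: float = 0.05
    h: float = 0.0
    n1_fraction: float = 0.3
    seed: int = 0
    standardize: bool = False
    partition: bool = True
    knn_backend: str = "exact"
    branching: int = 100
    search_budget: int = 1000
    kmeans_iters: int = 10
    leaf_size: int = 32
    contribution_buffer_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InvalidConfigurationError(f"k must be >= 1, got {self.k}")
        if not (1 <= self.s <= self.k):
            raise InvalidConfigurationError(
                f"s must satisfy 1 <= s <= k, got s={self.s}, k={self.k}")
        if not self.gamma > 0:
            raise InvalidConfigurationError(f"gamma must be > 0, got {self.gamma}")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.h < 0:
            raise InvalidConfigurationError(f"h must be >= 0, got {self.h}")
        if not (0.0 < self.n1_fraction < 1.0):
            raise InvalidConfigurationError(
                f"n1_fraction must be in (0,1), got {self.n1_fraction}")
        if self.knn_backend not in _BACKENDS:
            raise InvalidConfigurationError(
                f"knn_backend must be one of {_BACKENDS}, got {self.knn_backend!r}")
        if self.branching < 2:
            raise InvalidConfigurationError(f"branching must be >= 2, got {self.branching}")
        if self.search_budget < self.k:
            raise InvalidConfigurationError(
                f"search_budget must be >= k, got {self.search_budget} < {self.k}")
        if self.kmeans_iters < 1 or self.leaf_size < 1:
            raise InvalidConfigurationError("kmeans_iters and leaf_size must be >= 1")
        if self.contribution_buffer_cap < 2:
            raise InvalidConfigurationError("contribution_buffer_cap must be >= 2")

    def replace(self, **changes: Any) -> "OditParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OditParams":
        return cls(**d)
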