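"""Exact k-nearest-neighbor queries with deterministic tie handling.

Distances are Euclidean, computed chunk-wise through sklearn's BLAS-backed
pairwise kernel.  Ties between equal distances are broken by reference row
index (candidates are pre-sorted by index, then stably sorted by distance),
so repeated runs and backends agree on which neighbor is selected.
"""
from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from .errors import InvalidConfigurationError

# target number of entries per distance-matrix chunk (~80 MB of float64)
_CHUNK_ENTRIES = 10_000_000


def exact_knn(queries: np.ndarray, reference: np.ndarray, k: int):
    """Distances and indices of the k nearest reference rows per query.

    Parameters
    ----------
    queries : (n, d) array
    reference : (M, d) array
    k : int

    Returns
    -------
    dist : (n, k) array, nondecreasing along axis 1
    idx : (n, k) array of reference row indices
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    reference = np.asarray(reference, dtype=np.float64)
    M = reference.shape[0]
    if M < k:
        raise InvalidConfigurationError(
            f"reference set has {M} rows, fewer than k={k}")
    n = queries.shape[0]
    dist = np.empty((n, k))
    idx = np.empty((n, k), dtype=np.intp)
    rows_per_chunk = max(1, _CHUNK_ENTRIES // max(M, 1))
    for start in range(0, n, rows_per_chunk):
        stop = min(start + rows_per_chunk, n)
        D = euclidean_distances(queries[start:stop], reference)
        if k < M:
            part = np.argpartition(D, k - 1, axis=1)[:, :k]
        else:
            part = np.broadcast_to(np.arange(M), (stop - start, M)).copy()
        part.sort(axis=1)  # index order first, so a stable sort breaks ties by index
        pd_ = np.take_along_axis(D, part, axis=1)
        order = np.argsort(pd_, axis=1, kind="stable")
        idx[start:stop] = np.take_along_axis(part, order, axis=1)
        dist[start:stop] = np.take_along_axis(pd_, order, axis=1)
    return dist, idx
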