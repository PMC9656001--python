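"""Delimited-text matrices and the on-disk model archive.

A model archive is a directory holding ``model.json`` (parameters, sizes, the
borderline distance, the sorted training totals, per-dimension nominal
contribution means, and standardization statistics) plus ``reference.csv``
(the reference set, already in the standardized space the model computes
distances in).  Floats are written with 17 significant digits so a
save/load round trip reproduces detection output bit for bit with the exact
backend; the approximate backend's tree is rebuilt deterministically from the
stored reference set and seed.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import NominalModel
from .errors import InputFormatError, ModelFormatError
from .params import OditParams

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"


def read_matrix(path, has_header: bool | None = None):
    """Read a delimited numeric matrix (CSV or TSV).

    ``has_header=None`` sniffs the first line: if any cell is non-numeric the
    line is treated as a header.  Returns ``(matrix, column_names)`` with
    names ``None`` when there is no header.
    """
    path = Path(path)
    try:
        first = path.read_text().lstrip("﻿").splitlines()
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}") from None
    lines = [ln for ln in first if ln.strip()]
    if not lines:
        raise InputFormatError(f"{path} is empty")
    sep = "\t" if "\t" in lines[0] else ","
    if has_header is None:
        cells = lines[0].split(sep)
        has_header = not all(_is_float(c) for c in cells)
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                         float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise InputFormatError(f"{path}: malformed delimited text: {exc}") from None
    names = [str(c) for c in df.columns] if has_header else None
    try:
        X = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for i in range(df.shape[0]):
            try:
                df.iloc[i].astype(np.float64)
            except (TypeError, ValueError):
                raise InputFormatError(
                    f"{path}: non-numeric value in data row {i + 1}") from None
        raise InputFormatError(f"{path}: non-numeric values") from None
    if X.size == 0:
        raise InputFormatError(f"{path} contains no data rows")
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0]) + 1
        raise InputFormatError(f"{path}: non-finite value in data row {bad}")
    # C-contiguous so BLAS paths (and hence low-order bits) match arrays
    # produced in memory — required for bit-for-bit archive round trips
    return np.ascontiguousarray(X), names


def _is_float(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def write_matrix(path, X, names=None) -> None:
    """Write a matrix as CSV with full float precision."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    header = ",".join(names) if names else ""
    np.savetxt(path, X, fmt=_FLOAT_FMT, delimiter=",",
               header=header, comments="")


def save_model(model: NominalModel, path) -> None:
    """Write a model archive directory (metadata JSON + reference CSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "params": model.params.to_dict(),
        "d": model.d,
        "N1": model.N1,
        "N2": model.N2,
        "K": model.K,
        "L_K": model.L_K,
        "mu": model.mu.tolist(),
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "sorted_L": model.sorted_L.tolist(),
        "reference_file": "reference.csv",
    }
    (path / "model.json").write_text(json.dumps(meta))
    write_matrix(path / "reference.csv", model.reference)


def load_model(path) -> NominalModel:
    """Load and validate a model archive saved by :func:`save_model`."""
    path = Path(path)
    meta_path = path / "model.json"
    if not meta_path.is_file():
        raise ModelFormatError(f"missing metadata file {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupt metadata in {meta_path}: {exc}") from None
    if meta.get("format_version") != FORMAT_VERSION:
        raise ModelFormatError(
            f"unsupported model format version {meta.get('format_version')!r}; "
            f"expected {FORMAT_VERSION}")
    try:
        params = OditParams.from_dict(meta["params"])
        ref_file = path / meta["reference_file"]
        sorted_L = np.asarray(meta["sorted_L"], dtype=np.float64)
        mu = np.asarray(meta["mu"], dtype=np.float64)
        center = np.asarray(meta["center"], dtype=np.float64)
        scale = np.asarray(meta["scale"], dtype=np.float64)
        d, K, L_K = int(meta["d"]), int(meta["K"]), float(meta["L_K"])
        N1, N2 = int(meta["N1"]), int(meta["N2"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"incomplete model metadata: {exc}") from None
    if not ref_file.is_file():
        raise ModelFormatError(f"missing reference file {ref_file}")
    reference, _ = read_matrix(ref_file, has_header=False)
    # structural invariants
    if reference.shape != (N2, d):
        raise ModelFormatError(
            f"reference shape {reference.shape} != declared ({N2}, {d})")
    if sorted_L.size != N1 or mu.size != d or center.size != d or scale.size != d:
        raise ModelFormatError("metadata vector lengths are inconsistent")
    if np.any(np.diff(sorted_L) < 0) or np.any(sorted_L < 0):
        raise ModelFormatError("sorted_L must be nonnegative and nondecreasing")
    if K != int(np.floor(N1 * (1.0 - params.alpha))):
        raise ModelFormatError("K inconsistent with N1 and alpha")
    if not (1 <= K <= N1) or L_K != sorted_L[K - 1]:
        raise ModelFormatError("L_K does not match the K-th order statistic")
    return NominalModel(reference=reference, d=d, K=K, L_K=L_K,
                        sorted_L=sorted_L, mu=mu, center=center, scale=scale,
                        params=params)
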