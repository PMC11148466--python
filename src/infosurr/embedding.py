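"""Time-series containers and delay-embedded observation matrices.

All estimators and row/column shuffle surrogates in this package operate on
*observation matrices*: delay embeddings whose rows collect the present
sample of a process together with its ``q`` most recent past samples.  For a
series ``x`` of length ``N`` and memory order ``q`` the univariate matrix has
shape ``(N - q, q + 1)`` with row ``t`` holding
``(x[t+q], x[t+q-1], ..., x[t])`` — present first, deepest lag last.  The
bivariate matrix stacks the X block and the Y block side by side, giving
shape ``(N - q, 2 (q + 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "EmbeddingSpec",
    "ObservationMatrix",
    "zscore_normalize",
    "build_univariate_observation",
    "build_bivariate_observation",
    "read_csv_series",
]


@dataclass(frozen=True)
class TimeSeries:
    """One uniformly sampled, real-valued signal.

    Parameters
    ----------
    values : array-like of float
        The samples, in time order.
    label : str
        Identifier carried through normalization and embedding.
    """

    values: np.ndarray
    label: str = "x"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("empty series")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"series {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def __len__(self) -> int:
        return self.n_samples


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding and neighbor-search settings.

    ``q`` is the memory order (number of past lags approximating the process
    memory under a Markov truncation); ``k`` the neighbor count of the KNN
    estimator.  Distances are always measured in the maximum (Chebyshev)
    norm.  ``lags`` defaults to the uniform vector ``1..q``; a general
    strictly increasing lag vector is accepted, in which case ``q`` is the
    deepest lag.
    """

    q: int = 2
    k: int = 10
    lags: tuple[int, ...] | None = None
    metric: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric != "chebyshev":
            raise ValueError("only the maximum (chebyshev) norm is supported")
        if self.lags is None:
            object.__setattr__(self, "lags", tuple(range(1, self.q + 1)))
        else:
            lags = tuple(int(l) for l in self.lags)
            if len(lags) == 0 or any(l < 1 for l in lags):
                raise ValueError("lags must be positive integers")
            if any(b <= a for a, b in zip(lags, lags[1:])):
                raise ValueError("lags must be strictly increasing")
            if lags[-1] != self.q:
                raise ValueError("deepest lag must equal q")
            object.__setattr__(self, "lags", lags)


@dataclass(frozen=True)
class ObservationMatrix:
    """Delay-embedded present+past matrix.

    ``data`` has one row per admissible time point (ascending time) and one
    column per (process, lag) pair; ``column_roles`` lists those pairs in
    column order, lag 0 being the present.
    """

    data: np.ndarray
    column_roles: tuple[tuple[str, int], ...]
    source_labels: tuple[str, ...]
    q: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise ValueError("observation matrix must be 2-D")
        if arr.shape[1] != len(self.column_roles):
            raise ValueError("column_roles length must match column count")
        object.__setattr__(self, "data", arr)

    @property
    def n_rows(self) -> int:
        return int(self.data.shape[0])

    @property
    def is_bivariate(self) -> bool:
        return len(self.source_labels) == 2

    def columns_of(self, process: str, lags: "slice | list[int] | None" = None) -> np.ndarray:
        """Column indices belonging to ``process`` (optionally given lags)."""
        idx = [i for i, (p, _) in enumerate(self.column_roles) if p == process]
        if lags is not None:
            wanted = set(lags) if not isinstance(lags, slice) else None
            if wanted is not None:
                idx = [i for i in idx if self.column_roles[i][1] in wanted]
        return np.asarray(idx, dtype=int)

    def block(self, process: str) -> np.ndarray:
        """View of the (present + past) sub-matrix of one process."""
        return self.data[:, self.columns_of(process)]


def zscore_normalize(series: TimeSeries) -> TimeSeries:
    """Standardize a series to zero mean and unit sample standard deviation.

    KNN estimates in joint spaces are sensitive to the relative scale of the
    processes, so estimation is performed on z-scored data by default.

    Raises
    ------
    ValueError
        If the series is constant ("zero variance") or has fewer than two
        samples.
    """
    x = series.values
    if x.size < 2:
        raise ValueError("need at least 2 samples to normalize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"zero variance: series {series.label!r} is constant")
    return TimeSeries((x - x.mean()) / sd, label=series.label)


def _embed(x: np.ndarray, lags: tuple[int, ...], q: int) -> np.ndarray:
    n = x.size
    cols = [x[q:]] + [x[q - l : n - l] for l in lags]
    return np.column_stack(cols)


def build_univariate_observation(series: TimeSeries, spec: EmbeddingSpec) -> ObservationMatrix:
    """Build the ``(N - q) x (q + 1)`` observation matrix of one process.

    The first column is the present (``x_{q+1} .. x_N``); column ``j`` holds
    lag ``j`` (columns ordered present, lag 1, ..., lag q).
    """
    x = series.values
    if x.size <= spec.q:
        raise ValueError(
            f"series too short: N={x.size} <= q={spec.q}"
        )
    data = _embed(x, spec.lags, spec.q)
    roles = tuple((series.label, l) for l in (0,) + spec.lags)
    return ObservationMatrix(data, roles, (series.label,), spec.q)


def build_bivariate_observation(
    x: TimeSeries, y: TimeSeries, spec: EmbeddingSpec
) -> ObservationMatrix:
    """Build the ``(N - q) x 2(q + 1)`` joint observation matrix.

    Columns ``1..q+1`` are the X block (present + past), columns
    ``q+2..2(q+1)`` the Y block, each ordered as in the univariate case.
    """
    if x.n_samples != y.n_samples:
        raise ValueError(
            f"length mismatch: len(x)={x.n_samples}, len(y)={y.n_samples}"
        )
    if x.label == y.label:
        y = TimeSeries(y.values, label=y.label + "_2")
    mx = build_univariate_observation(x, spec)
    my = build_univariate_observation(y, spec)
    data = np.hstack([mx.data, my.data])
    roles = mx.column_roles + my.column_roles
    return ObservationMatrix(data, roles, (x.label, y.label), spec.q)


def read_csv_series(path, columns: list[str] | None = None) -> list[TimeSeries]:
    """Read one series per column from a plain CSV file.

    A single header row is optional; missing values are rejected.
    """
    try:
        df = pd.read_csv(path, skip_blank_lines=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"could not read CSV {path}: {exc}") from exc
    # Headerless files: pandas will have coerced the first data row into
    # column names.  Detect all-numeric "names" and re-read.
    def _numeric(s: str) -> bool:
        try:
            float(s)
            return True
        except (TypeError, ValueError):
            return False

    if len(df.columns) and all(_numeric(str(c)) for c in df.columns):
        df = pd.read_csv(path, header=None, skip_blank_lines=False)
        df.columns = [f"col{i}" for i in range(df.shape[1])]
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s) {missing} in {path}")
        df = df[columns]
    out = []
    for name in df.columns:
        col = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"column {name!r} contains missing or non-numeric values")
        out.append(TimeSeries(col, label=str(name)))
    return out
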