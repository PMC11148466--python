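"""Percentile-based one-sided surrogate hypothesis tests.

A test computes the discriminating statistic (IS or MIR) on the original
data and on M surrogates embodying the null hypothesis, and rejects the null
when the original value exceeds the empirical (1 - alpha) percentile of the
surrogate ensemble.  The percentile is the nearest-rank order statistic
(with M = 100 and alpha = 0.05, the 95th largest value); ties with the
threshold are conservatively not rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .embedding import (
    EmbeddingSpec,
    TimeSeries,
    build_bivariate_observation,
    build_univariate_observation,
    zscore_normalize,
)
from .knn import estimate_is, estimate_mir
from .surrogates import SurrogateSpec, iaaft, iaaft_bivariate, shuffle_present, shuffle_rows_block

__all__ = [
    "SurrogateEnsemble",
    "TestResult",
    "surrogate_test",
    "rejection_rate",
    "COMPATIBLE_METHODS",
]

#: Which surrogate methods are valid nulls for each statistic.
COMPATIBLE_METHODS = {
    "IS": ("shuffle_present", "iaaft"),
    "MIR": ("shuffle_rows", "iaaft_bivariate"),
}

#: Null hypothesis destroyed by each surrogate method.
NULL_TAGS = {
    "shuffle_present": "no self-dependencies (S_X = 0)",
    "iaaft": "exclusively linear univariate dynamics",
    "shuffle_rows": "independent processes (I_XY = 0)",
    "iaaft_bivariate": "exclusively linear coupling",
}


@dataclass(frozen=True)
class SurrogateEnsemble:
    """M surrogate statistic values with the spec that produced them."""

    values: np.ndarray
    method: SurrogateSpec
    statistic: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or not np.all(np.isfinite(vals)):
            raise ValueError("ensemble values must be a finite 1-D array")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one surrogate test."""

    __test__ = False  # not a pytest test class

    original: float
    ensemble: SurrogateEnsemble
    alpha: float
    threshold: float
    reject: bool
    null_hypothesis: str

    def as_dict(self) -> dict:
        return {
            "statistic": self.ensemble.statistic,
            "value_nats": self.original,
            "n_surrogates": int(self.ensemble.values.size),
            "alpha": self.alpha,
            "threshold": self.threshold,
            "reject": bool(self.reject),
            "method": self.ensemble.method.method,
            "seed": self.ensemble.method.seed,
            "null_hypothesis": self.null_hypothesis,
        }


def nearest_rank_percentile(values: np.ndarray, level: float) -> float:
    """Nearest-rank empirical percentile: the ``ceil(level * M)``-th order
    statistic of ``values`` (no interpolation)."""
    vals = np.sort(np.asarray(values, dtype=float))
    rank = int(math.ceil(level * vals.size))
    rank = min(max(rank, 1), vals.size)
    return float(vals[rank - 1])


def _spawn_rngs(seed, m: int) -> list[np.random.Generator]:
    # Independent substream per surrogate: reproducible regardless of order.
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(m)]


def surrogate_test(
    data: TimeSeries | tuple[TimeSeries, TimeSeries],
    statistic: str,
    method: SurrogateSpec,
    spec: EmbeddingSpec | None = None,
    alpha: float = 0.05,
    normalize: bool = True,
) -> TestResult:
    """Run a one-sided surrogate test of IS (univariate) or MIR (bivariate).

    Parameters
    ----------
    data : TimeSeries or (TimeSeries, TimeSeries)
        One series for IS, an ordered pair for MIR.
    statistic : {"IS", "MIR"}
    method : SurrogateSpec
        Surrogate method, ensemble size M, IAAFT iterations and seed.
    spec : EmbeddingSpec, optional
        Memory order q and neighbor count k (default q=2, k=10).
    alpha : float
        One-sided significance level, in (0, 0.5].
    normalize : bool
        Z-score the series before embedding (default, matching KNN practice).
    """
    if statistic not in COMPATIBLE_METHODS:
        raise ValueError(f"statistic must be 'IS' or 'MIR', got {statistic!r}")
    if method.method not in COMPATIBLE_METHODS[statistic]:
        raise ValueError(
            f"surrogate method {method.method!r} is incompatible with statistic "
            f"{statistic!r}; valid: {COMPATIBLE_METHODS[statistic]}"
        )
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    m = method.n_surrogates
    if m < math.ceil(1.0 / alpha) - 1:
        raise ValueError(
            f"too few surrogates for alpha: need M >= {math.ceil(1.0 / alpha) - 1}, got {m}"
        )
    spec = spec or EmbeddingSpec()

    if statistic == "IS":
        if not isinstance(data, TimeSeries):
            raise ValueError("IS test takes a single TimeSeries")
        x = zscore_normalize(data) if normalize else data
        obs = build_univariate_observation(x, spec)
        original = estimate_is(obs, k=spec.k).value
        rngs = _spawn_rngs(method.seed, m)
        if method.method == "shuffle_present":
            surr_vals = [
                estimate_is(shuffle_present(obs, rng), k=spec.k).value for rng in rngs
            ]
        else:  # iaaft
            surr_vals = []
            for rng in rngs:
                s = iaaft(x, iterations=method.iterations, rng=rng)
                surr_vals.append(
                    estimate_is(build_univariate_observation(s, spec), k=spec.k).value
                )
    else:  # MIR
        if not (isinstance(data, tuple) and len(data) == 2):
            raise ValueError("MIR test takes a pair (x, y) of TimeSeries")
        x, y = data
        if normalize:
            x, y = zscore_normalize(x), zscore_normalize(y)
        obs = build_bivariate_observation(x, y, spec)
        original = estimate_mir(obs, k=spec.k).value
        rngs = _spawn_rngs(method.seed, m)
        if method.method == "shuffle_rows":
            surr_vals = [
                estimate_mir(shuffle_rows_block(obs, rng), k=spec.k).value for rng in rngs
            ]
        else:  # iaaft_bivariate
            surr_vals = []
            for rng in rngs:
                sx, sy = iaaft_bivariate(x, y, iterations=method.iterations, rng=rng)
                surr_vals.append(
                    estimate_mir(build_bivariate_observation(sx, sy, spec), k=spec.k).value
                )

    ensemble = SurrogateEnsemble(np.asarray(surr_vals), method, statistic)
    threshold = nearest_rank_percentile(ensemble.values, 1.0 - alpha)
    return TestResult(
        original=original,
        ensemble=ensemble,
        alpha=alpha,
        threshold=threshold,
        reject=bool(original > threshold),
        null_hypothesis=NULL_TAGS[method.method],
    )


def rejection_rate(results) -> float:
    """Fraction of tests that rejected their null hypothesis."""
    results = list(results)
    if not results:
        raise ValueError("empty collection of test results")
    return sum(r.reject for r in results) / len(results)
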