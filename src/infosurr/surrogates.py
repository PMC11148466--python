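"""Surrogate generators embodying four null hypotheses.

Each method produces data that shares every property of the original except
the one under test:

``shuffle_present``
    No self-dependencies (IS = 0): the present column of the univariate
    observation matrix is randomly permuted, destroying present-past
    dependence while keeping the marginal distribution.
``iaaft``
    Purely linear univariate dynamics: iterative amplitude-adjusted Fourier
    transform surrogates preserve the amplitude distribution exactly and the
    power spectrum approximately while randomizing phases.
``shuffle_rows_block``
    No coupling (MIR = 0): the rows of one process's (present + past) block
    of the bivariate observation matrix are jointly permuted, preserving the
    within-process dynamics while destroying cross-process alignment.
``iaaft_bivariate``
    Purely linear coupling: IAAFT with a common per-frequency random phase
    added to both series at initialization, preserving each power spectrum
    and the cross-spectrum (hence all linear coupling) while destroying
    nonlinear structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .embedding import ObservationMatrix, TimeSeries

__all__ = [
    "SurrogateSpec",
    "shuffle_present",
    "iaaft",
    "shuffle_rows_block",
    "iaaft_bivariate",
]

METHODS = ("shuffle_present", "iaaft", "shuffle_rows", "iaaft_bivariate")


@dataclass(frozen=True)
class SurrogateSpec:
    """Which surrogate to build, how many, and from which seed."""

    method: str
    n_surrogates: int = 100
    iterations: int = 7
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown surrogate method {self.method!r}; choose from {METHODS}")
        if self.n_surrogates < 19:
            raise ValueError("need at least 19 surrogates for a meaningful 95th percentile")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def shuffle_present(obs: ObservationMatrix, rng) -> ObservationMatrix:
    """Permute the present column of a univariate observation matrix."""
    if obs.is_bivariate:
        raise ValueError("shuffle_present operates on univariate matrices")
    rng = _as_rng(rng)
    data = obs.data.copy()
    data[:, 0] = rng.permutation(data[:, 0])
    return ObservationMatrix(data, obs.column_roles, obs.source_labels, obs.q)


def shuffle_rows_block(obs: ObservationMatrix, rng, block: str | None = None) -> ObservationMatrix:
    """Jointly permute the rows of one process's block of a bivariate matrix.

    Each row's (present + past) tuple stays intact, so the internal dynamics
    of the shuffled process are preserved; only the alignment with the other
    process — the coupling — is destroyed.  ``block`` selects the process by
    label (default: the first process).  Either choice tests the same null.
    """
    if not obs.is_bivariate:
        raise ValueError("shuffle_rows_block operates on bivariate matrices")
    if block is None:
        block = obs.source_labels[0]
    if block not in obs.source_labels:
        raise ValueError(f"unknown block {block!r}; available: {obs.source_labels}")
    rng = _as_rng(rng)
    data = obs.data.copy()
    cols = obs.columns_of(block)
    data[:, cols] = data[np.ix_(rng.permutation(obs.n_rows), cols)]
    return ObservationMatrix(data, obs.column_roles, obs.source_labels, obs.q)


def _rank_rescale(current: np.ndarray, sorted_values: np.ndarray) -> np.ndarray:
    """Replace ``current`` by the original values, matched by rank.

    Stable argsort breaks ties by first occurrence.
    """
    order = np.argsort(current, kind="stable")
    out = np.empty_like(sorted_values)
    out[order] = sorted_values
    return out


def _iaaft_iterate(
    start: np.ndarray, target_amp: np.ndarray, sorted_values: np.ndarray, iterations: int
) -> np.ndarray:
    y = start
    for _ in range(iterations):
        spec = np.fft.rfft(y)
        phases = np.angle(spec)
        y = np.fft.irfft(target_amp * np.exp(1j * phases), n=sorted_values.size)
        y = _rank_rescale(y, sorted_values)
    return y


def iaaft(series: TimeSeries, iterations: int = 7, rng=None) -> TimeSeries:
    """Univariate IAAFT surrogate.

    Starts from a random permutation of the series, then alternates spectrum
    replacement (impose the original Fourier amplitudes, keep current phases)
    with rank rescaling (impose the original value distribution exactly).
    Returns the rank-rescaled series after ``iterations`` rounds, so the
    amplitude distribution is matched exactly and the spectrum approximately.
    Seven iterations keep the spectral mismatch to a few percent while
    staying cheap.
    """
    x = series.values
    if x.size < 8:
        raise ValueError("IAAFT needs at least 8 samples")
    if np.ptp(x) == 0:
        warnings.warn("constant series: IAAFT surrogate equals the input", stacklevel=2)
        return TimeSeries(x.copy(), label=series.label)
    rng = _as_rng(rng)
    target_amp = np.abs(np.fft.rfft(x))
    sorted_values = np.sort(x)
    start = rng.permutation(x)
    out = _iaaft_iterate(start, target_amp, sorted_values, iterations)
    return TimeSeries(out, label=series.label)


def _common_phase_start(x: np.ndarray, y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    # Same random phase per frequency bin added to both spectra; DC kept at
    # zero and the Nyquist bin (even N) kept real so the inverse is real.
    n = x.size
    fx = np.fft.rfft(x)
    fy = np.fft.rfft(y)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=fx.size)
    phi[0] = 0.0
    if n % 2 == 0:
        phi[-1] = 0.0
    rot = np.exp(1j * phi)
    return np.fft.irfft(fx * rot, n=n), np.fft.irfft(fy * rot, n=n)


def iaaft_bivariate(
    x: TimeSeries, y: TimeSeries, iterations: int = 7, rng=None
) -> tuple[TimeSeries, TimeSeries]:
    """Common-phase bivariate IAAFT surrogate pair.

    Identical to :func:`iaaft` except for the initialization: instead of an
    independent permutation per series, the *same* random phase sequence is
    added to the Fourier phases of both series.  This preserves the
    cross-spectrum (all linear coupling) along with each power spectrum,
    while nonlinear joint structure is destroyed.  The subsequent iterations
    run per series.
    """
    if x.n_samples != y.n_samples:
        raise ValueError("length mismatch between x and y")
    if x.n_samples < 8:
        raise ValueError("IAAFT needs at least 8 samples")
    rng = _as_rng(rng)
    sx, sy = _common_phase_start(x.values, y.values, rng)
    out_x = _iaaft_iterate(sx, np.abs(np.fft.rfft(x.values)), np.sort(x.values), iterations)
    out_y = _iaaft_iterate(sy, np.abs(np.fft.rfft(y.values)), np.sort(y.values), iterations)
    return TimeSeries(out_x, label=x.label), TimeSeries(out_y, label=y.label)
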