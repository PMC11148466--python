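"""Benchmark process generators and linear-Gaussian ground-truth oracles.

Four stochastic/deterministic systems span the test conditions:

* a stochastic AR(2) oscillator with complex-conjugate poles at radius
  ``rho`` and normalized frequency ``f`` (linear, self-dependent),
* the chaotic Henon map observed through additive Gaussian noise
  (nonlinear, self-dependent, tunable SNR),
* a unidirectionally coupled bivariate VAR with lag-2 coupling gain ``C``
  (linear coupling),
* a unidirectionally coupled Henon-Henon map (nonlinear coupling).

For the linear-Gaussian models the information measures have exact values:
the AR(2) information storage is ``0.5 ln(var(X)/var(innovation))`` with the
stationary variance from the Yule-Walker equations, and the VAR mutual
information rate is the integral transform of the squared coherency,
``-(1/4 pi) \\int ln(1 - |coherency|^2) d omega``.  These serve as ground
truth for validating the KNN estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .embedding import TimeSeries

__all__ = [
    "ARSpec",
    "VARSpec",
    "HenonSpec",
    "simulate_ar2",
    "simulate_noisy_henon",
    "simulate_var2",
    "simulate_coupled_henon",
    "theoretical_is_ar2",
    "theoretical_mir_var2",
]

_DIVERGE = 10.0  # |x| beyond this restarts a map trajectory


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ARSpec:
    """AR(2) oscillator: ``X_n = 2 rho cos(2 pi f) X_{n-1} - rho^2 X_{n-2} + e_n``."""

    rho: float
    f: float = 0.3
    n: int = 1000
    n_trans: int = 500
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("unstable: pole radius rho must be in [0, 1)")
        if not 0.0 < self.f < 0.5:
            raise ValueError("normalized frequency f must be in (0, 0.5)")
        if self.n < 1 or self.n_trans < 0:
            raise ValueError("invalid lengths")

    @property
    def a1(self) -> float:
        return 2.0 * self.rho * np.cos(2.0 * np.pi * self.f)

    @property
    def a2(self) -> float:
        return -self.rho**2


@dataclass(frozen=True)
class VARSpec:
    """Bivariate VAR, X driving Y at lag 2 with gain C.

    ``X_n = 2 rho_x cos(2 pi f_x) X_{n-1} - rho_x^2 X_{n-2} + e_n``
    ``Y_n = 2 rho_y cos(2 pi f_y) Y_{n-1} - rho_y^2 Y_{n-2} + C X_{n-2} + xi_n``
    with independent unit-variance Gaussian innovations.
    """

    C: float = 0.0
    rho_x: float = 0.3
    f_x: float = 0.3
    rho_y: float = 0.3
    f_y: float = 0.1
    n: int = 1000
    n_trans: int = 500

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_x < 1.0 and 0.0 <= self.rho_y < 1.0):
            raise ValueError("unstable: pole radii must be in [0, 1)")
        if self.C < 0:
            raise ValueError("coupling C must be >= 0")

    @property
    def x_spec(self) -> ARSpec:
        return ARSpec(self.rho_x, self.f_x, self.n, self.n_trans)

    @property
    def y_spec(self) -> ARSpec:
        return ARSpec(self.rho_y, self.f_y, self.n, self.n_trans)


@dataclass(frozen=True)
class HenonSpec:
    """Henon-map settings; ``sigma`` is an additive-noise *variance* and
    ``C`` the coupling gain of the coupled variant."""

    C: float = 0.0
    sigma: float = 0.0
    n: int = 1000
    n_trans: int = 1000

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise variance sigma must be >= 0")
        if not 0.0 <= self.C <= 0.5:
            raise ValueError("coupling C must be in [0, 0.5] (synchronization above)")
        if self.n_trans < 1:
            raise ValueError("burn-in must be >= 1")


def simulate_ar2(spec: ARSpec, rng) -> TimeSeries:
    """Draw one AR(2) realization (burn-in discarded)."""
    rng = _as_rng(rng)
    total = spec.n + spec.n_trans
    eps = rng.standard_normal(total) * spec.noise_sd
    x = lfilter([1.0], [1.0, -spec.a1, -spec.a2], eps)
    return TimeSeries(x[spec.n_trans :], label="x")


def simulate_var2(spec: VARSpec, rng) -> tuple[TimeSeries, TimeSeries]:
    """Draw one realization of the unidirectionally coupled VAR."""
    rng = _as_rng(rng)
    total = spec.n + spec.n_trans
    eps = rng.standard_normal(total)
    xi = rng.standard_normal(total)
    x = lfilter([1.0], [1.0, -spec.x_spec.a1, -spec.x_spec.a2], eps)
    drive = np.zeros(total)
    drive[2:] = spec.C * x[:-2]
    y = lfilter([1.0], [1.0, -spec.y_spec.a1, -spec.y_spec.a2], xi + drive)
    return (
        TimeSeries(x[spec.n_trans :], label="x"),
        TimeSeries(y[spec.n_trans :], label="y"),
    )


def _iterate_map(step, rng, n: int, n_trans: int, dim: int) -> np.ndarray:
    """Iterate a 2nd-order map with divergence-restart and random ICs.

    Initial conditions are 0.1 plus a seeded uniform jitter in [-0.05, 0.05];
    a trajectory leaving |state| <= 10 is restarted from fresh ICs.
    """
    total = n + n_trans
    for _ in range(100):
        state = np.empty((total, dim))
        state[0] = state[1] = 0.1 + rng.uniform(-0.05, 0.05, size=dim)
        ok = True
        for t in range(2, total):
            state[t] = step(state[t - 1], state[t - 2])
            if np.any(np.abs(state[t]) > _DIVERGE):
                ok = False
                break
        if ok:
            return state[n_trans:]
    raise RuntimeError("map trajectory diverged repeatedly")  # pragma: no cover


def simulate_noisy_henon(spec: HenonSpec, rng) -> TimeSeries:
    """Henon map ``X_n = 1 - 1.4 X_{n-1}^2 + 0.3 X_{n-2}`` observed as
    ``Y = X + noise`` with noise variance ``sigma``."""
    rng = _as_rng(rng)

    def step(s1, s2):
        return np.array([1.0 - 1.4 * s1[0] ** 2 + 0.3 * s2[0]])

    x = _iterate_map(step, rng, spec.n, spec.n_trans, dim=1)[:, 0]
    noise = rng.standard_normal(spec.n) * np.sqrt(spec.sigma)
    return TimeSeries(x + noise, label="y")


def simulate_coupled_henon(spec: HenonSpec, rng) -> tuple[TimeSeries, TimeSeries]:
    """Unidirectionally coupled Henon-Henon maps.

    ``X_n = 1.4 - X_{n-1}^2 + 0.3 X_{n-2}``
    ``Y_n = 1.4 - (C X_{n-1} Y_{n-1} + (1 - C) Y_{n-1}^2) + 0.3 Y_{n-2}``
    """
    rng = _as_rng(rng)
    c = spec.C

    def step(s1, s2):
        x = 1.4 - s1[0] ** 2 + 0.3 * s2[0]
        y = 1.4 - (c * s1[0] * s1[1] + (1.0 - c) * s1[1] ** 2) + 0.3 * s2[1]
        return np.array([x, y])

    out = _iterate_map(step, rng, spec.n, spec.n_trans, dim=2)
    return TimeSeries(out[:, 0], label="x"), TimeSeries(out[:, 1], label="y")


def ar2_stationary_variance(rho: float, f: float, noise_sd: float = 1.0) -> float:
    """Yule-Walker stationary variance of the AR(2) oscillator."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("unstable: rho must be in [0, 1)")
    a1 = 2.0 * rho * np.cos(2.0 * np.pi * f)
    a2 = -(rho**2)
    s2 = noise_sd**2
    return s2 * (1.0 - a2) / ((1.0 + a2) * ((1.0 - a2) ** 2 - a1**2))


def theoretical_is_ar2(rho: float, f: float, noise_sd: float = 1.0) -> float:
    """Exact information storage of the Gaussian AR(2) process, in nats.

    ``S_X = 0.5 ln(var(X) / var(innovation))``; exact for any embedding
    ``q >= 2`` since the process is Markov of order 2.
    """
    var_x = ar2_stationary_variance(rho, f, noise_sd)
    return 0.5 * float(np.log(var_x / noise_sd**2))


def theoretical_mir_var2(spec: VARSpec, n_freq: int = 4096) -> float:
    """Exact mutual information rate of the Gaussian VAR, in nats.

    Computed as ``-(1/4 pi) \\int_{-pi}^{pi} ln(1 - |coherency|^2) d omega``
    by dense trapezoidal quadrature of the model's cross-spectral matrix
    ``S(omega) = H(omega) H(omega)^*`` with ``H = (I - A1 z - A2 z^2)^{-1}``,
    ``z = exp(-i omega)``.
    """
    a1x, a2x = spec.x_spec.a1, spec.x_spec.a2
    a1y, a2y = spec.y_spec.a1, spec.y_spec.a2
    omega = np.linspace(-np.pi, np.pi, n_freq + 1)
    z = np.exp(-1j * omega)
    # A(z) = I - A1 z - A2 z^2 with A1 diagonal, A2 lower-triangular (C at [1,0])
    a = np.zeros((omega.size, 2, 2), dtype=complex)
    a[:, 0, 0] = 1.0 - a1x * z - a2x * z**2
    a[:, 1, 1] = 1.0 - a1y * z - a2y * z**2
    a[:, 1, 0] = -spec.C * z**2
    h = np.linalg.inv(a)
    s = h @ np.conjugate(np.transpose(h, (0, 2, 1)))
    coh2 = np.abs(s[:, 0, 1]) ** 2 / (s[:, 0, 0].real * s[:, 1, 1].real)
    coh2 = np.clip(coh2.real, 0.0, 1.0 - 1e-15)
    integrand = np.log(1.0 - coh2)
    return float(-np.trapezoid(integrand, omega) / (4.0 * np.pi))
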