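"""Nearest-neighbor estimation of entropy, information storage (IS) and
mutual information rate (MIR).

The estimators follow the Kraskov-style construction: a single k-nearest-
neighbor search is performed in the *highest-dimensional* joint space under
the maximum (Chebyshev) norm, and the per-point distances found there are
projected onto every lower-dimensional subspace, where they serve as ranges
for strict neighbor counts.  Keeping one distance scale across all spaces
cancels the dimension-dependent bias that independent searches per space
would introduce.

With ``eps_n`` twice the distance from point ``n`` to its k-th neighbor and
``N_S(n)`` the number of other points of subspace ``S`` strictly within
``eps_n / 2`` of point ``n``:

* information storage of a univariate embedding with rows ``(x_n, x_n^q)``::

      S_X = psi(N) + psi(k) - < psi(N_past + 1) + psi(N_present + 1) >

* mutual information rate of a bivariate embedding::

      I_XY = psi(k) + < psi(N_Xpast + 1) + psi(N_Ypast + 1)
                        - psi(N_X + 1) - psi(N_Y + 1) - psi(N_XYpast + 1) >

  where ``N_X`` counts in the (X present, X past) subspace, ``N_Y``
  analogously for Y, and ``N_XYpast`` in the joint past of both processes.

Both quantities are in nats.  Negative IS/MIR estimates occur for weak or
absent dependence (estimator bias) and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .embedding import ObservationMatrix

__all__ = [
    "InfoEstimate",
    "kth_neighbor_radii",
    "range_counts",
    "kth_neighbor_radii_brute",
    "range_counts_brute",
    "knn_entropy",
    "estimate_is",
    "estimate_mir",
]

# Jitter amplitude, relative to the per-column sample SD, used to break
# exact ties produced by deterministic maps.  Applied only when duplicate
# rows are present, so continuous data is handled untouched.
_JITTER_REL = 1e-10


@dataclass(frozen=True)
class InfoEstimate:
    """A scalar information measure plus the settings that produced it."""

    value: float
    measure: str  # "entropy" | "IS" | "MIR"
    k: int
    q: int | None
    n_points: int

    def __float__(self) -> float:
        return self.value


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, d) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    return pts


def _break_ties(pts: np.ndarray, seed: int) -> np.ndarray:
    """Add seeded uniform jitter if any two rows coincide exactly.

    Deterministic maps can revisit states, giving zero k-th-neighbor
    distances and an undefined ``ln eps``; a jitter of 1e-10 x column SD is
    far below any dynamical scale yet separates ties reproducibly.
    """
    if np.unique(pts, axis=0).shape[0] == pts.shape[0]:
        return pts
    rng = np.random.default_rng(seed)
    sd = pts.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return pts + rng.uniform(-0.5, 0.5, size=pts.shape) * (_JITTER_REL * sd)


def kth_neighbor_radii(points, k: int) -> np.ndarray:
    """Per-point radius: twice the max-norm distance to the k-th neighbor.

    The query point itself is excluded from its own neighbor list.
    """
    pts = _as_points(points)
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    return 2.0 * dist[:, k]


def range_counts(points, radii: np.ndarray) -> np.ndarray:
    """Number of other points strictly within ``radii/2`` of each point.

    ``radii`` must come from the matching full-space query set (same point
    order).  The strict inequality ``dist < radii/2`` is realized exactly in
    floating point by counting ``dist <= nextafter(radii/2, 0)``.
    """
    pts = _as_points(points)
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (pts.shape[0],):
        raise ValueError(
            f"radii length {radii.shape} does not match {pts.shape[0]} points"
        )
    tree = cKDTree(pts)
    r_strict = np.nextafter(radii / 2.0, 0.0)
    r_strict = np.maximum(r_strict, 0.0)
    counts = tree.query_ball_point(pts, r_strict, p=np.inf, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # remove the point itself


def kth_neighbor_radii_brute(points, k: int) -> np.ndarray:
    """O(n^2) reference implementation of :func:`kth_neighbor_radii`."""
    pts = _as_points(points)
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    d = np.max(np.abs(pts[:, None, :] - pts[None, :, :]), axis=2)
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    return 2.0 * d[:, k - 1]


def range_counts_brute(points, radii: np.ndarray) -> np.ndarray:
    """O(n^2) reference implementation of :func:`range_counts`."""
    pts = _as_points(points)
    radii = np.asarray(radii, dtype=float)
    if radii.shape != (pts.shape[0],):
        raise ValueError("radii length mismatch")
    d = np.max(np.abs(pts[:, None, :] - pts[None, :, :]), axis=2)
    np.fill_diagonal(d, np.inf)
    return (d < radii[:, None] / 2.0).sum(axis=1).astype(int)


def knn_entropy(samples, k: int = 10, tie_seed: int = 0) -> InfoEstimate:
    """Differential entropy of a d-dimensional sample, in nats.

    ``H = psi(N) - psi(k) + d < ln eps_n >`` with ``eps_n`` twice the
    max-norm distance to the k-th neighbor.
    """
    pts = _break_ties(_as_points(samples), tie_seed)
    n, d = pts.shape
    radii = kth_neighbor_radii(pts, k)
    if np.any(radii <= 0):
        raise ValueError("zero k-th neighbor distance; sample has unbroken ties")
    value = digamma(n) - digamma(k) + d * np.mean(np.log(radii))
    return InfoEstimate(float(value), "entropy", k, None, n)


def estimate_is(obs: ObservationMatrix, k: int = 10, tie_seed: int = 0) -> InfoEstimate:
    """Information storage of a univariate observation matrix, in nats.

    One neighbor search in the joint (present, past) space; strict range
    counts in the past-only and present-only projections.
    """
    if obs.is_bivariate:
        raise ValueError("estimate_is requires a univariate observation matrix")
    pts = _break_ties(obs.data, tie_seed)
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} embedded rows, got {n}")
    radii = kth_neighbor_radii(pts, k)
    n_past = range_counts(pts[:, 1:], radii)
    n_present = range_counts(pts[:, :1], radii)
    value = (
        digamma(n)
        + digamma(k)
        - np.mean(digamma(n_past + 1) + digamma(n_present + 1))
    )
    return InfoEstimate(float(value), "IS", k, obs.q, n)


def estimate_mir(obs: ObservationMatrix, k: int = 10, tie_seed: int = 0) -> InfoEstimate:
    """Mutual information rate of a bivariate observation matrix, in nats.

    One neighbor search in the full ``2(q+1)``-dimensional joint space; five
    strict range counts in the projections (X past), (Y past),
    (X present+past), (Y present+past) and (X past, Y past).
    """
    if not obs.is_bivariate:
        raise ValueError("estimate_mir requires a bivariate observation matrix")
    pts = _break_ties(obs.data, tie_seed)
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} embedded rows, got {n}")
    lx, ly = obs.source_labels
    ix = obs.columns_of(lx)
    iy = obs.columns_of(ly)
    ix_past, iy_past = ix[1:], iy[1:]
    radii = kth_neighbor_radii(pts, k)
    n_x_past = range_counts(pts[:, ix_past], radii)
    n_y_past = range_counts(pts[:, iy_past], radii)
    n_x_full = range_counts(pts[:, ix], radii)
    n_y_full = range_counts(pts[:, iy], radii)
    n_joint_past = range_counts(pts[:, np.concatenate([ix_past, iy_past])], radii)
    # grouped so the expression is symmetric in X and Y at the bit level
    value = digamma(k) + np.mean(
        (digamma(n_x_past + 1) + digamma(n_y_past + 1))
        - (digamma(n_x_full + 1) + digamma(n_y_full + 1))
        - digamma(n_joint_past + 1)
    )
    return InfoEstimate(float(value), "MIR", k, obs.q, n)
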