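"""Histogram binning of z-values and design matrices for the spline fit.

The mixture density f(z) of the z-values is estimated by Poisson regression
on histogram counts: with J equal-width bins of width ``Delta`` and midpoints
``x_j``, the counts ``m_j`` are modelled as Po(nu_j) with
``nu_j = N * Delta * f(x_j)`` and ``log(nu_j) = s(x_j; theta)`` a natural
cubic spline.  The empirical-null component is a quadratic
``q(x; beta) = beta_1 + beta_2 x + beta_3 x^2`` anchored on the bins whose
midpoints fall in a user-chosen null interval ``[a, b]``.

This module builds the spline basis matrix Gamma, the quadratic basis Omega,
their null-interval row-submatrices Gamma0/Omega0, and the linear constraint
matrix ``C = Gamma - Omega (Omega0' Omega0)^{-1} Omega0' Gamma0`` whose
non-negativity ``C theta >= 0`` expresses that the fitted log-mixture lies
above its own best quadratic approximation at every bin midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Histogram", "SplineDesign", "bin_z", "natural_spline_basis", "build_design"]


@dataclass(frozen=True)
class Histogram:
    """Binned z-values: Poisson-regression data for the density fit."""

    counts: np.ndarray      # (J,) nonnegative ints
    midpoints: np.ndarray   # (J,) equally spaced bin midpoints
    width: float            # bin width Delta
    total: int              # N = sum of counts

    @property
    def nbins(self) -> int:
        return int(self.counts.size)

    def density(self) -> np.ndarray:
        """Empirical density per bin, counts / (N * Delta)."""
        return self.counts / (self.total * self.width)


def bin_z(z, bins: int = 50, range: tuple[float, float] | None = None) -> Histogram:
    """Bin z-values into ``bins`` equal-width bins.

    Bins are half-open ``[lo, hi)`` with the last bin closed (the numpy
    convention).  The range defaults to ``[min(z), max(z)]``.

    Parameters
    ----------
    z : array-like
        z-values (probit-transformed test statistics).
    bins : int
        Number of bins J, at least 10.
    range : (float, float), optional
        Binning range; values outside are dropped.
    """
    z = np.asarray(z, dtype=float).ravel()
    if bins < 10:
        raise ValueError(f"need at least 10 bins, got {bins}")
    if z.size == 0 or not np.all(np.isfinite(z)):
        raise ValueError("z must be a non-empty finite vector")
    if range is None:
        lo, hi = float(z.min()), float(z.max())
    else:
        lo, hi = map(float, range)
    if not hi > lo:
        raise ValueError(f"degenerate binning range [{lo}, {hi}]")
    counts, edges = np.histogram(z, bins=bins, range=(lo, hi))
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no z-values fall inside the binning range")
    midpoints = 0.5 * (edges[:-1] + edges[1:])
    width = float(edges[1] - edges[0])
    return Histogram(counts=counts, midpoints=midpoints, width=width, total=total)


def natural_spline_basis(x, knots) -> np.ndarray:
    """Natural cubic spline basis evaluated at ``x``.

    With knots ``h_1 < ... < h_D`` the D basis functions are::

        B_1(x) = 1,   B_2(x) = x,
        B_d(x) = phi_{d-2}(x) - phi_{D-1}(x),          d = 3..D,
        phi_d(x) = [(x-h_d)_+^3 - (x-h_D)_+^3] / (h_D - h_d),

    where ``(u)_+ = max(u, 0)``.  The span is linear outside ``[h_1, h_D]``
    (every phi vanishes left of h_1; the cubic and quadratic terms cancel
    right of h_D), which is what makes the spline "natural".

    Returns an ``(len(x), D)`` matrix.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    h = np.asarray(knots, dtype=float)
    D = h.size
    if D < 3:
        raise ValueError(f"need at least 3 knots, got {D}")
    if np.any(np.diff(h) <= 0):
        raise ValueError("knots must be strictly increasing (no duplicates)")

    def phi(k: int) -> np.ndarray:  # k is a 0-based knot index
        a = np.clip(x - h[k], 0.0, None) ** 3
        b = np.clip(x - h[-1], 0.0, None) ** 3
        return (a - b) / (h[-1] - h[k])

    B = np.empty((x.size, D))
    B[:, 0] = 1.0
    B[:, 1] = x
    tail = phi(D - 2)  # phi_{D-1} in 1-based indexing
    for d in np.arange(3, D + 1):
        B[:, d - 1] = phi(d - 3) - tail
    return B


@dataclass(frozen=True)
class SplineDesign:
    """Design of the constrained Poisson-spline optimisation.

    ``beta_map`` is the 3 x D matrix ``(Omega0' Omega0)^{-1} Omega0' Gamma0``
    mapping spline coefficients theta to the coefficients beta of the best
    least-squares quadratic approximation of s(.; theta) on the null bins.
    ``constraint`` is ``C = Gamma - Omega @ beta_map``; the requirement that
    the null component never exceed the mixture is ``C theta >= 0``.
    """

    knots: np.ndarray        # (D,)
    gamma: np.ndarray        # (J, D) spline basis at bin midpoints
    omega: np.ndarray        # (J, 3) rows (1, x_j, x_j^2)
    null_bins: np.ndarray    # indices of bins with midpoint in [a, b]
    gamma0: np.ndarray       # rows of gamma at null bins
    omega0: np.ndarray       # rows of omega at null bins
    beta_map: np.ndarray     # (3, D)
    constraint: np.ndarray   # (J, D)
    null_interval: tuple[float, float]

    @property
    def df(self) -> int:
        return int(self.knots.size)

    def beta_from_theta(self, theta) -> np.ndarray:
        """Quadratic coefficients of the null component implied by theta."""
        return self.beta_map @ np.asarray(theta, dtype=float)


def _uniform_knots(x: np.ndarray, df: int) -> np.ndarray:
    return np.linspace(x[0], x[-1], df)


def _quantile_knots(x: np.ndarray, counts: np.ndarray, df: int) -> np.ndarray:
    # count-weighted quantiles of the midpoints, endpoints pinned to the
    # histogram bracket h_1 = x_1, h_D = x_J
    cw = np.cumsum(counts) / counts.sum()
    probs = np.linspace(0.0, 1.0, df)
    h = np.interp(probs, cw, x)
    h[0], h[-1] = x[0], x[-1]
    if np.any(np.diff(h) <= 0):
        raise ValueError("quantile knots collapse (counts too concentrated); "
                         "use knots='uniform' or fewer df")
    return h


def build_design(hist: Histogram, df: int,
                 null_interval: tuple[float, float],
                 knots: str = "uniform") -> SplineDesign:
    """Construct spline/quadratic design matrices and the constraint matrix.

    Parameters
    ----------
    hist : Histogram
        Binned z-values.
    df : int
        Number of spline basis functions D (equals the number of knots).
    null_interval : (a, b)
        Interval assumed to contain essentially only null z-values.  A bin
        belongs to the null set iff its midpoint lies in the closed interval.
    knots : {"uniform", "quantile"}
        Knot placement over [x_1, x_J].
    """
    x = hist.midpoints
    J = x.size
    if df < 3:
        raise ValueError(f"spline df must be >= 3, got {df}")
    if df > J:
        raise ValueError(f"spline df {df} exceeds the number of bins {J}")
    a, b = map(float, null_interval)
    if not b > a:
        raise ValueError(f"invalid null interval [{a}, {b}]")

    if knots == "uniform":
        h = _uniform_knots(x, df)
    elif knots == "quantile":
        h = _quantile_knots(x, hist.counts, df)
    else:
        raise ValueError(f"unknown knot rule {knots!r}")

    gamma = natural_spline_basis(x, h)
    omega = np.column_stack([np.ones(J), x, x * x])
    null_bins = np.nonzero((x >= a) & (x <= b))[0]
    if null_bins.size < 4:
        raise ValueError(
            f"null interval [{a}, {b}] covers only {null_bins.size} bin "
            "midpoints; need at least 4 for an over-determined quadratic fit")
    if null_bins[0] == 0 or null_bins[-1] == J - 1:
        warnings.warn(
            "null interval reaches the edge of the histogram; the natural "
            "spline is linear beyond its boundary knots, so a constrained "
            "fit cannot carry quadratic curvature there and may degenerate "
            "(beta_3 -> 0) — choose [a, b] interior to the z range")
    gamma0 = gamma[null_bins]
    omega0 = omega[null_bins]
    if np.linalg.matrix_rank(omega0) < 3:
        raise ValueError("quadratic design singular on the null bins "
                         "(fewer than 3 distinct midpoints in [a, b])")
    # beta_map solves min_B || Omega0 @ B - Gamma0 ||_F
    beta_map, *_ = np.linalg.lstsq(omega0, gamma0, rcond=None)
    constraint = gamma - omega @ beta_map
    return SplineDesign(knots=h, gamma=gamma, omega=omega, null_bins=null_bins,
                        gamma0=gamma0, omega0=omega0, beta_map=beta_map,
                        constraint=constraint, null_interval=(a, b))
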