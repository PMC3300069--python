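"""Estimators for the two-component empirical-Bayes mixture and its null.

Three routes to the empirical null N(delta, sigma^2) with prior weight p0:

* **CME** (central matching): fit the log mixture density by an
  *unconstrained* Poisson spline regression, then fit a quadratic to the
  spline over the null bins by least squares.
* **MLE**: maximum likelihood for (delta, sigma, p0) on the z-values inside
  the null interval, treating the non-null density as zero there.
* **Constrained** (the method this package exists for): estimate mixture and
  null *simultaneously* — maximise the Poisson likelihood of the histogram
  counts subject to the linear constraint C theta >= 0, which forces the
  fitted log mixture to lie on or above its own quadratic (null)
  approximation at every bin midpoint.  Each iteratively re-weighted
  least-squares (IRLS) step then becomes an inequality-constrained weighted
  least-squares problem, a convex QP solved exactly through its dual
  non-negative least-squares formulation.

All fits run on a :class:`~gelfdr.design.Histogram` plus a
:class:`~gelfdr.design.SplineDesign`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .design import Histogram, SplineDesign, bin_z, build_design, natural_spline_basis

__all__ = [
    "MixtureFit", "NullParams",
    "poisson_deviance", "fit_poisson_spline", "fit_constrained", "fit_cme",
    "cme_quadratic", "extract_null_params", "mle_null", "select_df_aic",
    "default_null_interval",
]

# linear-predictor bound: exp(30) ~ 1e13 dwarfs any realistic bin count, and
# exp(-30) keeps weights/working responses finite for empty tail bins
_ETA_MAX = 30.0


@dataclass
class MixtureFit:
    """Result of a Poisson spline fit to the z-value histogram.

    ``theta`` are the natural-cubic-spline coefficients of the log mixture
    ``s(x; theta)``; ``beta`` (when present) the quadratic coefficients of
    the log null component ``q(x; beta)``, both on the log-count scale, i.e.
    offset by log(N*Delta) from the log densities.
    """

    method: str                  # unconstrained | cme | constrained
    theta: np.ndarray
    beta: np.ndarray | None
    nu: np.ndarray               # fitted Poisson means per bin
    deviance: float
    iterations: int
    converged: bool
    hist: Histogram
    design: SplineDesign

    def log_mixture(self, z) -> np.ndarray:
        """s(z; theta) = log(N Delta f(z)), natural-linear beyond the knots."""
        return natural_spline_basis(z, self.design.knots) @ self.theta

    def log_null(self, z) -> np.ndarray:
        """q(z; beta) = log(N Delta p0 f0(z)); requires a fitted beta."""
        if self.beta is None:
            raise ValueError(f"{self.method!r} fit carries no null quadratic; "
                             "use fit_constrained or fit_cme")
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return self.beta[0] + self.beta[1] * z + self.beta[2] * z * z

    def null_params(self) -> "NullParams":
        """Interpretable (delta, sigma, p0) of the fitted null component."""
        if self.beta is None:
            raise ValueError("fit carries no null quadratic")
        return extract_null_params(self.beta, self.hist.total, self.hist.width)


@dataclass(frozen=True)
class NullParams:
    """Empirical null N(delta, sigma^2) with prior null proportion p0.

    ``p0`` is capped at 1; ``p0_raw`` keeps the uncapped value so that the
    (undesirable but possible) p0 > 1 outcome of unconstrained estimation
    remains reportable.
    """

    delta: float
    sigma: float
    p0: float
    p0_raw: float


def poisson_deviance(m, nu) -> float:
    """Poisson deviance 2 * sum{ m log m - m - (m log nu - nu) }.

    Uses the 0*log(0) = 0 convention for empty bins.  Zero iff nu == m
    elementwise.
    """
    m = np.asarray(m, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("fitted means must be strictly positive")
    return float(2.0 * np.sum(special.xlogy(m, m) - m - (special.xlogy(m, nu) - nu)))


def _nnls(A: np.ndarray, y: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Lawson–Hanson active-set solver for min_{x >= 0} ||A x - y||_2.

    Handles rank-deficient passive sets through least-squares subproblems.
    Written in-house because it must solve wide, heavily rank-deficient
    systems (the QP dual below has one variable per histogram bin but rank
    at most the spline df) to near machine precision.
    """
    m, n = A.shape
    if max_iter is None:
        max_iter = 5 * n
    x = np.zeros(n)
    P = np.zeros(n, dtype=bool)
    w = A.T @ y
    tol = 10 * np.finfo(float).eps * np.linalg.norm(A, 1) * (m + n)
    for _ in range(max_iter):
        if P.all() or (w[~P] <= tol * max(1.0, np.abs(w).max())).all():
            break
        j = np.flatnonzero(~P)[np.argmax(w[~P])]
        P[j] = True
        while True:
            s, *_ = np.linalg.lstsq(A[:, P], y, rcond=None)
            if s.size and s.min() <= 0:
                xp = x[P]
                neg = s <= 0
                alpha = np.min(xp[neg] / (xp[neg] - s[neg]))
                x[P] = xp + alpha * (s - xp)
                P[np.flatnonzero(P)[x[P] <= 1e-14]] = False
                x[~P] = 0.0
            else:
                x[P] = s
                x[~P] = 0.0
                break
        w = A.T @ (y - A @ x)
    return x


def _constrained_wls(gamma: np.ndarray, w: np.ndarray, mtilde: np.ndarray,
                     C: np.ndarray | None) -> np.ndarray:
    """Solve min_theta sum_j w_j (gamma_j' theta - mtilde_j)^2 [s.t. C theta >= 0].

    The constrained case is a convex QP, min 1/2 theta'H theta - g'theta with
    H = Gamma'WGamma, g = Gamma'W mtilde.  Its Lagrangian dual in the
    multipliers lambda >= 0 is

        min_{lambda >= 0} || A lambda + b ||^2,   A = L^{-1} C',  b = L^{-1} g,

    where H = LL' (Cholesky) — a non-negative least-squares problem solved
    by the Lawson–Hanson algorithm; the primal solution is recovered as
    theta = L'^{-1}(b + A lambda).  theta = 0 is always feasible, so the
    problem cannot be infeasible; if the recovered primal nevertheless
    violates the constraints beyond tolerance (never observed), an
    interior-point solve is used as a safety net.
    """
    H = gamma.T @ (w[:, None] * gamma)
    g = gamma.T @ (w * mtilde)
    if C is None:
        return cho_solve(cho_factor(H), g)
    try:
        L = cholesky(H, lower=True)
    except np.linalg.LinAlgError:
        H = H + (1e-10 * np.trace(H) / H.shape[0]) * np.eye(H.shape[0])
        L = cholesky(H, lower=True)
    b = solve_triangular(L, g, lower=True)
    A = solve_triangular(L, C.T, lower=True)
    lam = _nnls(A, -b)
    theta = solve_triangular(L.T, b + A @ lam, lower=False)
    if (C @ theta).min() < -1e-8:  # pragma: no cover - safety net
        res = optimize.minimize(
            lambda t: 0.5 * t @ H @ t - g @ t, np.zeros(H.shape[0]),
            jac=lambda t: H @ t - g, hess=lambda t: H,
            method="trust-constr",
            constraints=[optimize.LinearConstraint(C, 0.0, np.inf)],
            options={"gtol": 1e-12, "xtol": 1e-14})
        theta = res.x
    return theta


def _fit_irls(hist: Histogram, design: SplineDesign, constrained: bool,
              tolerance: float = 1e-8, max_iter: int = 100) -> MixtureFit:
    m = hist.counts.astype(float)
    nu = (m + m.mean()) / 2.0
    C = design.constraint if constrained else None

    def nu_of(th):
        return np.exp(np.clip(design.gamma @ th, -_ETA_MAX, _ETA_MAX))

    dev = np.inf
    theta = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = nu
        mtilde = np.log(nu) + (m - nu) / nu
        cand = _constrained_wls(design.gamma, w, mtilde, C)
        new_dev = poisson_deviance(m, nu_of(cand))
        # the (constrained) Newton step is not monotone in the deviance;
        # halve back toward the previous iterate (feasible set is convex,
        # so halved steps remain feasible) until the deviance improves
        halvings = 0
        while theta is not None and new_dev > dev + 1e-12 and halvings < 30:
            cand = 0.5 * (cand + theta)
            new_dev = poisson_deviance(m, nu_of(cand))
            halvings += 1
        theta = cand
        nu = nu_of(theta)
        old_dev, dev = dev, new_dev
        if abs(dev - old_dev) <= tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(f"IRLS did not converge in {max_iter} iterations "
                      f"(|deviance change| = {abs(dev - old_dev):.3g})")
    beta = design.beta_from_theta(theta) if constrained else None
    return MixtureFit(method="constrained" if constrained else "unconstrained",
                      theta=theta, beta=beta, nu=nu, deviance=dev,
                      iterations=it, converged=converged,
                      hist=hist, design=design)


def fit_poisson_spline(hist: Histogram, design: SplineDesign,
                       tolerance: float = 1e-8, max_iter: int = 100) -> MixtureFit:
    """Unconstrained Poisson spline regression of log nu_j = s(x_j; theta).

    Standard IRLS for the Poisson GLM with log link: weights w_j = nu_j and
    working response mtilde_j = log nu_j + (m_j - nu_j)/nu_j, iterated to a
    deviance change below ``tolerance``.
    """
    return _fit_irls(hist, design, constrained=False,
                     tolerance=tolerance, max_iter=max_iter)


def fit_constrained(hist: Histogram, design: SplineDesign,
                    tolerance: float = 1e-8, max_iter: int = 100) -> MixtureFit:
    """Simultaneous mixture/null fit under C theta >= 0.

    Maximises the Poisson likelihood subject to the fitted log mixture lying
    above its own quadratic null approximation at every bin midpoint, so the
    implied local fdr never exceeds 1 there.  theta = 0 is always feasible
    (C 0 = 0), so the QP subproblems cannot be infeasible.
    """
    fit = _fit_irls(hist, design, constrained=True,
                    tolerance=tolerance, max_iter=max_iter)
    slack = design.constraint @ fit.theta
    if slack.min() < -1e-8:
        warnings.warn(f"constraint violated beyond tolerance: "
                      f"min(C theta) = {slack.min():.3g}")
    return fit


def cme_quadratic(fit: MixtureFit, design: SplineDesign | None = None) -> np.ndarray:
    """Central-matching quadratic: least-squares fit of a parabola to the
    spline log-density over the null bins, beta = (Omega0'Omega0)^{-1} Omega0' Gamma0 theta."""
    design = design if design is not None else fit.design
    return design.beta_from_theta(fit.theta)


def fit_cme(hist: Histogram, design: SplineDesign,
            tolerance: float = 1e-8, max_iter: int = 100) -> MixtureFit:
    """Unconstrained spline fit with the central-matching quadratic attached."""
    fit = fit_poisson_spline(hist, design, tolerance=tolerance, max_iter=max_iter)
    fit.beta = cme_quadratic(fit, design)
    fit.method = "cme"
    return fit


def extract_null_params(beta, total: int, width: float) -> NullParams:
    """Invert the quadratic log-null for (delta, sigma, p0).

    On the fitted count scale, q(z) = log(N Delta) + log(p0 f0(z)) with
    f0 = N(delta, sigma^2), so::

        sigma^2 = -1 / (2 beta_3)
        delta   = beta_2 sigma^2
        log p0  = beta_1 - log(N Delta) + delta^2/(2 sigma^2)
                  + 1/2 log(2 pi sigma^2)

    ``beta_3 >= 0`` means the fitted central curvature is not concave and no
    normal null is identifiable from this fit.
    """
    b1, b2, b3 = np.asarray(beta, dtype=float)
    if not b3 < 0:
        raise ValueError(f"non-negative curvature beta_3 = {b3:.4g}: "
                         "null parameters not identifiable")
    sigma2 = -1.0 / (2.0 * b3)
    sigma = float(np.sqrt(sigma2))
    delta = float(b2 * sigma2)
    log_p0 = b1 - np.log(total * width) + delta ** 2 / (2.0 * sigma2) \
        + 0.5 * np.log(2.0 * np.pi * sigma2)
    p0_raw = float(np.exp(log_p0))
    return NullParams(delta=delta, sigma=sigma, p0=min(p0_raw, 1.0), p0_raw=p0_raw)


def mle_null(z, null_interval: tuple[float, float],
             p0_mode: str = "joint") -> NullParams:
    """Maximum-likelihood empirical null from the z-values in [a, b].

    Assumes the non-null density vanishes on [a, b].  With N0 z-values inside
    the interval, P0 = Phi((b-delta)/sigma) - Phi((a-delta)/sigma) and mixing
    weight theta = p0 * P0, the log likelihood is::

        N0 log(theta) + (N - N0) log(1 - theta)
        + sum_{z_i in [a,b]} [ log phi_{delta,sigma}(z_i) - log P0 ]

    ``p0_mode="joint"`` maximises over (delta, log sigma, logit p0) jointly;
    ``p0_mode="plugin"`` first fits the truncated normal (delta, sigma) and
    then sets p0 = N0 / (N * P0).  p0 is capped at 1 (raw value retained).
    """
    z = np.asarray(z, dtype=float).ravel()
    a, b = map(float, null_interval)
    inside = z[(z >= a) & (z <= b)]
    N, N0 = z.size, inside.size
    if N0 < 10:
        raise ValueError(f"only {N0} z-values in [{a}, {b}]; need >= 10")
    if p0_mode not in ("joint", "plugin"):
        raise ValueError(f"unknown p0_mode {p0_mode!r}")

    def _p0_of(delta, sigma):
        return stats.norm.cdf((b - delta) / sigma) - stats.norm.cdf((a - delta) / sigma)

    def negloglik(params):
        delta, log_sigma, logit_p0 = params
        sigma = np.exp(log_sigma)
        P0 = _p0_of(delta, sigma)
        if P0 <= 0:
            return np.inf
        trunc = np.sum(stats.norm.logpdf(inside, delta, sigma)) - N0 * np.log(P0)
        if p0_mode == "plugin":
            return -trunc
        p0 = special.expit(logit_p0)
        mix = np.clip(p0 * P0, 1e-12, 1.0 - 1e-12)
        return -(N0 * np.log(mix) + (N - N0) * np.log1p(-mix) + trunc)

    d0 = float(np.median(inside))
    s0 = float(np.std(inside)) or 1.0
    p_start = np.clip(N0 / (N * _p0_of(d0, s0)), 0.05, 0.95)
    x0 = np.array([d0, np.log(s0), special.logit(p_start)])
    res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 5000})
    if not res.success:
        warnings.warn(f"MLE optimiser did not report convergence: {res.message}")
    delta, log_sigma, logit_p0 = res.x
    sigma = float(np.exp(log_sigma))
    if p0_mode == "joint":
        p0_raw = float(special.expit(logit_p0))
    else:
        p0_raw = float(N0 / (N * _p0_of(delta, sigma)))
    return NullParams(delta=float(delta), sigma=sigma,
                      p0=min(p0_raw, 1.0), p0_raw=p0_raw)


def select_df_aic(hist: Histogram, null_interval: tuple[float, float],
                  df_range=range(4, 11), constrained: bool = True,
                  knots: str = "uniform", tolerance: float = 1e-8,
                  max_iter: int = 100) -> tuple[MixtureFit, pd.DataFrame]:
    """Choose the spline df by minimising AIC = deviance + 2 * df.

    Fits every df in ``df_range``; ties break toward the smaller df.  Returns
    the winning fit together with the per-df table (df, deviance, aic,
    converged).  Non-convergent fits are recorded but never selected unless
    no fit converged, in which case a RuntimeError is raised.
    """
    rows, fits = [], {}
    for D in sorted(df_range):
        try:
            d = build_design(hist, D, null_interval, knots=knots)
            f = _fit_irls(hist, d, constrained=constrained,
                          tolerance=tolerance, max_iter=max_iter)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"df": D, "deviance": np.nan, "aic": np.nan,
                         "converged": False, "error": str(exc)})
            continue
        fits[D] = f
        rows.append({"df": D, "deviance": f.deviance,
                     "aic": f.deviance + 2.0 * D,
                     "converged": f.converged, "error": ""})
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no spline df produced a convergent fit")
    best_df = int(ok.loc[ok["aic"].idxmin(), "df"])  # idxmin keeps first = smallest df
    best = fits[best_df]
    if constrained and best.beta is None:
        best.beta = best.design.beta_from_theta(best.theta)
    return best, table


def default_null_interval(z) -> tuple[float, float]:
    """Heuristic [a, b] when none is supplied: histogram mode +/- 1.6 robust SD.

    The robust SD is 1.4826 * MAD.  This is a convenience only — analyses
    should set the null interval explicitly from inspection of the histogram.
    """
    z = np.asarray(z, dtype=float).ravel()
    hist = bin_z(z, bins=min(50, max(10, z.size // 5)))
    mode = float(hist.midpoints[np.argmax(hist.counts)])
    scale = 1.4826 * float(np.median(np.abs(z - np.median(z))))
    if scale == 0:
        raise ValueError("z-values have zero spread")
    return (mode - 1.6 * scale, mode + 1.6 * scale)
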