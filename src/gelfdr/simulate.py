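"""Synthetic data and replicate studies for the two-component model.

Two generators:

* ``simulate_z`` draws z-values from the two-normal validation model —
  ``n_null`` draws from N(null_mean, null_sd^2) followed by ``n_alt`` draws
  from N(alt_mean, alt_sd^2).  The default configuration (5000 null from
  N(-1, 1), 500 non-null from N(3, 1), null proportion 10/11, null interval
  [-2, 0]) is the study condition the replicate harness summarises.
* ``simulate_quant_table`` builds a balanced 4 x n x K factorial
  quantification table from the linear model in :mod:`gelfdr.teststats`,
  with a configurable sparse set of truly-affected proteins, so the whole
  pipeline (table -> t -> z -> fit -> fdr) is exercisable end to end.

``run_replicates`` repeats simulate/bin/fit/extract over seeded replicates
and aggregates the null-parameter estimates and local-fdr accuracy per
method, mirroring a bias/SD simulation study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import bin_z, build_design
from .estimators import (MixtureFit, cme_quadratic, fit_cme, fit_constrained,
                         select_df_aic)
from .localfdr import local_fdr_curve
from .teststats import EFFECT_SIGNS, QuantTable

__all__ = ["SimulationConfig", "ReplicateSummary", "PROBE_Z",
           "simulate_z", "true_local_fdr", "true_tail_fdr",
           "run_replicates", "simulate_quant_table"]

# right-tail probes at which fdr accuracy is scored
PROBE_Z = (2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Two-normal z-value simulation study, defaults = the validation model."""

    n_null: int = 5000
    n_alt: int = 500
    null_mean: float = -1.0
    null_sd: float = 1.0
    alt_mean: float = 3.0
    alt_sd: float = 1.0
    bins: int = 100
    null_interval: tuple[float, float] = (-2.0, 0.0)
    df: int | None = None                 # fixed spline df; None -> AIC
    df_range: tuple[int, int] = (4, 10)   # inclusive AIC search bracket
    replicates: int = 100
    base_seed: int = 0

    def __post_init__(self):
        if self.n_null < 0 or self.n_alt < 0 or self.n_null + self.n_alt < 100:
            raise ValueError("need n_null + n_alt >= 100 nonnegative draws")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def p0(self) -> float:
        """True null proportion n_null / (n_null + n_alt)."""
        return self.n_null / (self.n_null + self.n_alt)

    @property
    def total(self) -> int:
        return self.n_null + self.n_alt


def simulate_z(config: SimulationConfig, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw one replicate; returns (z, is_null) with null draws first."""
    rng = np.random.default_rng(seed)
    z = np.concatenate([
        rng.normal(config.null_mean, config.null_sd, config.n_null),
        rng.normal(config.alt_mean, config.alt_sd, config.n_alt),
    ])
    is_null = np.zeros(config.total, dtype=bool)
    is_null[:config.n_null] = True
    return z, is_null


def true_local_fdr(z, config: SimulationConfig) -> np.ndarray:
    """Closed-form fdr of the two-normal model,
    p0 phi0(z) / [p0 phi0(z) + (1-p0) phi1(z)]."""
    z = np.asarray(z, dtype=float)
    p0 = config.p0
    null = p0 * stats.norm.pdf(z, config.null_mean, config.null_sd)
    alt = (1.0 - p0) * stats.norm.pdf(z, config.alt_mean, config.alt_sd)
    return null / (null + alt)


def true_tail_fdr(z0: float, config: SimulationConfig, side: str = "right") -> float:
    """Closed-form tail FDR E_f{fdr(Z) | tail}: the null tail mass over the
    mixture tail mass."""
    p0 = config.p0
    if side == "right":
        null = stats.norm.sf(z0, config.null_mean, config.null_sd)
        alt = stats.norm.sf(z0, config.alt_mean, config.alt_sd)
    elif side == "left":
        null = stats.norm.cdf(z0, config.null_mean, config.null_sd)
        alt = stats.norm.cdf(z0, config.alt_mean, config.alt_sd)
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return float(p0 * null / (p0 * null + (1.0 - p0) * alt))


@dataclass
class ReplicateSummary:
    """Aggregates over seeded replicates of the simulation study.

    ``params``: per (method, parameter) mean, SD and Monte-Carlo SE of the
    null-parameter estimates.  ``probes``: per (method, z) mean/SD of
    fdr-hat(z) with the closed-form truth and the mean/truth ratio.
    ``fdr_exceeds_one``: per-method count of replicates whose *unclipped*
    fdr-hat exceeds 1 at some bin midpoint.  ``n_failed`` counts replicates
    excluded because a fit or extraction step errored.
    """

    config: SimulationConfig
    params: pd.DataFrame
    probes: pd.DataFrame
    per_replicate: pd.DataFrame
    fdr_exceeds_one: dict[str, int]
    n_failed: int
    failures: list[str] = field(default_factory=list)


def _fit_one(hist, config: SimulationConfig, method: str) -> MixtureFit:
    constrained = method == "constrained"
    if config.df is not None:
        design = build_design(hist, config.df, config.null_interval)
        fit = fit_constrained(hist, design) if constrained \
            else fit_cme(hist, design)
    else:
        lo, hi = config.df_range
        fit, _ = select_df_aic(hist, config.null_interval,
                               df_range=range(lo, hi + 1),
                               constrained=constrained)
        if not constrained:
            fit.beta = cme_quadratic(fit)
            fit.method = "cme"
    return fit


def run_replicates(config: SimulationConfig,
                   methods: tuple[str, ...] = ("constrained", "cme")) -> ReplicateSummary:
    """Seeded replicate study of null-parameter and local-fdr estimation.

    Replicate r uses seed ``base_seed + r`` so each replicate is
    independently reproducible.  Per replicate and method the fitted null
    parameters (delta, sigma, p0) and fdr-hat at the probe z-values are
    recorded; summaries report means, SDs and Monte-Carlo standard errors.
    """
    rows, failures = [], []
    exceeds = {m: 0 for m in methods}
    for r in range(1, config.replicates + 1):
        seed = config.base_seed + r
        z, _ = simulate_z(config, seed)
        hist = bin_z(z, bins=config.bins)
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = _fit_one(hist, config, method)
                    np_ = fit.null_params()
                    raw = local_fdr_curve(fit, hist.midpoints, clip=False)
                    probes = local_fdr_curve(fit, np.array(PROBE_Z))
            except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
                failures.append(f"rep {r} method {method}: {exc}")
                continue
            if raw.max() > 1.0 + 1e-8:
                exceeds[method] += 1
            row = {"rep": r, "seed": seed, "method": method,
                   "delta": np_.delta, "sigma": np_.sigma,
                   "p0": np_.p0, "p0_raw": np_.p0_raw,
                   "df": fit.design.df, "deviance": fit.deviance,
                   "converged": fit.converged,
                   "max_fdr_mid": float(raw.max())}
            row.update({f"fdr_at_{p:g}": float(v)
                        for p, v in zip(PROBE_Z, probes)})
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise RuntimeError("every replicate failed: " + "; ".join(failures[:5]))

    R = config.replicates
    prows = []
    for method, grp in per_rep.groupby("method"):
        for par in ("delta", "sigma", "p0"):
            vals = grp[par].to_numpy()
            prows.append({"method": method, "param": par,
                          "mean": vals.mean(),
                          "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                          "se": (vals.std(ddof=1) / np.sqrt(vals.size))
                                if vals.size > 1 else np.nan,
                          "n": vals.size})
    params = pd.DataFrame(prows).set_index(["method", "param"])

    qrows = []
    for method, grp in per_rep.groupby("method"):
        for p in PROBE_Z:
            vals = grp[f"fdr_at_{p:g}"].to_numpy()
            truth = float(true_local_fdr(p, config))
            qrows.append({"method": method, "z": p,
                          "mean": vals.mean(),
                          "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                          "true_fdr": truth,
                          "ratio": vals.mean() / truth,
                          "n": vals.size})
    probes = pd.DataFrame(qrows).set_index(["method", "z"])

    return ReplicateSummary(config=config, params=params, probes=probes,
                            per_replicate=per_rep, fdr_exceeds_one=exceeds,
                            n_failed=len(failures), failures=failures)


def simulate_quant_table(n_proteins: int = 147, n_replicates: int = 3,
                         n_altered: int = 11, effect: str = "treatment",
                         effect_size: float = 1.0, noise_sd: float = 0.3,
                         seed: int = 0, baseline: float = 10.0,
                         gel_effect_sd: float = 0.0,
                         ) -> tuple[QuantTable, pd.DataFrame]:
    """Balanced factorial table with a sparse set of truly-affected proteins.

    A seeded subset of ``n_altered`` proteins carries the chosen effect at
    size ``effect_size``; everything else is pure noise N(0, noise_sd^2).
    ``gel_effect_sd`` adds a random intercept per *gel* (each group x
    replicate image), shared by all proteins on that gel.  Because these
    offsets are common to whole images they do not average out across
    proteins: they shift every contrast coherently and inflate the pooled
    variance, so the downstream z-values acquire a non-theoretical null —
    the same mechanism (unobserved per-image covariates, correlated tests)
    that displaces empirical nulls in real gel sets.  Note that a constant
    shift or a pure rescaling of the noise would cancel exactly in the
    t statistics, which is why the perturbation must live at the gel level.

    Returns the table and a truth DataFrame (id, effect size, altered flag).
    The defaults mirror a spiked validation study: 11 affected spots out of
    147 with an effect large enough to separate cleanly from the null.
    """
    if n_proteins < 10:
        raise ValueError("need at least 10 proteins")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    if not 0 <= n_altered <= n_proteins:
        raise ValueError("n_altered out of range")
    rng = np.random.default_rng(seed)
    signs = EFFECT_SIGNS[effect]                      # validates effect name
    altered = np.zeros(n_proteins, dtype=bool)
    idx = rng.permutation(n_proteins)[:n_altered]
    altered[idx] = True
    eff = np.where(altered, effect_size, 0.0)
    mu = baseline + rng.normal(0.0, 1.0, n_proteins)  # protein abundances

    mean = mu[None, None, :] + signs[:, None, None] * eff[None, None, :]
    eps = rng.normal(0.0, noise_sd, size=(4, n_replicates, n_proteins))
    if gel_effect_sd > 0:
        gel = rng.normal(0.0, gel_effect_sd, size=(4, n_replicates, 1))
        eps = eps + gel
    table = QuantTable(values=mean + eps)
    truth = pd.DataFrame({"id": table.protein_ids, "effect_size": eff,
                          "altered": altered})
    return table, truth
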