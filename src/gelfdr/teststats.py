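"""Per-protein test statistics for a balanced 2x2 factorial gel experiment.

The quantification table holds log-scale protein quantities y[g, l, i] for
group g = 1..4, replicate l = 1..n, protein i = 1..K.  Groups follow the
factorial coding

    group 1: treatment -, gender -        group 2: treatment -, gender +
    group 3: treatment +, gender -        group 4: treatment +, gender +

and the linear model per protein is

    y_1li = mu - tau - gamma - (tg) + eps      y_2li = mu - tau + gamma + (tg) + eps
    y_3li = mu + tau - gamma + (tg) + eps      y_4li = mu + tau + gamma - (tg) + eps

with eps ~ N(0, sigma_i^2).  Each effect is tested by the contrast of the
four group means carrying those +/- signs, divided by 2 S_i / sqrt(n) where
S_i^2 is the variance pooled within the four groups; under the null the
statistic is t with df = 4(n-1).  z_i = Phi^{-1}(F_df(t_i)) maps it to the
normal scale, N(0, 1) under the theoretical null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["QuantTable", "EffectTests", "EFFECT_SIGNS",
           "compute_effect_tstats", "t_to_z", "compute_effect_z"]

# per-group sign of (tau, gamma, taugamma) in the model above; the row for an
# effect is also its group-mean contrast
EFFECT_SIGNS = {
    "treatment":   np.array([-1.0, -1.0, 1.0, 1.0]),
    "gender":      np.array([-1.0, 1.0, -1.0, 1.0]),
    "interaction": np.array([-1.0, 1.0, 1.0, -1.0]),
}


@dataclass(frozen=True)
class QuantTable:
    """Complete balanced log-scale quantification array, shape (4, n, K)."""

    values: np.ndarray
    protein_ids: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != 4:
            raise ValueError("values must have shape (4 groups, n replicates, "
                             f"K proteins); got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("quantification table contains non-finite values "
                             "(missing cells are not supported)")
        object.__setattr__(self, "values", v)
        ids = self.protein_ids
        if ids is None:
            ids = np.arange(1, v.shape[2] + 1)
        ids = np.asarray(ids)
        if ids.size != v.shape[2]:
            raise ValueError("protein_ids length does not match K")
        object.__setattr__(self, "protein_ids", ids)

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_proteins(self) -> int:
        return int(self.values.shape[2])


@dataclass
class EffectTests:
    """t statistics (and optionally z-values) for one factorial effect."""

    effect: str
    t: np.ndarray
    df: int
    z: np.ndarray | None = None


def compute_effect_tstats(table: QuantTable, effect: str) -> EffectTests:
    """t_i = (signed sum of the four group means) / (2 S_i / sqrt(n)).

    S_i^2 pools the within-group sample variance across all four groups,
    giving df = 4(n - 1).  Proteins with zero pooled variance produce a
    non-finite t and a warning.
    """
    if effect not in EFFECT_SIGNS:
        raise ValueError(f"unknown effect {effect!r}; choose from "
                         f"{sorted(EFFECT_SIGNS)}")
    v = table.values
    n = table.n_replicates
    if n < 2:
        raise ValueError("need at least 2 replicates per group for a "
                         "pooled variance")
    group_means = v.mean(axis=1)                      # (4, K)
    resid = v - group_means[:, None, :]
    df = 4 * (n - 1)
    s2 = (resid ** 2).sum(axis=(0, 1)) / df           # pooled S_i^2
    contrast = EFFECT_SIGNS[effect] @ group_means     # (K,)
    degenerate = s2 <= 0.0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} protein(s) with zero pooled "
                      "variance; their t statistics are non-finite")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = contrast / (2.0 * np.sqrt(s2) / np.sqrt(n))
    return EffectTests(effect=effect, t=t, df=df)


def t_to_z(t, df: int) -> np.ndarray:
    """Probit transform z = Phi^{-1}(F_df(t)); N(0,1) under the null.

    Uses the survival function on the positive branch so extreme statistics
    keep tail precision; probabilities that still underflow are clamped away
    from {0, 1} with a warning.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tiny = np.finfo(float).tiny
    neg = t <= 0
    p = np.where(neg, stats.t.cdf(t, df), stats.t.sf(t, df))
    if np.any((p <= 0) & np.isfinite(t)):
        warnings.warn("t so extreme that the tail probability underflows; "
                      "clamping away from 0")
    p = np.clip(p, tiny, 1.0)
    z = stats.norm.ppf(p)
    return np.where(neg, z, -z)


def compute_effect_z(table: QuantTable, effect: str) -> EffectTests:
    """Convenience: t statistics plus their z transform for one effect."""
    tests = compute_effect_tstats(table, effect)
    finite = np.isfinite(tests.t)
    z = np.full_like(tests.t, np.nan)
    if finite.any():
        z[finite] = t_to_z(tests.t[finite], tests.df)
    tests.z = z
    return tests
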