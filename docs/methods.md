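# Methods

## Model

Per-protein test statistics from a balanced 2×2 factorial design (groups =
treatment × gender, n replicate gels per group, K proteins) are formed from
the log-scale quantifications y_gli under the linear model

    y_1li = μ_i − τ_i − γ_i − (τγ)_i + ε_1li
    y_2li = μ_i − τ_i + γ_i + (τγ)_i + ε_2li
    y_3li = μ_i + τ_i − γ_i + (τγ)_i + ε_3li
    y_4li = μ_i + τ_i + γ_i − (τγ)_i + ε_4li ,   ε ~ N(0, σ_i²).

Each effect is tested by the contrast of the four group means carrying that
effect's ± signs, divided by 2S_i/√n, where S_i² pools the within-group
sample variance over all four groups; the statistic is t with df = 4(n−1)
under the null. (The denominator is implemented as 2S_i/√n: this is the
unique scaling under which the contrast of four group means of n
observations each, with unit error variance, has unit variance and the
stated df.) The probit transform z_i = Φ⁻¹(F_df(t_i)) is applied with the
survival function on the positive branch to preserve tail accuracy;
probabilities that underflow are clamped away from {0, 1} with a warning.

z-values are modelled by the two-component mixture f = p0·f0 + (1−p0)·f1
with empirical null f0 = N(δ, σ²), and inference is by the local fdr
fdr(z) = p0 f0(z)/f(z) and the tail FDR, the f-weighted average of fdr over
a tail. The left-tail conditioning FDR(z0) = E_f{fdr(Z) | Z ≤ z0} is the
primitive definition; the right-tail analogue (conditioning on Z ≥ z0),
used for right-tail effects, follows by symmetry of the construction.

## Density estimation

z-values are binned into J equal-width bins (half-open [lo, hi), last bin
closed; range = data range unless given). Counts are treated as independent
Poisson, m_j ~ Po(ν_j) with ν_j = NΔ f(x_j) at the bin midpoints, and
log ν_j = s(x_j; θ) is a natural cubic spline with D knots: basis B₁ = 1,
B₂ = x, B_d = φ_{d−2} − φ_{D−1} for d = 3..D, with
φ_d(x) = [(x−h_d)₊³ − (x−h_D)₊³]/(h_D − h_d). The span is linear outside
[h₁, h_D]. Knots are equally spaced over [x₁, x_J] by default
(deterministic, and consistent with the bracket h₁ = x₁ ≤ … ≤ h_D ≤ x_J);
count-weighted quantile placement is available as an option.

The null component on the log-count scale is the quadratic
q(x; β) = β₁ + β₂x + β₃x², tied to the null interval [a, b]: a bin belongs
to the null set iff its *midpoint* lies in the closed interval (the simplest
deterministic reading; full-bin containment would differ only at the two
edge bins). [a, b] must cover at least 4 midpoints so the quadratic fit is
over-determined. Given β, the null parameters are

    σ² = −1/(2β₃),   δ = β₂σ²,
    log p0 = β₁ − log(NΔ) + δ²/(2σ²) + ½·log(2πσ²),

with p̂0 capped at 1 (the raw value is always recorded, because
unconstrained estimation can and does produce p̂0 > 1). β₃ ≥ 0 is reported
as an error: no normal null is identifiable from a non-concave centre.

### Estimators

* **Unconstrained / CME.** Standard Poisson IRLS (weights w_j = ν_j,
  working response m̃_j = log ν_j + (m_j − ν_j)/ν_j) maximises the
  likelihood; central matching then sets β̂ = (Ω₀′Ω₀)⁻¹Ω₀′Γ₀θ̂, the least
  squares quadratic approximation to s on the null bins.
* **MLE.** With f1 assumed to vanish on [a, b], N₀ the number of z in
  [a, b], P₀ = Φ((b−δ)/σ) − Φ((a−δ)/σ) and mixing weight θ = p0P₀, the
  likelihood θ^N₀(1−θ)^(N−N₀) Π φ_{δ,σ}(z_i)/P₀ is maximised over
  (δ, log σ, logit p0) by Nelder–Mead (joint optimisation by default; the
  plug-in p̂0 = N₀/(NP₀) after a truncated-normal fit is available).
* **Constrained (the package's core).** The Poisson likelihood is maximised
  subject to Cθ ≥ 0 with C = Γ − Ω(Ω₀′Ω₀)⁻¹Ω₀′Γ₀, i.e. s ≥ q at every bin
  midpoint — the discrete version of "the null component never exceeds the
  mixture", which the smoothness of both curves makes sufficient in
  practice. Each IRLS step becomes the convex QP

      min_θ Σ w_j (s(x_j; θ) − m̃_j)²   s.t.   Cθ ≥ 0,

  always feasible (C·0 = 0).

### The constrained weighted least-squares step

With H = Γ′WΓ (positive definite; Γ has full column rank) and g = Γ′Wm̃,
the QP dual in the multipliers λ ≥ 0 is the non-negative least-squares
problem min ‖Aλ + b‖² with A = L⁻¹C′, b = L⁻¹g, H = LL′; the primal
solution is θ = L′⁻¹(b + Aλ). A is wide (one column per bin) and has rank
at most D, so the solver must handle heavy rank deficiency exactly: the
package carries its own Lawson–Hanson active-set implementation (validated
against an interior-point reference on hundreds of random QPs; worst
constraint violation ~1e−13), and falls back to scipy's `trust-constr` in
the never-observed event that the recovered primal violates Cθ ≥ −1e−8.

The IRLS loop itself is damped: the constrained Newton step is not monotone
in the deviance, so a step that increases it is halved back toward the
previous iterate (the feasible set is convex, so halved steps stay
feasible). Convergence is declared when the deviance
Dev = 2Σ{m_j log m_j − m_j − (m_j log ν_j − ν_j)} (with 0·log 0 = 0)
changes by at most `tolerance` (default 1e−8; `max_iter` 100; initial
ν_j = (m_j + m̄)/2). The linear predictor is clipped to |s| ≤ 30 purely as
an overflow guard — realistic bin counts live far below e³⁰. Fits that
exhaust `max_iter` return `converged=False` and are never selected by the
df search.

### Spline df

D is chosen by minimising AIC = deviance + 2D over a user range (default
4–10), ties broken toward the smaller D. (Deviance and −2·log-likelihood
differ only by a data-only constant, so this is the usual AIC up to an
irrelevant shift.) Deviance is *not* monotone in D under uniform knot
placement — knot sets at different D are not nested — which the AIC search
tolerates naturally.

## Local fdr

fdr̂(z) = exp{q(z; β̂) − s(z; θ̂)}, evaluated by direct evaluation of the
fitted spline and quadratic at arbitrary points rather than by
interpolating bin-midpoint values: the natural-spline basis *is* the
natural linear continuation beyond the knots, direct evaluation is exact on
the estimation grid, and tail probes may lie beyond the last midpoint.
Points outside the histogram range trigger an extrapolation warning.
Constrained fits clip tiny overshoots into [0, 1]; unconstrained fits are
reported unclipped so their fdr > 1 pathology remains visible. Tail FDR is
computed on the midpoint grid, weighting fdr̂(x_j) by ν̂_j.

## What the constraint really does — and how to choose [a, b]

The least-squares residuals of the quadratic fit on the null bins sum to
zero, so nonnegative slack there forces *zero* slack: a feasible fit is
**exactly** quadratic at every null midpoint, and fdr̂ ≡ 1 on [a, b]. Two
practical consequences, both verified against an independent interior-point
solve of the same convex program (so they are properties of the optimum,
not optimizer artifacts):

* [a, b] must be interior to the z range. The natural spline carries zero
  curvature at its boundary knots, so if four or more null midpoints fall
  in the first (or last) knot span, exact quadratic agreement forces
  β₃ = 0 and the null degenerates. `build_design` warns when [a, b]
  reaches the histogram edge.
* [a, b] should be a *narrow band around the central peak*, not most of the
  histogram. Every knot span inside [a, b] spends its cubic freedom on
  being quadratic; with small samples, a wide interval plus a detached
  non-null spike can leave too little flexibility outside and the global
  constrained optimum collapses (β₃ → 0). Null intervals of width ~1.5–2.5
  centred on the peak behave well at realistic sizes; this matches how the
  interval is chosen in practice.

When no interval is supplied, the mode ± 1.6·(1.4826·MAD) heuristic is used
with a warning; real analyses should set [a, b] from the histogram.

## Synthetic data

`simulate_z` draws the validation model: n0 null values from N(δ0, σ0²)
followed by n1 non-null from N(μ1, σ1²). Defaults are the study condition
used throughout: 5000 from N(−1, 1) plus 500 from N(3, 1) (p0 = 10/11),
null interval [−2, 0], 100 bins — with a scaled-down variant of 500 + 50
draws and 50 bins. The closed-form fdr of this mixture provides the truth
for accuracy ratios.

`simulate_quant_table` builds a balanced 4×n×K factorial table from the
linear model above, with a seeded sparse subset of proteins carrying a
chosen effect (defaults: 11 of 147, mirroring a spiked two-condition
validation study) and optional per-gel random intercepts (`gel_effect_sd`)
shared by all proteins on a gel. Those shared offsets shift every contrast
coherently and inflate the pooled variance, displacing the downstream null
from N(0, 1) — the realistic mechanism for empirical-null departures.
(A constant shift or a global rescaling of the noise would cancel exactly
in the t statistics and cannot produce this effect.)

What the generators do *not* emulate: gel images and everything upstream of
quantification (spot detection, segmentation, alignment), heteroscedastic
or heavy-tailed measurement error, correlation between proteins beyond the
gel-level intercepts, and missing spots. Passing tests therefore certify
the statistical pipeline from quantifications (or z-values) onward, not
robustness to image-processing artifacts.

## Replicate studies and problem sizes

`run_replicates` runs R seeded replicates (replicate r uses base_seed + r,
so any replicate is independently reproducible), fits the requested methods
with AIC-selected df (4–10) per replicate, extracts (δ̂, σ̂, p̂0), records
whether the unclipped fdr̂ exceeds 1 at any midpoint, and evaluates fdr̂ at
probe points z ∈ {2, 2.5, 3, 3.5, 4}. Summaries report per-method means,
SDs, Monte-Carlo standard errors and mean/truth fdr ratios. Failed
replicates (e.g. a β₃ ≥ 0 extraction on an unconstrained fit, roughly one
per hundred small-sample replicates) are excluded and counted; constrained
fits have not been observed to fail. The packaged studies use R = 100
replicates in three configurations (100 bins × 5500 z; 50 bins × 550;
100 bins × 550), a few minutes of single-CPU time in total.

## Known limitations

* The normal-null family is fixed; broader null families are not supported.
* The fdr curve is not post-processed for monotonicity; monotone spline
  regression of the tail is out of scope.
* The MLE route inherits the usual sensitivity of truncated-normal fits to
  the interval choice; the constrained route is the recommended default.
* AIC is computed from the binned deviance, so very different bin counts
  are not directly comparable.
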