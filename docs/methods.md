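# Methods

## Model and construction

The half logistic–truncated exponential distribution (HL-TEXPD) is built
by the truncated T-X composition implemented in `hltexpd.family`: for a
base variable X left-truncated at τ with conditional cdf F and a
generator T on [0, ∞) with density r and cdf R,

    G(x) = R(H(x)),   H(x) = −log(1 − F(x | x > τ)),
    g(x) = r(H(x)) · f(x)/(1 − F(x)).

With an exponential base of rate θ the cumulative hazard is linear,
H(x) = θ(x − a), so the composition reduces exactly to
g(x) = θ·r(θ(x − a)); with a half-logistic generator this gives the
closed forms in `hltexpd.distribution`. The generator is assumed
supported on [0, ∞); composition with the unit-exponential generator
reproduces the base distribution and is used as an identity check. The
exponential base uses the standard cdf 1 − e^{−θx}. Where the base
survival has numerically vanished (below 1e-15) the composed density
returns its correct limit 0 instead of forming 0/0. Evaluators are pure
functions; the intended samples are tiny, so nothing is cached.

## Parameters

* `a` — truncation/location threshold, in data units. Any finite value;
  the support is [a, ∞). Fitted as the sample minimum.
* `theta` — rate, in inverse data units; must be positive. Controls
  scale only: skewness (≈ 1.5397) and non-excess kurtosis are constants
  of the family, a useful sanity check that the fitted shape is an
  assumption, not an inference.

## Closed-form properties and their oracles

Raw moments follow from E[(a + U/θ)^p] with U standard half-logistic,
whose moments are 2·p!·η(p) (η the Dirichlet eta): E X = a + log 4/θ,
E U² = π²/3, E U³ = 9ζ(3), E U⁴ = 7π⁴/15. The `raw_moment` method
offers both the binomial closed form and adaptive quadrature of
2(a + u/θ)^p e^{−u}/(1+e^{−u})² on u ∈ [0, 40] (the truncated tail is
below 1e-12 since the integrand decays like u^p e^{−u}); tests require
agreement to 1e-8 relative. Published transcriptions of the third and
fourth moments and of some central-moment expressions omit the a-free
terms (they evaluate to 0 at a = 0, contradicting E U³ = 9ζ(3)); this
package derives the moments from the integral definition and verifies
them against the eta-series oracle, so those omissions are corrected
rather than reproduced.

Shannon entropy is 2 − ln 2 − ln θ nats, verified against numeric
−∫ g ln g to 1e-6. A published closed form states the constant as
1.6989 = 2 − log₁₀ 2, a mixture of decimal and natural logarithms; only
the all-natural-log value matches direct integration, so that is what
`entropy()` returns.

The quantile is a + (1/θ)·log((1+p)/(1−p)) (the printed exponent
placement is readable only this way if G(x_p) = p is to hold; verified
against a bisection inverse of the cdf). p = 1 returns +inf. Sampling is
inverse-transform with numpy's PCG64 generator, bit-reproducible for a
fixed seed within one numpy version. The survival function is computed
as 2e^{−z}/(1 + e^{−z}) with z = θ(x − a), which degrades gracefully to
2e^{−z} for large z instead of forming an indeterminate ratio.

## Estimation

The threshold MLE is the sample minimum (the likelihood increases in a
up to the smallest observation). The profile score in θ is strictly
decreasing with limits +∞ at 0⁺ and −Σdᵢ < 0, so the root is unique; it
is bracketed starting from the moment initialiser θ₀ = log 4 / (x̄ − â)
and the bracket [θ₀/10, 10θ₀] is expanded geometrically until the score
changes sign, then solved by Brent's method to relative tolerance 1e-10.
Observations equal to the minimum contribute dᵢ = 0 terms, which are
finite; ties are not jittered. Samples with fewer than two observations
or with all values equal are rejected (the score equation has no root).

AIC = 2k − 2ℓ and BIC = k log n − 2ℓ use k = 1: the rate is the only
parameter treated as free, with the threshold fixed at the minimum. This
is the convention consistent with the published comparison tables
(e.g. AIC = 2 + 2·122.675 for the Kevlar fit). The same k = 1 applies to
the shifted-exponential baseline. One published BIC (guinea-pig fit,
205.33) is inconsistent with the definition — it is smaller than the
corresponding AIC at n = 72, which is impossible for k ≥ 1 — so BIC is
always recomputed from the definition (209.33 there).

Standard errors use observed information,
−ℓ''(θ̂) = n/θ̂² + 2Σ dᵢ² e^{−θ̂dᵢ}/(1+e^{−θ̂dᵢ})², which reproduces the
published SEs (0.070, 0.083) to printed precision; whether those were
observed- or expected-information based is not stated, and observed
information is the package's choice.

## Monte-Carlo study

`run_cell` draws `reps` samples of size n by inverse transform from
(a_true, θ_true), refits each with the threshold re-estimated as the
sample minimum, and aggregates: bias = mean(θ̂ − θ), MSE =
mean((θ̂ − θ)²) (identically the estimate variance plus bias²), MRE =
mean(|θ̂ − θ|)/θ, and the coverage of per-replicate Wald intervals
θ̂ ± z_{ε/2}·SE(θ̂) with observed-information SEs. Defaults mirror the
published design: 1000 replicates, θ ∈ {0.5, 0.3, 0.05},
n ∈ {20, 50, 100, 200}, nominal 99% intervals, a_true = 0. Design
choices where the source protocol is silent or inconsistent:

* a_true is 0 and the threshold is re-estimated every replicate; this
  matches the fitting protocol and produces the characteristic positive
  small-n bias (the minimum overshoots the threshold, shrinking the
  residuals).
* The published interval formula divides the SE by √1000, which cannot
  yield its own reported coverages (35%–99% for a nominal 99% band);
  standard per-replicate Wald intervals are used instead, and coverage
  is reported but the published coverage column is not a verification
  target. The same applies to the published per-cell "(S.E)" values of
  order 1e-5, which match no standard estimator-SE definition.
* The absolute value in MRE is made explicit; without it the printed
  values (≈ 0.798·RMSE/θ, the mean absolute deviation of a near-normal
  estimator) are not recoverable.
* Per-cell seeds are spawned from the master seed via
  `SeedSequence([seed, i, j])`, so a grid rerun with the same master
  seed is byte-identical.

The MRE ≈ 0.798·√MSE/θ normal-limit identity is asserted at n = 200
within 10%.

## Descriptive statistics

Quartiles use linear interpolation at plotting position (k−1)/(n−1)
(the numpy/R type-7 default), which reproduces the published medians
exactly; the SD uses the n−1 denominator; skewness and kurtosis are the
central-moment ratios m₃/m₂^{3/2} and m₄/m₂² with mₖ = mean((x − x̄)^k)
— kurtosis is **not** excess and carries no small-sample correction
(the published kurtosis ≈ 8 for the Kevlar data is only consistent with
that convention). Two caveats: the Kevlar Q1 prints as 0.9048 where the
type-7 quartile is 0.90470 (no standard quartile convention we tried
yields 0.9048 with the other cells unchanged), and a few printed cells
are truncated rather than rounded (e.g. SD 37.479 from 37.47954);
tests therefore allow one unit in the last printed place. Datasets are
stored verbatim to full printed precision and never rounded on load;
suspected historical typos in these classical datasets are left as
printed.

## Diagnostics

The scaled total-time-on-test transform uses order statistics
x₍₁₎ ≤ … ≤ x₍ₙ₎: Tᵢ = [Σ_{j≤i} x₍ⱼ₎ + (n−i)x₍ᵢ₎]/Σx₍ⱼ₎, T₀ = 0, plotted
against i/n. Concave curves indicate increasing failure rate; the
exponential gives the diagonal. Plotting positions: the empirical cdf
uses i/n (right-continuous, via statsmodels' ECDF), P-P pairs i/n with
the fitted cdf, Q-Q uses (i − 0.5)/n. These are conventional defaults;
the curves are qualitative diagnostics and no automated shape
classification is attempted. Figure rendering is left to the caller —
the tested artifact is the numeric series.

## What the simulations do and do not show

The synthetic-data generator is the model's own inverse-transform
sampler: simulation results demonstrate estimator behaviour *under the
model* (consistency, shrinking bias/MSE, near-nominal Wald coverage at
n = 200) and say nothing about robustness to misspecification,
censoring, or measurement rounding, all of which real lifetime data
exhibit. The bundled datasets are complete (uncensored) samples; no
censored-data likelihood is provided. Problem sizes in the test suite —
up to 1000 replicates of n = 200 for the Monte-Carlo checks, 10⁵ draws
for the Kolmogorov sampling check — were chosen to hold Monte-Carlo
error comfortably below the asserted tolerances.

## Known limitations

* Only the half-logistic generator is registered; the composition
  machinery accepts any generator on [0, ∞) but no other named family
  ships with the package.
* The moment-generating function has no closed form here and is not
  evaluated numerically.
* Goodness-of-fit statistics (Kolmogorov–Smirnov, Cramér–von Mises,
  Anderson–Darling) are not computed; model choice is by information
  criteria.
* The threshold estimate â = min(xᵢ) is super-efficient and its
  sampling error is ignored by the k = 1 information criteria and the
  rate's Wald interval; for very small n this understates uncertainty.
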