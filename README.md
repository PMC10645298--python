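# hltexpd

Lifetime modelling with the **half logistic–truncated exponential
distribution** (HL-TEXPD): a two-parameter law for positive, left-bounded
failure-time data with a monotonically increasing hazard. The package is
aimed at reliability engineers and biostatisticians fitting small
uncensored lifetime samples — fatigue-fracture times, survival times,
revolutions to failure — where an ageing (increasing-failure-rate) model
with an explicit support threshold beats the memoryless exponential.

## The model

HL-TEXPD arises from a truncated T-X construction: the cdf *R* of a
half-logistic generator is evaluated at the cumulative hazard of a
left-truncated exponential base. With threshold *a* and rate *θ > 0*,

```
g(x) = 2θ e^{-θ(x-a)} / (1 + e^{-θ(x-a)})²,        x ≥ a
G(x) = (1 - e^{-θ(x-a)}) / (1 + e^{-θ(x-a)})
h(x) = θ / (1 + e^{-θ(x-a)})                       (hazard)
```

— a location-shifted half-logistic law. The hazard rises from θ/2 at the
threshold toward the asymptote θ; mean = a + log 4/θ; variance
≈ 1.368/θ²; skewness ≈ 1.54 and kurtosis are parameter-free constants;
Shannon entropy is 2 − ln 2 − ln θ nats.

Maximum likelihood is a profile scheme: â = min(xᵢ) (the density is
positive at the support edge), and θ̂ solves the one-dimensional score
equation

```
n/θ − Σ(xᵢ − â) + 2 Σ (xᵢ − â) e^{-θ(xᵢ-â)} / (1 + e^{-θ(xᵢ-â)}) = 0,
```

which is strictly decreasing in θ, so a bracketed Brent solve finds the
unique root. Standard errors come from observed information; model
comparison uses AIC/BIC with k = 1.

## Worked example

Three classical datasets ship with the package: `kevlar76`
(fatigue-fracture lifetimes of 76 Kevlar 373/epoxy specimens),
`guinea72` (survival times of 72 tubercle-infected guinea pigs) and
`bearings23` (millions of revolutions to failure for 23 ball bearings).

```sh
$ hltexpd compare --dataset kevlar76
model	loglik	a_hat	theta_hat	se	aic	bic
hl-texpd	-122.6751	0.0251	0.7357	0.0701	247.3501	249.6808
texpd	-126.1344	0.0251	0.517	0.0593	254.2688	256.5995
exponential	-127.1143		0.5104	0.0585	256.2287	258.5594
```

HL-TEXPD attains the highest log-likelihood and the lowest AIC/BIC of the
three candidates: the fitted rate θ̂ = 0.7357 h⁻¹ (SE 0.0701) above the
threshold â = 0.0251 h implies a failure rate climbing from 0.37 to
0.74 h⁻¹ as specimens age. The same API is available from Python:

```python
from hltexpd import fit_hl_texpd, load_dataset
fit = fit_hl_texpd(load_dataset("guinea72").values)
fit.theta_hat, fit.loglik, fit.aic   # (0.8689, -102.5245, 207.0491)
```

or through sklearn-style estimators (`HalfLogisticTruncExpMLE().fit(x)`)
that support `get_params`/`clone`, `score_samples` and `sample`.

Descriptive summaries and failure-rate diagnostics:

```sh
$ hltexpd describe --dataset bearings23
min	q1	median	mean	q3	max	sd	skewness	kurtosis
17.88	47.2	67.8	72.2383	95.88	173.4	37.4795	0.9413	3.4883

$ hltexpd ttt --dataset bearings23      # scaled total-time-on-test curve
```

The bearings sample is right-skewed (skewness 0.94) and its concave TTT
curve indicates an increasing failure rate — exactly the regime HL-TEXPD
is built for. `hltexpd simulate` runs the Monte-Carlo bias/MSE/coverage
study of the rate estimator over a (θ, n) grid with a fixed seed.

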