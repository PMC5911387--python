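# growthscore

Single-number growth metrics for 96-well bacterial phenotype assays.

High-throughput phenotype panels measure a full optical-density (OD) time
series in every well; downstream analysis needs each curve reduced to one
interpretable number. This package fits the four-parameter Zwietering
logistic growth model to plate-reader curves and scores each well with the
**Growth Score**

```
GS = (A − y₀) + 0.25·μ
```

where y₀ is the starting absorbance, A the biomass yield (stationary-phase
asymptote) and μ the maximum growth rate (OD/h). GS depends only on the
fitted parameters — not on the time grid or the lag time — so it also works
on parameter tables produced by other curve-fitting software. The legacy
**Growth Level** (an amplitude-weighted harmonic mean of the fitted curve,
GL = n / Σᵢ 1/xᵢ with xᵢ = (ŷᵢ − y₀) + (A − y₀)) is implemented alongside
for comparison, together with a simulation study that quantifies how
closely the two metrics agree.

The fitted model is

```
ŷ(t) = y₀ + (A − y₀) / (1 + exp[(4μ/A)(λ − t) + 2])
```

with λ the lag time in hours. Either metric maps to an ordinal growth
class ("−" no growth … "++++" very high growth) via configurable
thresholds.

Intended users: microbiologists running 96-well phenotype microarrays or
growth screens, and pipeline authors who need a scriptable fitter/scorer.

## Worked example

Fit a single curve with the scikit-learn style estimator:

```python
import numpy as np
from growthscore import ZwieteringLogistic, GrowthParameters, logistic, growth_score

t = np.arange(0.0, 48.0, 0.5)                      # hours
od = logistic(GrowthParameters(y0=0.05, lag=6.0, mu=0.3, A=1.0), t)

est = ZwieteringLogistic().fit(t, od)
print(est.y0_, est.lag_, est.mu_, est.A_)          # 0.05 6.0 0.3 1.0
print(growth_score(est.params_))                   # 1.025
```

The recovered parameters match the generating ones and GS = (1.0 − 0.05) +
0.25·0.3 = 1.025: a well that accumulated 0.95 OD of biomass at a moderate
rate — class "+++" under the shipped default thresholds.

From the shell, simulate a cohort of 1,000 curves with parameters drawn
uniformly from realistic ranges (y₀ ∈ [0.05, 0.10], λ ∈ [0, 120] h,
A ∈ [0.1, 1.2], μ ∈ [A/240, 1.1A]) and compare the two metrics:

```
$ growthscore simulate -n 1000 --seed 1 -o cohort.tsv
$ growthscore compare cohort.tsv
pearson_r	0.961361
p_value	0
skew_gl	0.178512
skew_gs	0.0649299
regression_slope	0.662812
regression_intercept	0.0487378
n_reclassified	236
n_sign_flips	34
n_curves	1000
```

GL and GS correlate strongly (r ≈ 0.96 on this seed); a fifth of curves
change ordinal class between the two systems but only 3% flip between
"no growth" and a growing class. `growthscore fit` scores a real plate file
(long tab-delimited `sample/well/time/od`, or wide CSV), and
`growthscore score` consumes a bare parameters table (`y0/lag/mu/A`) from
any external fitter.

## Documentation

See `docs/methods.md` for the model, its assumptions, the simulation
design, numerical choices and known limitations.
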