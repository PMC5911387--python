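# Methods

## Growth model

Each well's OD time series is described by the Zwietering
reparameterization of the logistic curve,

    yhat(t) = y0 + (A − y0) / (1 + exp[(4μ/A)(λ − t) + 2]),

whose parameters are directly interpretable growth-curve properties:
starting absorbance y0 (OD), lag time λ (h), maximum growth rate μ (OD/h)
and biomass yield A (OD). The constant 2 anchors the curve so that
yhat(λ) − y0 = (A − y0)/(1 + e²) exactly — the lag time is where the
tangent at the inflection point crosses the baseline. Two consequences
worth noting:

* the analytic maximum slope of this parameterization is μ(A − y0)/A, not
  μ itself; the two coincide only when y0 ≪ A. Tests assert the exact
  identity rather than the approximation.
* the exponent is clamped to [−700, 700] before exponentiation so extreme
  (λ − t)·μ/A products return the exact asymptote instead of overflowing;
  the clamp is invisible at any physically plausible argument.

Assumptions: OD readings are already blank-corrected (no background
subtraction is performed), time is in hours (file readers convert from
minutes/seconds), and a single logistic phase describes the well — no
diauxie, death phase or multi-phase kinetics.

## Metrics

**Growth Score.** GS = (A − y0) + 0.25·μ. Yield (amplitude) is the primary
component; the rate enters at 25% weight so that fast-but-low growth cannot
dominate the score. GS needs no raw data and no lag estimate, so it applies
to parameter tables from any curve-fitting software. Negative values
(A ≤ y0, a non-growing well) are reported as computed — clamping would bias
cohort statistics — and classify into the lowest class.

**Growth Level** (legacy). GL = n / Σᵢ 1/xᵢ with
xᵢ = (yhatᵢ − y0) + (A − y0), a harmonic mean of the model curve weighted by
the attained amplitude, evaluated on the observed time grid. Because it
averages over time it inherits a dependence on lag time and experiment
length — the motivation for replacing it. It is computed on the model
curve, never the raw readings, over exactly the observed window. If any
xᵢ ≤ 0 (flat or non-growing fits) the harmonic mean is undefined; GL is
then defined as 0 with a degenerate flag rather than an error, since
non-growing wells are routine.

**Classes.** Metric values map to the ordinal labels −, +, ++, +++, ++++
via ascending cutoffs with *inclusive lower bounds* (a value equal to a
cutoff takes the higher class; the upstream convention is unpublished, so
this package picks one and documents it). The shipped defaults
(`src/growthscore/data/default_thresholds.cfg`) are implementation
defaults: GL cutoffs 0.25/0.75/1.25/1.75, and GS cutoffs obtained by
mapping those through the GS-on-GL regression line of a reference cohort
(default configuration, seed 0), so the two class systems are directly
comparable. Both are fully overridable via `--thresholds FILE`; no test
depends on their particular values.

## Fitting

`ZwieteringLogistic` estimates (y0, λ, μ, A) by bounded nonlinear least
squares (scipy's trust-region reflective solver) on the plain, unweighted
residual sum of squares — no robust loss. Defaults:

* tolerance 1e-12 on parameters/cost/gradient, max 1000 objective
  evaluations (tight enough that noise-free curves reach rss ≈ 0);
* data-driven box constraints y0 ∈ [0, max od], A ∈ [min od, 2·max od],
  μ ∈ [1e-6, 10 × steepest observed slope], λ ∈ [0, max time] — these keep
  the exponent well scaled and forbid non-physical negatives, and always
  contain the truth for curves generated inside the simulation ranges;
* a single deterministic start from a heuristic initial guess (moving
  median smoothing, window 3, used *only* for initialization): y0 from the
  first readings, A from the smoothed maximum, μ from the steepest
  finite-difference slope (floored at 1e-6), λ from the tangent-line
  crossing clipped to the observed window;
* an optional seeded multistart (5 perturbed starts) behind a flag for
  hard curves.

Degenerate inputs: flat curves converge to A ≈ y0 and are flagged
non-growing downstream; when μ < 0.01 the lag/rate trade-off becomes
numerically unidentifiable and λ accuracy is not guaranteed (the other
three parameters still are).

## Simulation study

`simulate_cohort` draws noise-free logistic curves with independent
uniform parameters on a 0–240 h grid (dt = 0.5 h, 481 points):
y0 ~ U(0.05, 0.10), λ ~ U(0, 120), A ~ U(0.1, 1.2), and — conditioned on
the drawn A — μ ~ U(A/240, 1.1·A). Tying the rate range to the yield keeps
draws realistic: the lower end just reaches its yield by the end of the
experiment, the upper end within about an hour. The sampling order
(y0, λ, A, μ) is fixed so a seed reproduces the same cohort across
versions. The default cohort size is 1,000 curves.

dt is a first-class configuration field because GL averages over the time
grid and therefore depends on it (GS does not); 0.5 h is a typical
plate-reader cadence. Optional Gaussian observation noise (`noise_sd`,
default off) exists for exercising the fitter; the comparison study itself
uses noise-free curves, computing GL on the model curve and GS from the
true parameters — the curves are generated directly from the model, so
refitting would be an identity operation (the fitter is validated
separately by parameter-recovery tests).

`compare_metrics` reports: Pearson r between GL and GS with its two-sided
p-value, adjusted Fisher–Pearson sample skewness of each metric, the
GS-on-GL ordinary least-squares line, and two disagreement counts —
curves whose ordinal class differs between metrics, and the subset flipping
between "−" and any growing class. When GS thresholds are not supplied they
are derived by mapping the GL cutoffs through the fitted regression line.

Across seeds at n = 1000 the correlation is ≈ 0.96 ± 0.01; GL skewness
typically exceeds GS skewness, and class flips between no-growth and growth
are an order of magnitude rarer than reclassifications. Statistics that
depend on a particular realization and on the (unpublished) upstream class
cutoffs — exact skewness values and disagreement counts — are treated as
seed- and threshold-dependent tendencies, not fixed targets.

What the generator does not emulate: measurement noise and drift,
condensation and evaporation artefacts, multi-phase growth, well-to-well
spatial effects, and ragged or missing time points. Passing simulation
tests therefore demonstrate correctness of the model, metrics and
statistics, not robustness to every artefact of real plate data (the noisy
recovery tests cover simple Gaussian noise only).

## File formats

Long tab-delimited tables (`sample`, `well`, `time`, `od`; one reading per
row) and wide CSV (first column `time`, one column per well) are read into
per-well curves; condition maps are tab-delimited `well`/`condition`
files. Well labels are normalized ("A1" → "A01") so joins are stable;
labels outside the 96-well grid are rejected except in the relaxed mode
used for simulated-cohort exports. Times in files default to decimal
hours, with minutes/seconds conversion on read. Results tables (TSV or
JSON) print floats at 6 significant digits in a deterministic row order so
reruns are byte-identical.

## Test problem sizes

The suite exercises cohorts of 1,000 curves for the comparison statistics
(20 seeds), 200 noise-free plus 100 noisy curves for parameter recovery,
and 10,000 draws for range conservation; these sizes make the stochastic
assertions stable while keeping the full suite around ten seconds.

## Known limitations

* Only the Zwietering logistic form is implemented (no Gompertz,
  Richards or Baranyi alternatives) — GS itself is model-agnostic given
  (y0, μ, A) from any fitter, via `growthscore score`.
* No confidence intervals on fitted parameters.
* The shipped class cutoffs are implementation defaults, not the
  (unpublished) upstream PMAnalyzer values, so disagreement counts under
  default thresholds are indicative only.
* Plot rendering is out of scope; the package computes the statistics
  behind such figures, not the figures.
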