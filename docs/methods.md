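# Methods

## The model

All intervals assume a measurand produced by a stable process: results are
independent draws from a normal distribution whose center is the
homeostatic set point (for a patient) or the target value (for a QC
material), and whose spread combines within-person biological variation
and analytical variation. Under that assumption a single future result
x lies, with probability `level`, inside

    center ± k · dispersion · c(n)

where the multiplier family `k` and the inflation factor `c(n)` depend on
where the center and the dispersion came from:

| scenario | mean        | variance    | k       | c(n)      |
|----------|-------------|-------------|---------|-----------|
| 1        | population µ| population σ²| z      | 1         |
| 2        | sample X̄, n | population σ²| z      | √(1+1/n)  |
| 3        | population µ| sample s², n | t(n−1) | 1         |
| 4        | sample X̄, n | sample s², n | t(n−1) | √(1+1/n)  |

A known (population) variance pairs with the standard-normal quantile z; an
estimated variance pairs with Student's t at n−1 degrees of freedom, which
compensates for the uncertainty of s and converges to z as n grows. The
√(1+1/n) factor carries the sampling error of an estimated mean. The
confidence interval for the mean itself is `X̄ ± t(n−1)·s/√n` and is
strictly narrower than the scenario-4 PI built from the same data, since
√(1/n) < √(1+1/n).

Scenario 3 ships without the √(1+1/n) factor by default: the external mean
(a peer-group or reference-method value) is treated as exact. The
`inflate=True` flag restores the factor for users who regard the external
mean as itself estimated. Degrees of freedom are n−1 in every t-based
formula, including scenario 3 where only the variance is sample-derived.

For scenario-4 intervals the stated coverage is exact, not asymptotic: for
i.i.d. normal data, (x − X̄)/(s·√(1+1/n)) is exactly t-distributed with
n−1 df. `labpi.qc.coverage_simulation` verifies this by Monte Carlo
(100 000 replicates at n = 10 reproduce 0.95 within three binomial
standard errors, < 1 s vectorised).

## Rounding modes

Bench worksheets carry summary statistics at two decimals and critical
values as printed in two-decimal t tables. Reproducing such a worked
calculation from raw data therefore requires rounding *intermediates*, not
just the final bounds. Two modes are exposed wherever a pipeline starts
from a series:

* `full_precision` (default) — no intermediate rounding; what a scientist
  should use on real data.
* `worked_example` — summary statistics and the critical value are rounded
  to two decimals before the interval formula, emulating the desk
  calculation. E.g. the 30-day glucose IQC run gives limits [4.07, 4.35]
  mmol/L in this mode but [4.07, 4.36] at full precision, because the
  full-precision SD is 0.0726 rather than 0.07.

Printed t tables list three decimals (2.262, 2.045, 2.093, 2.776); desk
values keep two. At df 29 this matters: t = 2.0452 rounds to 2.05 directly
but the table chain 2.045 → 2.04 is what two-decimal tables print, and the
often-quoted ≈4.1% t-vs-z penalty at n = 30 follows from 2.04/1.96 − 1.
The library always computes quantiles at full precision
(`scipy.stats.t.ppf`); table rounding happens only in `worked_example`
mode and in tests that check printed desk values.

Interval endpoints are closed: a QC result exactly on a limit is accepted.

## Personalized reference intervals

`compute_prri` supports two regimes:

* `cvi_based` (n ≥ 3): the individual contributes only a mean; the spread
  is borrowed from the population within-subject biological variation
  CV_I (e.g. the EFLM biological-variation database), converted to an SD
  as CV_I·mean/100 and treated as a population σ (scenario 2, z).
* `own_data` (n ≥ 5): mean and SD both come from the individual's series
  (scenario 4, t). The series must first pass quality screening —
  Dixon's Q for a single gross outlier and an OLS trend test — because a
  drifting or contaminated series violates the stable-process assumption.
  A failed screen raises unless `force=True`; nothing is ever removed
  automatically.

## Reference change values

The conventional RCV, `z·√2·√(CV_A²+CV_I²)`, uses population CVs and is
identical for everyone. The personalized RCV replaces them with the
individual's own CV and, because that CV is estimated from n results, uses
t(n−1): `RCV_P = t(n−1)·√2·CV`. The CV of an individual's repeated
results already contains analytical variation, so it is used directly as a
total CV_T without subtracting CV_A; supplying a pre-separated CV_P gives
the same formula (`cv_kind` only records provenance).

The observed change is Δ% = 100·(x1 − x2)/x1 — baseline denominator,
negative for a rise — and is significant when |Δ| exceeds the RCV, in
either direction (no asymmetric log-normal variant). The verdict is
invariant under unit rescaling of the pair.

## Quality screening choices

* Dixon's Q is the basic two-sided r10 ratio, gap/range for the more
  extreme of the minimum and maximum, against Rorabacher's 95% critical
  values (n = 3–30). Larger-n variants (r11, r21) are deliberately not
  used. Only α = 0.05 is tabulated; other levels raise rather than
  silently interpolate. One pass only — no iterative removal.
* Sensitivity is bounded: the suspect value itself inflates the range
  denominator, so a 6-SD spike in ten points is caught about 88% of the
  time, a 10-SD spike essentially always. The screen targets gross
  errors, not moderate ones.
* The trend test is OLS of value on occasion index (1, 2, …), not
  calendar time, with a two-sided t test of zero slope at n−2 df. Under
  an i.i.d. normal null its p-values are uniform (KS distance < 0.02 over
  10 000 simulated series).

## QC monitoring

`establish_baseline` freezes the limits of a data-collection period:
n ≥ 30 results are treated as population data (scenario 1, z — the
Levey-Jennings mean ± kSD rule with k = 1.96 rather than the ≈2
approximation); shorter runs (5 ≤ n < 30, e.g. a new instrument in
verification) get the wider provisional scenario-4 limits. The cutover is
configurable down to 20 via `established_min_n`. Baselines are frozen
documents (JSON) — no rolling update — and evaluation is the single
inside/outside-PI rule; Westgard multirules are out of scope.
`levey_jennings_points` exports chart-ready rows (z-score and ±1/±2/±3 SD
band per result) rather than rendering figures.

## Synthetic data

`generate_series` draws `value_i = set_point + slope·i + ε_i` with
ε ~ N(0, (set_point·√(cv_p²+cv_a²)/100)²): additive normal noise on the
concentration scale, the two variation sources combined in quadrature, an
optional linear drift and an optional single injected outlier expressed in
SD units. Deterministic per seed (`numpy.random.default_rng`). It emulates
exactly the steady-state the PI model assumes; real serial data can add
skewness, autocorrelation, circadian structure and analytical drift, so
passing tests demonstrate correctness of the statistics under the model,
not robustness to those departures.

One estimator property worth knowing: the sample CV at small n is biased
low (E[s] = c4(n)·σ; c4(10) = 0.9727), so the recovery test compares the
mean estimated CV over 1 000 seeded replicates to c4(n)·CV_true, the exact
sampling expectation, within three Monte-Carlo standard errors.

## Numerical and degenerate-input policy

Quantiles come from scipy at machine precision; no normal approximation to
t is ever substituted silently. Zero dispersion yields a degenerate
[X, X] interval rather than an error. Zero range makes Dixon's Q
undefined and raises. A single result has no sample SD and raises. CVs
are undefined at zero mean and raise. All intervals are symmetric about
their input mean to ~1e−12 relative tolerance and that symmetry is
property-tested.

## Known limitations

Normal-theory only: no log-normal RCV, no one-sided intervals, no
tolerance intervals, no intervals for the mean or SD of several future
results. Dixon screening handles a single outlier. The fixture tables
reproduce their sources verbatim, including desk-rounding artifacts (a
printed CV of 1.66% where full precision gives 1.72%, and one printed mean
that is an external peer-group value rather than the series average);
those quirks are documented in the dataset module rather than "fixed".
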