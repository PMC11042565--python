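# labpi

Prediction-interval based monitoring for laboratory medicine.

Clinical laboratories watch two kinds of serial data: internal quality
control (IQC) results that tell them an analyser is stable, and a
patient's repeated results that tell a clinician whether something has
changed. Both questions are the same statistical question — *given
historical results from a stable process, where should the next result
fall?* — and the answer is a **prediction interval** (PI): an interval
that contains a single future observation with a stated probability
(usually 95%).

`labpi` implements the PI for a single future result under the four
provenance scenarios of its two ingredients, the mean and the variance:

| scenario | mean         | variance      | 95% interval                 |
|----------|--------------|---------------|------------------------------|
| 1        | population µ | population σ² | µ ± z·σ                      |
| 2        | sample X̄, n  | population σ² | X̄ ± z·σ·√(1+1/n)            |
| 3        | population µ | sample s², n  | µ ± t(n−1)·s                 |
| 4        | sample X̄, n  | sample s², n  | X̄ ± t(n−1)·s·√(1+1/n)       |

with z the two-sided normal quantile (1.96 at 95%) and t(n−1) the
two-tailed Student-t value. On top of the kernel it provides:

* **QC monitoring** — establish baseline limits from a data-collection
  period (z-based once n ≥ 30, wider t-based "provisional" limits for a
  new instrument), accept/flag new QC results, export Levey-Jennings
  chart data, and verify coverage by Monte Carlo.
* **Personalized reference intervals (prRI)** — a PI centred on an
  individual's homeostatic set point, either from 3–4 results plus the
  population within-subject biological variation CV_I (scenario 2), or
  from ≥ 5 of the individual's own results (scenario 4) after Dixon's-Q
  outlier and OLS trend screening.
* **Reference change values (RCV)** — conventional
  `z·√2·√(CV_A²+CV_I²)` and personalized `t(n−1)·√2·CV_P`, with
  significance verdicts for a pair of consecutive results
  (Δ% = 100·(x1−x2)/x1).
* **Confidence intervals** — `X̄ ± t(n−1)·s/√n`, always narrower than the
  matching PI.
* **Synthetic data** — the worked-example fixture tables and a seeded
  generator (set point + quadrature-combined CV_P/CV_A noise + optional
  drift/outlier) for testing and power studies.

See `docs/methods.md` for assumptions, rounding policy and limitations.

## Worked example

A laboratory collected 30 daily glucose IQC results (bundled as fixture
`table1`; mean 4.21 mmol/L, SD 0.07 mmol/L). Establish limits and check a
suspicious new result:

```sh
$ labpi fixtures --table table1 --out t1.csv
$ labpi qc establish t1.csv --rounding worked_example --out baseline.json
{"series_id": "table1_iqc_glucose", "regime": "established",
 "stats": {"n": 30, "mean": 4.21, "sd": 0.07, "cv_percent": 1.66},
 "interval": {"lower": 4.0728, "upper": 4.3472, "level": 0.95,
              "multiplier": 1.96, "kind": "prediction",
              "scenario_number": 1, "n_used": null}}
$ labpi qc evaluate --baseline baseline.json --value 4.50
{"value": 4.5, "verdict": "flag", "z_score": 4.1429,
 "rule": "above 95% PI limit 4.347"}
```

The 95% PI is 4.07–4.35 mmol/L: a new result of 4.16 is accepted as
expected variation, while 4.50 is flagged as a possible random error or
unreproducible measurement.

For a patient with ten weekly glucose results (fixture `table5`), the
own-data personalized reference interval and the personalized RCV:

```sh
$ labpi fixtures --table table5 --out t5.csv
$ labpi prri t5.csv --series glucose
{"series_id": "glucose", "unit": "mmol/L", "lower": 3.91, "upper": 4.67,
 "level": 0.95, "multiplier": 2.26, "kind": "prediction",
 "scenario_number": 4, "n_used": 10}
$ labpi rcv --cv-t 3.73 --n 10
{"rcv_percent": 11.93, "kind": "personalized", "cv_kind": "cv_t",
 "n": 10, "level": 0.95}
$ labpi change 4.22 5.11 --rcv 11.93
{"x1": 4.22, "x2": 5.11, "delta_percent": -21.09, "rcv_percent": 11.93,
 "significant": true, "direction": "increase"}
```

This patient's glucose prRI is 3.91–4.67 mmol/L, and a day-to-day rise
from 4.22 to 5.11 mmol/L (|Δ| = 21.1%) exceeds the personalized RCV of
11.9%, so the change is significant even though both results lie inside
the population reference interval — the point of personalizing the
threshold.

The same operations are available as library calls:

```python
from labpi import fixture_table, compute_prri

series = fixture_table("table2")          # 4 sampling occasions
prri = compute_prri(series, mode="cvi_based", cv_i=5.00,
                    rounding_mode="worked_example")
print(prri.rounded(2))                    # lower=3.75, upper=4.67
```

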