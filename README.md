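# theatreflow

Does the order of an operating list change how long each operation takes?
Surgeons may *warm up* as they repeat the same procedure within a list, and
lose time when they *switch* to a different one.  `theatreflow` is a Python
library for estimating these list-composition effects from routinely
collected procedure records, together with a synthetic theatre-list
generator so the whole analysis chain can be exercised and validated
without access to any patient data.

It is aimed at researchers working with theatre records (one row per
performed procedure: surgeon, hospital, date, start time, procedure code,
patient age band, ASA grade, duration) and at methodologists who want a
tested reference implementation of the two estimators involved.

## The model

Each case on a theatre list — the ordered procedures one surgeon performs
at one hospital on one day — is coded with its **absolute list number**
A (position on the list), its **procedure-specific list number** S (how
many times that procedure has occurred on the list so far) and a
**switch** flag W (the preceding case was a different procedure; the first
case of a list is coded 0).

Operating times are zero-bound and right-skewed, so effects are additive
on the natural-log scale.  The primary estimator is a linear mixed-effects
model, fitted by REML:

    log T = μ + β_abs (A−1) + β_spec (S−1) + β_switch W + b_cell + ε,
    b_cell ~ N(0, τ²),   ε ~ N(0, σ²)

with a random intercept `b_cell` shared by all cases of the same
(procedure, age group, ASA grade) cell — controlling for casemix without
assuming any functional relationship between age, ASA and baseline time.
A log-scale coefficient β is rendered as the percent change
`100·(e^β − 1)`, the geometric-average proportional change.

The second estimator is a randomized exact-matched paired analysis:
within each procedure, cases at procedure-specific position 1 are paired
with position-2 cases that have identical age group and ASA grade (random
scan order, uniform random candidate choice, unselected candidates
returned to the pool), and the effect of repeating a procedure is the mean
within-pair difference in log duration, with a paired-t CI.  Because
matching is exact on the cell, every cell yields min(n₁, n₂) pairs
regardless of the random seed.

The same machinery fits log length of stay as a secondary outcome, and
repeats the matched analysis stratified by surgical method (open vs
minimally invasive) and complexity grade.

## A worked example

```python
import theatreflow as tf

cfg = tf.GeneratorConfig(seed=7)          # defaults: ~35k records, 35 procedures
raw = tf.generate_dataset(cfg)            # raw EPR-like rows, noise included
clean, summary = tf.clean_records(raw)    # exclusion flow with full accounting
coded = tf.assign_list_numbers(tf.build_lists(clean))
fit = tf.fit_lmm(coded, outcome="duration")
```

Running `python examples/02_simulate_and_fit.py` prints:

```
generated 35265 rows, retained 34502 after cleaning
switch fraction: 52.0%

absolute_order   -0.44% (95% CI  -0.63 to  -0.24)   generating value -0.39%
specific_order   -1.19% (95% CI  -1.92 to  -0.46)   generating value -0.98%
switch           +6.21% (95% CI  +5.16 to  +7.27)   generating value +6.48%
```

Each line is the estimated percent change in operating time per unit of
that covariate with its Wald 95% CI; the generator's true effect sizes
fall inside every interval.  `examples/03_matched_analysis.py` does the
same for the matched estimator (a −6.18% generating repetition benefit,
recovered as −6.15%, CI −7.31 to −4.98), and `examples/04_full_pipeline.py`
runs every stage and writes all tables plus a replayable manifest.

A thin CLI mirrors the library (`theatreflow simulate / code / fit /
match / run`), e.g.:

```bash
theatreflow simulate --out scratch/demo --seed 1
theatreflow code --input scratch/demo/simulated.csv --out scratch/demo
theatreflow fit --coded scratch/demo/coded.csv --outcome duration --out scratch/demo
```

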