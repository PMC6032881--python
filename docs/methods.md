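# Methods

## List coding

A theatre list is keyed by (surgeon, hospital, date); the key is
configurable (`include_hospital=False` treats a surgeon's whole day as one
list) because routine records do not themselves say where one "list" ends.
Within a list, cases are ordered by start time with ties broken by record
id — a deterministic rather than realistic tie-break, chosen so that the
coding of a dataset is a pure function of its contents.  The first case of
every list has its switch flag coded 0 (no preceding case, no switch
cost); this keeps the covariate defined everywhere, and `fit_lmm` offers
`drop_first_position=True` as a sensitivity check that removes first
cases from estimation entirely.  No attempt is made to repair list
numbering around suspected cancellations or data holes: holes are
tolerated as noise, which if anything attenuates order effects, and any
repair would require subjective inference.

Cleaning applies exclusion rules in a fixed order — missing surgeon id,
missing start time, duplicate row (byte-identical to an earlier row; the
earlier one kept), non-positive duration, unrecognized age/ASA category —
counting each row under the first rule that catches it, so the summary
partitions the input exactly.

## Mixed-effects model

The duration model is a single-grouping-factor random-intercept model on
log duration: fixed effects (A−1), (S−1), W entered as numeric covariates,
random intercept per (procedure, age group, ASA grade) cell, fitted by
REML (statsmodels `MixedLM`).  Treating the cells as exchangeable and
mutually independent is deliberately conservative: it controls for casemix
without modelling how baseline times vary with age or ASA.  Covariates are
centred at the first position so the intercept reads as a first-position,
non-switch log baseline; slopes are invariant to that shift.

Numerical choices: the optimizer chain is lbfgs → bfgs → powell →
Nelder–Mead, falling through on non-convergence or linear-algebra failure
near the τ = 0 boundary (small or balanced inputs can profile the cell
variance to zero, where gradient methods may fail); CIs and p-values are
Wald at α = 0.05; a covariate with no variation (e.g. no switches in a
subset) is reported as undefined (NaN), never as zero.  Per-procedure
fits refit the model within each code with (age, ASA) cells, skipping
codes below a case-count floor (default 200); no multiple-testing
correction is applied across per-procedure fits, and this is a display
convention, not an inferential claim.  Percent renderings use
100·(e^β − 1) throughout; the linear approximation 100·β is also exposed
(`pct_linear`) and differs only beyond the second decimal at these effect
sizes.

The length-of-stay model is structurally identical on log minutes of
stay; its switch coefficient is always reported even when its CI covers
zero.

## Matched analysis

Matching is exact on the (procedure, age group, ASA grade) cell between
procedure-specific positions k and k+1 (default 1 vs 2; k is a clearly
labelled generalization).  The implementation scans the position-k pool in
a seed-shuffled order and picks uniformly among compatible position-(k+1)
candidates, removing both; non-selected candidates remain available.  For
exact-cell compatibility this greedy is provably maximal — each cell
yields min(n_k, n_{k+1}) pairs for every seed, which the tests assert
against a counting oracle — so the seed affects pair membership but never
the pair count.  The paired estimate uses the two-sided paired t
procedure on log differences; with all differences equal the SE is zero
and the interval degenerates to a point.  One seed governs both the scan
shuffle and the candidate choices and is recorded in the result for
replay.

## Synthetic generator

The generator emulates a multi-hospital elective-surgery record extract
under exactly the generative reading of the fitted model: log-normal
durations with per-procedure baselines, independent N(0, τ²) cell
intercepts drawn once per (procedure, age, ASA) cell, additive fixed
effects of A, S and W, and N(0, σ²) residuals (a Student-t option,
`residual_law="t"`, exists for misspecification checks).  Length of stay
follows the same form with its own coefficients and residual SD.  Raw
rows carry no order codes and no latent values: downstream stages must
recompute the coding, as they would on real data.

Default conditions, chosen once:

- **Effect sizes** — β_abs, β_spec, β_switch log-equivalents of −0.39%,
  −0.98% and +6.48% per unit; length-of-stay effects +0.55% and −0.72%,
  with the stay/switch coefficient set to 0 (it was reported
  non-significant with no printed magnitude, so zero is the only
  information-consistent choice).
- **Scale** — 9000 lists ≈ 35–40k records: desk scale, minutes of CPU for
  the full test suite.  The acceptance script raises this to ~66 000
  lists ≈ 255k records, the scale at which the pooled estimates it
  reproduces were originally computed.
- **Composition** — list lengths 1–12, truncated-geometric (mean ≈ 3.9);
  procedure sequences first-order Markov with repeat probability
  `p_same = 0.27`, whose closed-form consequence (given mean list length
  and the chance a fresh draw repeats the previous code) is a ~52% overall
  switch fraction, matching the share of switching cases in the data the
  analysis is modelled on.
- **Casemix** — 35 procedures with log-spaced baseline durations
  (12–150 min), sampling weights decaying with rank, age skewed towards
  older bins, ASA towards grades I–II.
- **Variances** — τ = 0.25, σ = 0.35 (log scale), typical of surgical
  duration data; note the *fitted* cell SD is larger (≈ 0.8) because the
  model's cells also absorb the spread of per-procedure baselines.
- **Noise** — missing-surgeon, missing-start and duplicate rates equal to
  the proportions observed in the real exclusion flow (≈ 1.84%, 0.30%,
  0.007%), injected by blanking fields and re-emitting uniformly chosen
  rows.

What the generator does *not* emulate: turnover and anaesthesia time
(start times are fixed 40-minute slots — only within-day order matters to
the analysis), surgeon learning across days, seasonal effects, erroneous
(as opposed to missing) entries, and any dependence of casemix on surgeon
or hospital.  Passing recovery tests therefore shows the estimators are
correct under the model they assume, plus the injected missingness — not
that the model is correct for any particular real dataset.

## Validation strategy

Three independent oracles back the estimators: a brute-force profiled-REML
search (1-D bounded optimization over the variance ratio, with GLS
coefficients and the residual variance profiled out in closed form) that
must agree with the package fit to 1e-4 on small instances; a per-cell
min-count oracle for the matcher; and closed-form percent conversions
exact to 1e-10.  Recovery tests check that CIs cover the generating
values at full scale and that empirical CI coverage over 200 replicates at
n ≈ 2000 sits within 95 ± 3 points.  The acceptance script averages its
recovered estimates over independent replicates (16 mixed-model, 3
matched) purely to reduce Monte Carlo error in the reported numbers.

## Known limitations

Crossed random effects (surgeon, hospital), random slopes, profile-
likelihood CIs, propensity or caliper matching and causal-identification
machinery are out of scope.  The cleaning step detects only byte-identical
duplicates.  Matching ignores surgeon and hospital, so a pair may span
sites; cells are (procedure, age, ASA) only.
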