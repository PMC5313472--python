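# Methods

`herdfap` predicts, for every dairy cow on every herd-test day, the **future
average production (FAP)**: the expected production value of milk, in kg per
day of remaining life (dry periods included), from herd recording data
alone.  FAP is a ranking signal for culling decisions and an ingredient for
within-herd simulation models.  This note documents the model, its
assumptions, the tunable parameters, the synthetic-data generator, and the
numerical and design choices.

## Model

### Energy-corrected milk and total cell count

Test-day milk is converted to energy-corrected milk,
`ECM = milk (0.122 fat + 0.077 protein + 0.249)` (kg/day, fat and protein
in percent), so that yields are comparable across compositions.  Somatic
cell counts are modelled as *total* test-day cells, `tSCC = SCC * milk`
((x1000 cells/mL)*kg), which stabilises residual variance relative to
modelling concentration directly; concentrations are recovered by dividing
by milk whenever a price is computed.

### Herd curves and cow levels

Each herd's average lactation is described per parity group (1, 2, 3+):

* milk: a Wood-type curve with a pregnancy decline,
  `f(t) = alpha_m * a * t^b * exp(-(c + I_P d (t - t_P)) t)`, where `t` is
  days in milk, `I_P` pregnancy and `t_P` the conception day.  The
  typeset source of this form is ambiguous about whether the pregnancy term
  multiplies `t`; both parses are implemented (`literal`, the default
  shown, and `additive`), selectable per fit and recorded in model
  metadata.  The framework is explicitly insensitive to the specific curve
  family.
* tSCC: a Wilmink-inspired double exponential fitted on the log scale,
  `f(t) = exp(exp(alpha_c a + b t) + d exp(-exp(c) t) - e)` with `e`
  Euler's number (absorbable into `a`; kept for fidelity to the published
  form).  The early-lactation term `d exp(-exp(c) t)` captures the
  fresh-cow cell spike.

A cow is reduced to one *level* per quantity per lactation (`alpha_m`,
`alpha_c`), relative to the herd-average cow: herd parameters are fitted
first with all levels at 1, then each cow's level with herd parameters
fixed.  At least **six test days** are required to fit a level; lactations
below that keep level 1 (or a dam-derived prior when available).  Because
`alpha_c` sits inside the inner exponential, its fitted spread is
numerically small (~0.02) even though the cow-to-cow spread of tSCC itself
is ~40%; the two are monotonically linked.

### Carry-over, survival, smoothing

* **Carry-over.**  Level deviations regress toward 1 between lactations:
  `alpha_l - 1 = xi (alpha_j - 1)`, with `xi` the no-intercept regression
  slope of later on earlier deviations (typical value 0.3).  Skip-lactation
  correlations are chained products of the per-step estimates.
* **Survival.**  The probability of at least one further lactation, as a
  function of days open, is a Richards decay
  `S(t) = A - A / [1 + (2^nu - 1) e^{-B(t-M)}]^{1/nu}` — equal to `A/2` at
  `t = M`, non-increasing, in `[0, A]`.  It is fitted by weighted least
  squares to binned empirical survival fractions, restricted to cows with
  `alpha_m >= 1`: below-average cows are culled for reasons beyond days
  open (manager selection, disease), while at-or-above-average cows show
  stable survival.  Given survival past lactation `j`, the distribution of
  the final lactation reached is `gamma` (normalised to sum to 1 — the
  source does not state a normalisation, and the survival-weighted
  combination below requires one).
* **Smoothing.**  Every record is converted to a relative level against the
  herd curve and folded into exponentially smoothed estimates
  `x~_t = lambda x_t + (1 - lambda) x~_{t-1}` (initialised at 1, or at the
  dam-correlated value when dam information exists).  `lambda` is chosen by
  a grid search (step 0.01) minimising the squared distance between the
  smoothed value at each time point and the mean of all future observations
  of the same cow — a deterministic, robust alternative to continuous
  optimisation.

### Pricing: production value of milk

Milk price carries a bulk-tank SCC correction in stepwise percentage bands.
The default scheme is +2% below 200, 0% in 200–300, −2% in 300–400, −4% in
400–500 (x1000 cells/mL); the +2 and −4 anchors follow the published Danish
scheme and the intermediate bands are a configurable convention.  The steps
are made continuous by linear interpolation through band-midpoint anchors
with linear extrapolation, so every marginal change has a price impact.

A cow's **production value of milk** is her ECM plus the whole-herd price
effect of removing her from the tank:
`PVM_c = ECM_c + [f(SCC_B) - f(SCC_B + Delta_c SCC_B)] * sum_i ECM_i`,
where `Delta_c SCC_B` is the bulk SCC without minus with the cow.  The same
high-cell cow is charged less in a large herd (dilution).  During
prediction the herd's bulk SCC and totals are frozen at their
training-period means; predicted ECM is converted to a raw-milk proxy with
the herd's ECM/milk ratio before entering the mixing formula (the method
needs a volume weight and the curves predict ECM — a documented
convention).

### FAP assembly

With gestation 282 d, dry period 56 d and a standard 61 d to conception,
the predicted last day in milk is `DIM_L = DIM_P + 226` for pregnant cows
and `max(DIM + 226, 287)` for open cows.  Then

* `FP_C`: predicted PVM summed daily from the current DIM to `DIM_L`;
  `FAP_C = FP_C / T_RC` with `T_RC = DIM_L - DIM + 56` (the dry period
  belongs to the remaining time);
* `FP^F_l`: a future lactation's production, summed over the standard
  lactation (days 3–287) with both smoothed levels shrunk toward 1 by
  `xi`; `FAP^F_l = FP^F_l / T_S` with `T_S = 343 = 282 + 61`;
* the survival-weighted combination over life courses:

      FAP = (1 - S) FAP_C
            + S * sum_{l=j+1}^{n} gamma_jl (FP_C + sum_{m=j+1}^l FP^F_m)
                                  / (T_RC + (l - j) T_S)

  with `S` evaluated at the cow's days open — her DIM when open, her
  conception day when pregnant (she stopped being open at conception) —
  and a horizon of `n = 8` lactations (configurable; sensitivity beyond 8
  is negligible because `gamma` mass vanishes).

One source table lists `T_S = 321` while the defining ratio prints
`FP/(282+61)`; this package uses 343 and treats 321 as an erratum (either
value can be configured).

Current-lactation predictions use the cow's *actual* recorded pregnancy
state; hypothetical future lactations are evaluated without a pregnancy
term, exactly as the future-production formula is printed.  A switch
(`assume_future_conception`) instead activates the decline from the assumed
conception day everywhere, for users who prefer a biologically complete
projection; the default follows the printed form.

## Fitting pipeline

Per herd: derive records → herd curves per parity group → cow levels →
`xi` (per parity step, pooled fallback below 10 pairs) → survival on the
`alpha_m >= 1` subset (binned LS, 5 multi-starts, bounds `A in (0.2, 1]`,
`B in [5e-4, 0.2]/d`, `nu in [0.2, 5]`, `M in [0, 600] d`) → `gamma` →
`lambda` → bulk operating point.  Multi-herd fits add three
partial-pooling steps, each a deliberate design choice:

* **Pregnancy-decline rate `d`.**  Within one herd most records come from
  pregnant cows, so `c` and `d` are nearly collinear and the *non-pregnant*
  curve level (needed to predict future lactations) is undetermined to
  ±10–20%.  Pregnancy decline is cow biology, not herd management: `d` is
  set to the across-herd median of free fits per parity group and the herd
  curves refitted with it fixed.
* **Survival and `gamma`.**  A 4-parameter sigmoid on a few hundred binary
  outcomes is noise-dominated; herds contributing fewer than 400 usable
  outcomes receive the across-herd pooled estimates.
* **`lambda`.**  One global pair (milk, scc) across herds, the method's
  stated default; per-herd values apply when fitting a single herd.

`gamma` is estimated with censoring-aware product-limit continuation
probabilities (a lactation whose next calving would fall past the data end
has an unknown outcome).  Restricting to completed histories — the naive
estimator, also provided — is biased toward short lives in observation
windows of a few years.

## Synthetic herds

The generator emulates national milk-recording structure: herds tested 6 or
11 times per year; per-cow milk levels `N(1, 0.4)` (floored at 0.05);
lognormal tSCC levels (median 1, log-sd 0.385, i.e. ~0.4 multiplicative
spread); AR(1) carry-over `xi = 0.3` for both; test-day noise 2.0 kg ECM
and 0.3 log-tSCC; conception at `21 + Gamma(1.3, 30.77)` days (mean 61);
gestation 282 d, dry 56 d; survival to the next lactation Bernoulli with
the Richards decay (`A=0.93, B=0.012, nu=1.3, M=145`) at the conception
day; culled cows replaced by heifers.  Curve scales are calibrated so
per-parity mean ECM lands at typical Holstein herd medians (25.7 / 29.1 /
30.3 kg/day) — a realism calibration, not a fit.  Everything is
reproducible from the config seed and ships with a `TruthBundle` of all
latent quantities.

What the generator does **not** emulate: disease processes, seasonality,
yield-dependent manager culling bias (survival depends only on days open,
so model assumptions match the generator by construction), dam pedigrees,
and within-lactation drift of cow levels.  Passing recovery tests therefore
demonstrate estimator correctness under the model's own assumptions, not
robustness to real-data violations of them.

## Numerical choices

* Curve fits: `scipy.optimize.least_squares` (trust-region reflective),
  5 multi-starts from perturbed Wood-type initial values, seed-controlled;
  tSCC on the log scale; the log-tSCC exponent is clamped at 80 (logged at
  debug level — routine during optimizer exploration).
* Cow milk levels have a closed-form least-squares solution; cow tSCC
  levels use bounded scalar minimisation on `[0.01, 3]`.
* Daily production sums use integer DIM steps with inclusive bounds; a
  prediction day past the predicted dry-off returns `FP_C = 0` with a
  warning and `T_RC = 56`.
* Degenerate inputs: all-surviving cohorts return a flat curve at `A = 1`;
  single-cow herd days define the bulk-without-cow as 0; records with zero
  milk weight are rejected into a side-car report, never silently dropped.
* Serialization: YAML with shortest-repr floats (exact round trip).

## Evaluation design and its limits

Out-of-sample evaluation compares FAP at every test-period cow-day against
the *realized weighted future-mean PVM*: the mean of the cow's future
observed PVM multiplied by `(281 + 61 - 56)/(281 + 61)` (the constant kept
exactly as printed in the source design, including the 281), versus three
naive predictors (latest PVM, mean of last three, lifetime mean), per herd,
with continuity-corrected Wilcoxon rank-sum comparisons across herds.

Two properties of this comparator matter when reading results.  First, it
conditions on survival: only living cows produce future observations, while
FAP prices in the probability that production stops.  Second, its fixed
dry-off weight assumes a full-parity dry share (56/342); for late-lactation
cow-days the true remaining horizon is mostly dry period, so the comparator
sits above any correctly computed per-day average.  On model-matched
synthetic herds with a one-year test window these two effects leave a
herd-mean gap of roughly 1 kg/day concentrated at high days in milk —
visible even with the generator's true parameters plugged in, i.e. it is a
property of the comparison, not an estimation error.  FAP nevertheless
beats all three naive predictors by a wide margin on every synthetic
configuration tested.

## Known limitations

* Per-herd survival asymptotes (`A`) are extrapolations: conception rarely
  happens after ~180 days open, so the lower plateau of the decay is
  unobserved and `A`, `B` estimates at 100-cow-herd scale carry
  finite-sample bias (the fitted curve is well calibrated where conceptions
  occur).
* Fitted carry-over for tSCC is mildly attenuated by measurement error in
  per-lactation levels (classical errors-in-variables; plain regression is
  used deliberately, matching the method's original formulation).
* The pricing scheme ships only the two published anchors plus convention
  bands; users should configure their processor's actual scheme.
* No economic layer (feed, replacement prices, retention pay-off), no
  Kalman-filter level tracking, no disease-specific correlation structures.
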