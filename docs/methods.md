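# Methods

## Fitness from colony size

The pipeline converts daily colony areas into per-generation selection
coefficients in five steps.

**Calibration.** Colony area S (pixels) and population size N (cells) are
related by ordinary least squares on log10 scales,
`log10 N = a·log10 S + b`. The published coefficients
(a = 1.46397, b = 3.19251, R² = 0.9689) ship as `PUBLISHED_CALIBRATION`; users
with their own excised-colony counts can refit with `fit_calibration`
(unweighted OLS of log-cells on log-size; the regression direction is fixed
to match the shipped equation). The inverse map uses the same line, so the
size↔cells round trip is exact.

**Day-0 anchoring.** Pinning deposits a roughly constant cell number
regardless of culture density, so every trajectory's day-0 record is set to
the mean pinned size (57 px ↔ 579,506 cells). Records zeroed by the imaging
software must carry an explicit `zero_flag`: `present` re-enters the record
at the day-0 size (status `RESET_TO_DAY0`), `absent`/`complicated` discards
the whole colony trajectory. The software never guesses this adjudication —
it was a visual call in the original workflow and cannot be automated
faithfully.

**Generation axis.** For each plate × condition, each ancestor replicate
contributes g(day) = log2(N_day/N_0); the axis is the per-day mean over all
ancestor replicates, both members of the ancestor pair pooled
(log-then-average; the alternative average-then-log differs only at second
order in the replicate spread). A non-growing ancestor yields a degenerate
axis and downstream slope fits are rejected rather than returning 0/0.

**Slopes and s.** Each colony's Malthusian rate is the OLS slope of
log(cells) on g over days 0–4 (flagged intermediate days are dropped from
that colony's regression). `s = slope(evolved) − mean(per-replicate ancestor
slopes)`. Two response logs are supported: natural log (default; slopes are
directly comparable to the competitive assay's ln-ratio regression, and an
ancestor regressed on its own axis has slope ln 2) and log2 (ancestor slope
1, so a slope difference reads as doublings-per-generation; the two differ
by exactly the factor ln 2). `fitness_by_day_window` restricts the
regression to days 0..d; on noisy data the replicate SD of s falls
monotonically as the window grows to day 4, matching the error ordering the
assay was designed around.

## Spatial effects

Positions are concentric layers (layer 0 = outer ring; a 16×24 plate has
layers 0–7). Layer-vs-center deviations are tested with Welch two-sample
t-tests under BH-FDR across layers. The four plate corners are excluded from
all analysis by default (their variance is disproportionate even on trimmed
plates); per-ring corners are not treated specially.

`rowcol_normalize` performs two sequential multiplicative passes: each value
is scaled by (grand statistic)/(row statistic), statistics are recomputed,
then scaled by (grand)/(column statistic). With the mean statistic the
output column means equal the output grand mean exactly, and a plate whose
structure is exactly multiplicative row × column flattens to its grand mean
in one application (idempotent to machine precision there; generic noisy
plates re-normalize only to second order, ~0.5% at 0.5% base noise). An
additive variant (value − row mean − col mean + grand mean) and a per-layer
mean normalization are provided.

**Known attenuation.** Row and column means contain the focal colony's own
strain signal. Conditional on a colony's position, its row is enriched for
its own strain by (1 − 1/k) colonies (k = number of strain groups), so mean
normalization shrinks the evolved-minus-ancestor slope difference by
approximately (1 − 1/k)(1/n_cols + 1/n_rows) — about 9–10% of s on a 384
plate, independent of the strain mix. This is an intrinsic property of
row/column mean normalization with replicated strains, the flip side of the
caveat that normalization can remove strain signal when size differences are
extreme. Consequence: on edge-free or trimmed synthetic data the unnormalized
anchored pipeline recovers s unbiasedly, while the normalized pipeline
recovers ~0.9·s; the test suite asserts both behaviours. A further caution:
cycling a single strain permutation along the snake path (the default
layout) places strains periodically, which can interact with normalization
to give layout-specific biases; `reshuffle_each_cycle=True` draws a fresh
permutation per block and removes the periodicity.

## Snake layouts

`make_snake_layout` enumerates positions ring by ring from the plate edge
inward, clockwise from (0,0) — the traversal direction is a fixed convention
for reproducibility — and assigns strains by cycling a seeded permutation
(optionally re-drawn per block, above). Every strain gets an equal number of
positions (±1) and appears in every layer at least once per cycle, which is
what lets spatial effects cancel in the evolved-vs-ancestor contrast.

## Liquid growth parameters

From a 24-h OD600 trace on the 4-minute grid: **max_rate** is the largest
OLS slope of ln(OD) in a 15-point (1 h) sliding window (ties to the earliest
window); **lag** is the intersection of the line fitted to the first 15
ln(OD) points with the max-rate window's line (undefined, not clamped, when
the two are parallel within 1e-6 h⁻¹, e.g. growth from t = 0; lags more than
1 h before the first sample are flagged suspicious); **auc** is the
trapezoidal integral of ln(OD) minus the rectangle under the smallest
measured ln(OD); **capacity** is the maximum OD observed. Natural log
throughout, rates in h⁻¹. No blank subtraction or detector-nonlinearity
correction is applied; inputs are assumed blank-corrected and positive.

The window estimator has two small, opposite-signed biases: averaging over a
1-h window underestimates the instantaneous maximum of a logistic (a few
percent when the inoculum is ≥10% of capacity), and maximizing over many
noisy windows selects upward (≈1 SD of the per-window slope error — at
0.002 OD noise and OD ~0.1 this is ~0.02 h⁻¹). Recovery tolerances are
therefore stated per-curve for noise-free curves and as means over 100
curves for noisy ones.

## Competitive fitness

Gates are fitted classically (sample mean/covariance; an optional 1%-trimmed
robust variant) on the pooled events of one day × condition: a 99%
chi-square(2) Mahalanobis ellipse on log10(SSC-A) × log10(FSC-A), then a 95%
ellipse on FSC-H × Width of the survivors. The YFP threshold is the midpoint
between the two largest peaks of the log10 YFP-A histogram (256 bins,
9-bin moving-average smoothing, peaks must reach 5% of the mode and be
separated by a valley dipping below half the smaller peak — guards without
which Poisson bin noise splits single modes); once set on the first day it
is held constant, and a user-supplied threshold overrides detection, since
the original gate was placed manually. Reference-only controls give the
false-negative fraction f (fraction of gated marked cells below threshold;
values above 0.5 are flagged implausible), and the unmarked:reference ratio
is `Total·(1−f)/P − 1`, i.e. the true marked count is P/(1−f). Ignoring the
correction inflates the ratio to (R + f)/(1 − f) for true ratio R.

Generations per daily cycle are log2(conc_end/(conc_prev_end · dilution))
with one 1/1000 dilution per 24 h, concentrations taken from the ancestor
cultures (gated events / acquired volume, or supplied directly); s is the
OLS slope of ln(ratio) on the cumulative axis, and an evolved strain's
fitness difference is s_evolved − mean(s of its two ancestors).

## Synthetic data

`simulate_plate` draws colony cells as
`N0 · 2^(g(day)·(1+s)) · edge(layer, day) · e^(σZ)` and inverts the
calibration to sizes. Defaults: g = (0, 3.0, 4.8, 5.7, 6.03) doublings —
saturating growth reaching ~3.8×10⁷ cells by day 4 from the 5.8×10⁵-cell
pin; σ = 0.05 (natural-log size noise per colony-day); a linear edge ramp
over the outer 4 layers growing with day, amplitude 0.12·day intact vs
0.03·day trimmed (so trimming cuts the effect ~four-fold and intact plates
show more layer-explained variance, as diagnostics expect). On this
convention truth is a doubling advantage, so the log2-response estimator
recovers s on its own scale. The generator does not emulate pinned-cell-count
variability (anchoring absorbs it; an option could inject it), colony
merging, or condition-dependent calibration drift — passing recovery tests
therefore validates the estimation arithmetic, not image segmentation.

`simulate_growth_curve` holds OD at the inoculum (default 0.1 — an
OD-resolvable inoculum; cultures diluted far below the reader's resolution
are out of scope) until the lag, then follows a logistic to capacity whose
maximum ln-slope equals the requested rate (internal rate r/(1 − od0/K)),
plus Gaussian noise floored at 0.001 OD. `simulate_flow_experiment` draws
per-day event tables from log-normal scatter clusters (single cells plus 2%
debris below the scatter gate and 3% wide-pulse doublets outside the singlet
gate), mixes strain and reference according to a ratio trajectory
r0·e^(s·g), draws a fraction f of reference events dim, and emits matching
reference-only controls and end-of-cycle concentrations (~constant, as
saturating daily cultures give ~log2(1000) ≈ 10 generations per cycle).
Every generator is a deterministic function of its config and seed.

## Statistics

One-sample two-sided t-tests against 0 per strain × condition; BH-FDR across
the groups of one assay (never across assays). RMSE is computed from one-way
ANOVA residuals with the total-n denominator by default (the
degrees-of-freedom variant is an option). Power uses the noncentral-t
distribution of the one-sample t-test; `power_min_detectable` solves for the
effect size reaching the target power (default 0.80 at α = 0.05, reading
"0.95 significance" as α = 0.05) and scales by the error SD. At the
competitive assay's error scale (0.0176) and 32 replicates the minimum
detectable difference is ~0.009 — below 1%. Reproducibility between
experiments is the Pearson correlation of strain × condition mean fitness
(≥3 shared groups required). Confidence intervals in outputs are t-based
95% CIs of the mean.

## Problem sizes used in the validation suite

Plate recovery: one 384 plate, 6 strain groups, 32-replicate subsamples,
days 0–4. Competitions: 7 replicates × 4 daily samplings × 20,000 events.
Growth: 100 curves × 361 points. Null calibration: 200 simulated tables of
24 groups × 32 replicates. These sizes match the study design the package
emulates and keep the full suite under a minute of compute.

## Known limitations

- The size→cells calibration is treated as condition-independent; stress
  media that change colony morphology would need their own calibration.
- Row/column mean normalization attenuates extreme strain effects (~10% of
  s; see above) and cannot help on plates where most colonies fail to grow.
- The flow simulator's clusters are idealized log-normals; spillover
  compensation and instrument drift are out of scope.
- FCS input covers list-mode FCS 3.0/3.1 with float or uniform 16/32-bit
  integer data — the subset the targeted instruments emit.
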