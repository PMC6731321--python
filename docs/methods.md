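# Methods

## The models

Tumor cell burden `T` follows logistic growth, `dT/dt = k (1 - T/theta) T`,
with `T` expressed in fractional-confluence units (1.0 = a fully covered
well), `k` the growth rate (1/day) and `theta` the carrying capacity on the
same confluence scale.  Time is measured in days from plating; treatment
starts at day 1 and every drug exposure lasts 24 h, after which a media
change removes all remaining *free* drug.  Bound antibody and internalized
paclitaxel are untouched by the wash.

**Trastuzumab** acts through bound antibody `A_b`:

    dT/dt  = k (1 - f) (1 - T/theta) T,
    f      = eta_A * A_b        once t - t_apply > t_star_A, else 0,
    dA_b/dt = beta_A (A_f - A_b)(T * r - A_b)   while A_f > 0, else 0,

with `r` the receptor pool per unit confluence (HER2 expression divided by
the 1e6-receptor normalization unit).  The delay `t_star_A` represents the
lag between binding and disrupted intracellular signaling.  `f` may exceed
1: `(1 - f) < 0` is net antibody-driven cell loss, which is what the
observed decline of trastuzumab-treated wells (day-4 confluence 0.24-0.43
versus 0.61 in controls) requires.  Capping `f` at 1 would turn the model
into "growth arrest only" and make `eta_A` unidentifiable above the cap;
we therefore do not clamp it.

**Paclitaxel** acts by shrinking the carrying capacity through internalized
drug `P_i`:

    dT/dt  = k (1 - T/(theta - h)) T,
    h      = delta_P (exp(-gamma_P (t - t_apply - t_star_P)) + S) P_i,
    dP_i/dt = alpha_P (P_f - P_i) T   while P_f > 0, else 0.

The exponential is the immediate toxicity burst: it exceeds the persistent
term until `t_star_P` after application and then decays at rate `gamma_P`.
`S` is the synergy multiplier on the persistent capacity reduction: 1 for
monotherapy (no interaction), > 1 when a partner drug enhances paclitaxel's
long-term effect, < 1 when it diminishes it.

**Combined model**: both mechanisms at once, `dT/dt = k (1-f)
(1 - T/(theta-h)) T`, with the antibody and paclitaxel equations unchanged
and `S` free.

### Numerical choices

* Piecewise integration (LSODA, rtol 1e-6, atol 1e-9) with hard restarts at
  every dose/wash event and at the trastuzumab effect onset
  (`t_apply + t_star_A`), where the right-hand side is discontinuous.
  Same-instant wash-then-dose ordering at day-2 boundaries.
* `theta - h` is floored at `1e-6 * theta` (logged, never a silent NaN) and
  the capacity factor `(1 - T/(theta-h))` at -1e3: a death rate of
  ~k*1000/day is already instantaneous on the 4-day timescale and the cap
  keeps extreme multistart draws integrable.
* When *both* `(1 - f)` and the capacity factor are negative the raw
  product would read as explosive growth; each factor alone encodes cell
  loss, so the product's sign is corrected to net loss.  Without this
  guard, trastuzumab-first combinations (where paclitaxel's toxicity burst
  pushes the effective capacity below a still-high `T` while `f > 1`)
  diverge.
* Conservation equations for the free pools (`dA_f/dt = -dA_b/dt`,
  `dP_f/dt = -dP_i/dt`) are integrated explicitly so that total drug is
  conserved between events.

### Units and dosing

Working drug units are *dose-equivalents per application*: applying a drug
sets its free pool to 1.  Dose strength is carried by the per-dose effect
parameters (`delta_P`, `eta_A`), mirroring an analysis in which every dose
group is calibrated separately; this also keeps every dose group in the
same, identifiable uptake regime.  A physical mode converts doses instead
(25 nM paclitaxel in 100 uL -> 2.5 pmol; ug/mL trastuzumab -> molecules via
a 148 kDa molecular weight).  Confluence converts to cell number as
`cells = confluence * well_area / (pi * cell_radius^2)` with defaults
0.32 cm^2 and 1.25e-3 cm (~6.5e4 cells at full coverage; the 3.5e4-cell
seeding corresponds to confluence 0.537).

## Synthetic data

The generator stands in for unavailable raw microscopy: 8 replicate wells
per condition, sampled every 3 h over 4 days (33 points), for the full
study layout of 16 conditions — control, paclitaxel at 10/25/50/100/250/500
nM, trastuzumab at 10/25/50 ug/mL and six combinations (two paclitaxel
doses x three orderings at 25 ug/mL trastuzumab).

Truth parameter defaults were fixed once by anchoring to the published
summary numbers: growth `k = 0.83`/day and `theta = 0.67` (reported
medians; they put the day-4 control at 0.66, inside the reported control
CI), and per-dose `delta_P`/`eta_A` chosen so the simulated day-4
confluences land on the reported dose-response panel (0.45 -> 0.25 across
paclitaxel doses; 0.43/0.38/0.24 for trastuzumab).  Combination `S`
defaults are the reported calibrated values (0.09-1.47).  The kinetic
defaults (`alpha_P = 0.68`, `beta_A = 2.0`, `gamma_P = 6.35`,
`t_star_P = 0.30`, `t_star_A = 0.6` days) keep uptake/binding on the
exposure timescale and reproduce the qualitative phenotypes — an immediate
monotone paclitaxel response and a ~1-day-delayed trastuzumab response —
without driving the system into the capacity-crash regime, where the
trajectory stops carrying parameter information.  Delay clocks run from
each drug's application time, so a drug applied second behaves the same as
when applied first.

Replicate noise is additive Gaussian with scale 0.025 by default, which
puts the 95% CI half-width of the 8-replicate mean (t-distribution, 7 df)
at ~0.021 confluence, matching the magnitudes printed for the real day-4
data (0.01-0.06 across conditions).  A proportional-Gaussian variant and
optional zero-mean wash-time artifacts exist to probe robustness; both are
off by default.  What the generator does *not* emulate: temporal noise
correlation within a well, heteroscedasticity over time, plate-edge
effects, and model mismatch (data are generated by the same family that is
fitted).  Passing recovery tests therefore demonstrate the pipeline's
correctness and the information content of this design, not robustness to
real-data artifacts.

## Calibration

The objective is the CI-weighted L2 misfit
`sqrt(sum_t ((M(t) - O(t)) / Conf(t))^2)` with `Conf` the per-timepoint 95%
CI half-width floored at 1e-3.  Optimization is bound-constrained
least-squares (scipy's trust-region reflective method) on the weighted
residual vector — the same minimizer as the scalar objective — with a
relative finite-difference step of 1e-4 (above integrator noise).
Multistart draws initial guesses uniformly within the bounds from one
seeded stream; deterministic starts at the package's scale anchors (with
the leading effect-magnitude parameter swept over a decade) are included
because the per-dose effect magnitudes span that range.  The lowest
objective wins; ties keep the first-found start.

Stages: (1) logistic `(k, theta)` per control set under wide global bounds
(`(1e-6, 10 * anchor)`), envelope across sets expanded by a multiplicative
margin (default 10%) -> the allowed range for all treated sets; (2)
`(k, theta)` on each treated set's first 24 h within that range, then
frozen (the pre- and post-treatment windows are closed on the left);
(3) the applied drug's parameters on days 1-4 by multistart; (4) for
combinations, first-drug parameters tuned on day 1-2 within
`value * (1 +/- mean recovery error)` intervals from the verification
study, then second-drug parameters plus `S` (bounds [0, 5], started at the
no-interaction value 1) on days 2-4; simultaneous regimens tune everything
plus `S` on days 1-4.  The drug-free part of every prediction is evaluated
with the closed-form logistic solution — exact and cheap — and the treated
part by the piecewise integrator.

## Verification study and identifiability

For each condition (control plus all nine single-dose groups) the study
draws truth parameters uniformly — growth parameters within +/-5% of the
defaults (wells of one cell line plated from one passage), drug parameters
within +/-20% of the per-condition defaults — simulates, adds noise,
re-calibrates with the same sequential pipeline, and reports the mean
absolute percent error per parameter (median/max/min across parameters).
The +/-20% intervals double as the drug-stage calibration bounds of the
protocol: truths are drawn inside them and fits may not leave them.
`(k, theta)` recovery is scored on the control sets, where the full growth
curve identifies them; on treated sets the pre-treatment stage only pins
them inside the control-derived range.

At zero noise the pipeline recovers every parameter essentially exactly
(median across parameters ~0.02%, worst parameter ~1%; desk scale of 5
sets per condition).  At experiment-matched noise the picture changes
qualitatively: because the wash freezes the internalized/bound pools, the
late trajectory constrains only the products `delta_P * P_i(wash)` and
`eta_A * A_b(wash)`, and the separate factors are informed solely by the
early uptake/binding shape — a signal comparable to the replicate noise.
Profile analysis (restarting the optimizer at the generating truth) shows
the local maximum-likelihood scatter alone is ~6-15% for the kinetic
pairs, i.e. the limitation is the information content of the design, not
the optimizer.  Measured at desk scale (8 sets per condition, 12 starts,
noise scale 0.025) the per-parameter mean errors have median ~13% and
maximum ~21%.  Sub-percent per-parameter recovery at this noise level is
therefore not achievable for this design; it is reachable only in the
low-noise limit, and the package reports what it measures.  The practical
consequence for combination fits is mild: the verification errors are used
as tuning-interval widths, and `S` remains well identified (see below)
because the tuning intervals bound the compensating parameters.

## Synergy metrics

`S` recovery on synthetic combination data (trastuzumab-first, 25 nM
paclitaxel, experiment noise): data generated with `S = 1` fit back within
[0.9, 1.1] and `S = 1.5` within 10%, with first/second-drug parameters
tunable inside 5% intervals.  `S` and `delta_P` enter the persistent
capacity term as a product, so `S`'s accuracy is anchored by the tuning
interval of `delta_P` — the reason the tuning stage exists.

The Loewe combination index is `CI = [A]/[A*] + [B]/[B*]` with `[X*]` the
monotherapy dose achieving the combination's day-4 response.  With a
discrete dose panel the reference lookup is conservative: the smallest
tested dose whose response is at least as strong (confluence at or below
the target; ties count as achieving it).  Non-monotone panels are
isotonically adjusted (pool-adjacent-violators) with a warning before
lookup.  Reporting follows the paclitaxel axis: an exact paclitaxel match
gives a point value; a bracketed response gives the CI at both bracketing
paclitaxel doses as an interval; a response stronger than the strongest
tested dose gives an upper bound (largest dose as reference).  The
trastuzumab term always uses its conservative reference.  This rule
reproduces all six published table entries exactly (0.75; [0.7, 0.9];
0.55; <0.7; <0.55; <0.7); the source text calls its values "approximated"
without stating a rule, so this is a reconstruction validated against the
printed numbers.  Log-dose linear interpolation is a possible refinement
but is deliberately not the default, because it would break that exact
correspondence.

The concordance correlation coefficient
`CCC = 2 Cov(x,y) / (Var(x) + Var(y) + (mean x - mean y)^2)` (sample
moments, ddof 1) measures model-data agreement; it is symmetric, bounded
by the Pearson correlation in magnitude, and errors on degenerate input
(constant equal series).

## Problem sizes

Default desk scales: verification 8 sets per condition x 10 conditions
with 12 multistart seeds (the full-scale analog is 100 sets and 100
seeds); zero-noise verification 5 sets; combination fits 10-20 starts.
These sizes keep a complete run in minutes while leaving the Monte-Carlo
summaries stable to well under the asserted margins.

## Known limitations

* Single cell line; no pharmacokinetic decay, receptor trafficking or
  efflux; one antibody per receptor.
* The synergy formulation is the persistent-capacity multiplier only;
  alternative couplings (timing, binding, toxicity burst) are extension
  points, not implemented.
* No uncertainty quantification beyond the recovery study; no global
  sensitivity analysis.
* Table-scale constants mix units in the source material; this package's
  normalized scale is self-consistent but not unit-identical to the
  original fits, so parameter values are comparable in structure, not
  numerically one-to-one.
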