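# Methods

## The model

`bcgtx` models a standard induction course of intravesical Bacillus
Calmette-Guérin (BCG) immunotherapy for non-invasive bladder cancer as a
six-compartment impulsive ODE system.  The state is
`(B, E, T_i, T_u, H_u, H_i)`: intravesical BCG, effector immune cells,
BCG-infected and uninfected cancer cells, and uninfected and BCG-infected
healthy urothelial cells.  Outside instillations the dynamics are

```
dB/dt   = -p1 E B - p2 B T_u - p8 B H_u - mu_B B
dE/dt   = -mu_E E + alpha (T_i + H_i) + p4 E B - p5 E T_i - p6 E H_i
dT_i/dt =  p2 B T_u - p3 T_i E
dT_u/dt =  lambda T_u - p2 B T_u - p3 T_u E
dH_u/dt =  p7 H_u (1 - (H_u + H_i + T_u + T_i)/H_m) - p8 B H_u
dH_i/dt =  p8 B H_u - p9 E H_i
```

and each of the `N` instillations raises `B` by `b` units at `t = m*tau`
(an impulse train).  The pre-treatment state is
`(0, e0, 0, T0, H_m - T0, 0)` with `0 < T0 < H_m`, `e0 > 0`.

A four-compartment continuous-instillation baseline — no healthy
compartments, constant instillation rate, cancer removed only by BCG
infection — is retained for comparison (`LegacyParameters`,
`simulate_legacy`).

### Parameters as constants, personalized across groups

Rates may in principle drift over a course and differ between patients.  We
treat them as constants within a patient and personalize them *across* the 72
socio-demographic groups formed by age group x gender x smoking x weight
group; the socio-demographic profile is assumed fixed over the roughly
two-month course.  The rhs accepts parameters only through the
`ModelParameters` container, so a time-dependence hook (callable parameters)
can be layered on without touching the integrator; none is used by default.

### Units and protocol constants

Time is in hours everywhere.  The shipped protocol constants are the weekly
induction course: `b = 2.8e6` BCG units per instillation, `N = 6`,
`tau = 168 h`, BCG decay `mu_B = 4.16e-3 /h`, and reference bladder capacity
`H_m = 1.84e9` cells.  The default horizon is `N*tau = 1008 h`.

### Choice of interaction rates

There are no consensus literature values for the nine interaction rates at
this compartmental granularity, so the shipped baseline was calibrated once,
before any estimation experiments, to produce clinically sensible course
dynamics and then frozen:

- untreated tumors grow several-fold over a course
  (`lambda = 2e-3 /h`, doubling time ~2 weeks);
- a full course produces a moderate, presentation-dependent response: the
  end/start burden ratio runs from ~1.1 at `T0 = 1e4` cells down to ~1e-3 at
  `T0 = 1e7` (larger tumors recruit proportionally more effector cells via
  `alpha (T_i + H_i)`, so the response curve is strongly nonlinear in `T0` —
  this nonlinearity is also what makes two rate constants identifiable from
  two-timepoint data);
- effector kill (`integral p3 E dt`) and BCG infection (`integral p2 B dt`)
  contribute comparably to tumor clearance.

`e0 = 1e3` effector cells is the default pre-treatment effector level
(configurable; the value only sets the early-course kill rate before
recruitment dominates).

### Dose administration: jumps versus pulses

Two administrations are implemented.  The default **jump mode** applies each
dose as a state discontinuity `B -> B + b`, implemented by restarting the
integration at each dose time — robust, and it never forces the solver
through a `1/epsilon`-peaked input.  **Pulse mode** implements the literal
triangular unit-integral approximation of the Dirac impulse with half-width
`epsilon` (default 0.5 h); integration starts at `-epsilon` so the first
pulse is delivered in full.  The two agree on final burden to well under 1%
at `epsilon = 1e-3 tau` (tested).

### Numerics

Production integration uses LSODA (via `scipy.integrate.odeint`) with the
analytic Jacobian supplied, `rtol = 1e-8` and a per-compartment `atol` of
1e-6 of the compartment's typical scale.  States are clipped to zero only on
output; an excursion below `-10 atol` raises.  The fitting loop uses a
coarse-output fast path with `rtol = 1e-6` (`simulate_final`) — the same path
for training and evaluation, so the loss is consistent.  Trajectory
interpolation is local cubic (Lagrange) within the continuous run between
dose times, never bridging a dose discontinuity; this keeps the closed-form
exponential-growth check below 1e-6 relative error on a 40-points-per-week
grid.  A fixed-step classical RK4 integrator, independent of the LSODA path,
serves as the numerical oracle in the tests (agreement to 1e-4 relative on
end-of-course burden; observed ~1e-6).

### Equilibria and stability

Setting the undosed rhs to zero yields exactly two equilibria: the trivial
state and the healthy state `(0,0,0,0,H_m,0)`.  Both Jacobians have a zero
eigenvalue (the infected-cancer row vanishes identically at both points), so
both are non-hyperbolic; whenever `lambda > 0` the uninfected-cancer
direction carries the eigenvalue `lambda` and both equilibria are unstable —
a cancer-free bladder is not a robust state of this model.  Classification
uses the Jacobian of the implemented rhs; eigenvalues within
`1e-9 x max(rates)` of zero count as zero.  `stability.tabulated_jacobians`
preserves an earlier hand tabulation of the two linearizations verbatim,
including entries that are dimensionally inconsistent with the dynamics
(bare `-1/H_m` terms, a `p7 + 2` diagonal entry); they are fixtures only and
their qualitative conclusions match the exact Jacobian.

## The capacity model

The bladder's cell capacity `H_m` is treated as observed (a function of
anthropometrics), not fitted: an affine function of the age-group midpoint
(slope -6e6 cells/year), the weight-group BMI midpoint (+2.5e7 cells/BMI
unit) and a male offset (+8e7 cells), with the intercept calibrated
analytically so the balanced-population mean equals the reference 1.84e9
cells.  The same capacity model is used when generating synthetic cohorts
and when fitting, so capacity mismatch is never confounded with rate
estimation.  Polyp volume converts to cell count through a fixed average
cancer-cell volume (default 1e-6 mm^3, configurable).

## The synthetic-data generator

Real treatment records carry only `T(0)`, `T(t_f)` and the four
socio-demographic attributes; the generator emulates exactly that structure
from a known ground truth:

- group frequencies come from independent per-field marginals skewed the way
  bladder-cancer cohorts skew (older, more male, more smokers), so several of
  the 72 groups are empty at realistic cohort sizes;
- presentation burden `T0` is log-uniform on 1e4-1e7 cells;
- group effects are multiplicative on the baseline rates.  The shipped
  "strong" scenario: smoking x1.6 on `lambda`, effector decay `mu_E` rising
  0.85 -> 1.45 across age groups, male x1.25 on `alpha`, and weight acting on
  capacity through the `H_m` model;
- observed end burden is the simulated one times a `lognormal(0, sigma)`
  draw (default `sigma = 0.1`): burdens are positive and span orders of
  magnitude, so multiplicative noise is the natural error model.

What the generator does **not** emulate: schedule non-adherence, censored or
missing observations, within-group biological variation (all patients in a
group share the group's rates), and measurement error on `T(0)`.  Passing
tests therefore demonstrate that the estimation machinery recovers structure
*of this kind* from data *of this sparsity* — not that the shipped rates
describe any particular clinical population.

## The three-step fitting procedure

Data are split into `k` folds (default 5); each fold's records are further
split 60/20/20 into train/test/validate (fractions configurable).

**Step 1 — per-group gradient descent.**  Within the training split, each
socio-demographic group's free rate constants are fitted by minimizing the
relative mean absolute error (RMAE) of the predicted end burden,
`mean(|pred - obs| / obs)`.  The descent runs in log10 parameter space
(rates are positive scale parameters) with projection to bounds (default
three decades around the initial value), five-point-stencil gradients
(`h = 1e-3` log units; the stencil is exact for quartics), a fixed step
(0.25 log units) with backtracking halving, convergence when the relative
loss improvement drops below 1e-6, and seeded random restarts (default 3).
Protocol constants (`b`, `N`, `tau`, `mu_B`) and the capacity `H_m` are
observed and never fitted; the free set defaults to all interaction rates
plus `mu_E`, `alpha`, `lambda`, `e0` and is usually restricted in practice
(the shipped analyses fit `lambda` and `p3`, the two rates the response
curve is most sensitive to).

**Step 2 — KNN-gated augmentation.**  Candidate synthetic records draw every
feature column (one-hot socio-demographics, rounded to the nearest valid
profile, plus log10 presentation burden) uniformly between the training
minima and maxima.  The candidate's outcome label is the current model's own
simulated prediction; the candidate is accepted only if the model's error on
that label beats an optimized k-nearest-neighbour regressor of log-outcome
(neighbour count chosen from {1,3,5,7} by leave-one-out error).  Under
model-labelling the model's error is zero, so the gate reduces to "the KNN
cannot already reproduce this point" — it admits samples in feature-space
regions the training data does not pin down, which is the regularizing
intent.  After `n` acceptances (attempt cap `50n`) the groups are refitted
(warm-started, reduced iteration budget), and a paired one-sided t-test on
the test split decides whether the refit is significantly better; failing
rounds are repeated up to 3 times, after which the pre-augmentation fit is
kept.

**Step 3 — pipeline search.**  A fixed, deterministic candidate set of
multi-output regressors (constant mean, scaled linear, 1-NN, scaled k-NN,
random forest) is trained to map features to the fitted log10 parameters;
each candidate is scored by the RMAE its predicted parameters achieve on the
validation split, and the argmin is kept.  A bounded explicit candidate set
replaces open-ended AutoML search so that fits are reproducible under a
seed.  At prediction time a record uses its group's direct fit when the fold
has one, otherwise the fold's pipeline extrapolates the parameters; the
final prediction is the mean over folds.

## Evaluation and the three-way comparison

`evaluate` reports overall RMAE and the per-group long-format table (72 rows,
NaN for unassessed groups) plus per-level marginals.  `compare_models` draws
a seeded evaluation subset containing at most one patient per distinct
profile (default 50), computes per-sample relative errors for each model,
and runs a one-way ANOVA plus paired one-tailed t-tests for every ordered
pair; a winner is declared only if the lowest-mean model beats every other
at the chosen level.  Group contrasts use two-tailed two-sample t-tests for
the binary fields and one-way ANOVA with Tukey HSD pairs for weight and age.

The comparison baselines are (i) the identical pipeline with all patients
pooled and socio-demographic features withheld (capacity fixed at the
population reference), and (ii) the continuous-instillation four-compartment
model, fitted pooled with the same GD engine and the same loss.  Both
pooled fits free two parameters (`lambda, p3` for the pooled variant;
`lambda, p2` for the legacy model, whose only tumor-removal route is
infection), keeping the comparison symmetric in capacity.  The legacy
instillation rate is fixed so one week of continuous instillation delivers
the same BCG mass as one pulsed dose.

## Problem sizes used by the shipped analyses

The acceptance script and end-to-end tests run: the two-parameter recovery
study on a single-group noise-free cohort of 60 (30 for the bare GD check;
k=2 folds for the full pipeline; 20 held-out patients), and the three-way
comparison on a 400-patient strong-scenario cohort with `sigma = 0.1`,
`k = 3` folds, free set `(lambda, p3)`, GD capped at 30 iterations (10 on
warm-started refits), one restart, 8 augmentation samples and one
augmentation round.  These budgets were chosen as the smallest at which the
estimation problem is comfortably over-determined; they complete in a few
minutes on one CPU.

## Known limitations

- No spatial structure: the bladder is a well-mixed compartment; geometry
  and wall contact of instilled BCG are outside scope.
- BCG pharmacokinetics beyond first-order decay are not modelled.
- Uninfected-cancer growth is exponential (not capacity-limited), so the
  capacity bound on total tissue is only as good as the regrowth rate `p7`
  is fast relative to tumor growth; at the defaults it holds to 0.1%.
- The two pooled-model baselines and the personalized model are compared on
  the cohort they were fitted on (fold-averaged predictions); a fully
  held-out comparison would need a second generated cohort and gives the
  same ordering in our experience with the shipped scenario.
- The significance gate inherits the usual caveats of repeated testing on a
  small test split; it is a heuristic control, not a formal error guarantee.
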