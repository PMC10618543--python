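# bcgtx

Personalized modelling of intravesical BCG (Bacillus Calmette-Guérin)
immunotherapy for non-invasive bladder cancer.

BCG induction therapy — weekly bladder instillations of an attenuated
bacterium — is the standard of care for superficial bladder cancer, yet its
outcome varies widely between patients and the protocol is one-size-fits-all.
`bcgtx` couples a mechanistic tumor-immune model of the treated bladder to
cheap, routinely available socio-demographics (age group, gender, smoking,
weight group), so that end-of-treatment tumor burden can be predicted per
patient group rather than per population.  The package is aimed at
modellers and methods researchers working on treatment-outcome prediction
from sparse clinical data: every stage — simulation, estimation, evaluation —
is testable end-to-end on generated virtual cohorts with known ground truth.

## The model

Six coupled compartments inside the bladder: intravesical BCG `B`, effector
immune cells `E`, BCG-infected / uninfected cancer cells `T_i`, `T_u`, and
uninfected / BCG-infected healthy urothelium `H_u`, `H_i`:

    dB/dt   = Σ_{m=0}^{N-1} b δ(t − mτ) − p₁EB − p₂BT_u − p₈BH_u − μ_B B
    dE/dt   = −μ_E E + α(T_i + H_i) + p₄EB − p₅ET_i − p₆EH_i
    dT_i/dt = p₂BT_u − p₃T_iE
    dT_u/dt = λT_u − p₂BT_u − p₃T_uE
    dH_u/dt = p₇H_u(1 − (H_u+H_i+T_u+T_i)/H_m) − p₈BH_u
    dH_i/dt = p₈BH_u − p₉EH_i

with impulsive dosing (`N = 6` weekly instillations of `b = 2.8e6` BCG
units, `τ = 168 h`) and start state `(0, e₀, 0, T₀, H_m − T₀, 0)`.  The
system has exactly two equilibria (empty bladder, healthy bladder); both are
non-hyperbolic and, for any positive cancer growth rate λ, unstable.

Only two tumor-burden observations per patient exist (start and end of
treatment), so rate constants are estimated per socio-demographic group —
72 disjoint groups from age × gender × smoking × weight — by a three-step
procedure: per-group gradient descent on the relative mean absolute error
(RMAE) with five-point-stencil gradients, KNN-gated synthetic augmentation
with a paired-test significance gate, and a per-fold pipeline search that
extrapolates parameters to groups without direct fits.  Predictions average
over cross-validation folds.  See `docs/methods.md` for the full account.

## Worked example

Generate a heterogeneous 120-patient virtual cohort (smoking raises λ, age
raises effector decay, gender shifts recruitment, weight shifts capacity;
10% multiplicative measurement noise), fit the personalized model, and
compare it against the pooled (no socio-demographics) variant and the
continuous-instillation four-compartment baseline:

```python
from bcgtx import (FitConfig, PersonalizedBCGModel, PooledBCGModel,
                   LegacyInstillationModel, compare)
from bcgtx.synthetic import strong_scenario, generate_cohort

cohort = generate_cohort(strong_scenario(sigma=0.1), n=120, seed=3)
config = FitConfig(k=3, free=("lambda_", "p3"), gd_max_iter=30,
                   gd_refit_iter=10, restarts=1, n_augment=6,
                   max_aug_rounds=1, seed=0)

res = PersonalizedBCGModel(cohort.records, config).fit()
print(res.summary())

pooled = PooledBCGModel(cohort.records, config).fit()
legacy = LegacyInstillationModel(cohort.records, config).fit()
report = compare({"personalized": res, "no-socio": pooled, "legacy": legacy},
                 cohort.records, n_samples=50, seed=1)
for name in report.means:
    print(f"{name:13s} RMAE {report.means[name]:.3f} +/- {report.sds[name]:.3f}")
print(f"ANOVA p = {report.anova_p:.2e}; winner: {report.winner}")
```

Output:

```
========================================================================
  BCG treatment-outcome model (personalized)
========================================================================
  patients:   120    folds (k): 3    free parameters: lambda_, p3
  overall RMAE: 0.2048
------------------------------------------------------------------------
  per-fold errors:
 fold  train   test  validate      pipeline  n_augmented
    0 0.0163 0.3606    0.3053 scaled-linear            0
    1 0.0153 0.3721    0.3050 scaled-linear            0
    2 0.0194 0.2049    0.2912 scaled-linear            0
------------------------------------------------------------------------
  groups with evaluated patients: 48 of 72
========================================================================
personalized  RMAE 0.275 +/- 0.616
no-socio      RMAE 0.564 +/- 0.511
legacy        RMAE 0.868 +/- 0.154
ANOVA p = 4.80e-08; winner: personalized
```

Reading this: within-fold training error is ~2% (the per-group fits match
their own patients almost exactly); held-out error is dominated by the 10%
measurement noise and by patients whose group fell outside the fold's
training split, where the selected pipeline (here a scaled linear map from
the one-hot socio-demographics to the log-rates) extrapolates.  On a
50-sample evaluation subset with pairwise-distinct profiles, personalization
roughly halves the pooled model's error, and the continuous-instillation
baseline — which cannot represent pulsed dosing, healthy-tissue dynamics, or
immune kill of uninfected cancer cells — trails both.

A command-line interface mirrors the library:
`bcgtx generate`, `bcgtx simulate`, `bcgtx stability`, `bcgtx fit`,
`bcgtx evaluate`, `bcgtx compare` (see `bcgtx --help`).

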