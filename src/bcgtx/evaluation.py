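"""Scoring fitted models and the three-way model comparison.

The evaluation mirrors how such a prediction model is judged clinically:
the relative mean absolute error (RMAE) of the predicted end-of-treatment
tumor burden, overall and broken down by socio-demographic group, plus a
three-way comparison of the personalized model against (i) the same pipeline
with all patients pooled and socio-demographics withheld, and (ii) the
four-compartment continuous-instillation baseline model.  Group-wise error
contrasts use standard two-sample t-tests (smoking, gender) and one-way
ANOVA with Tukey post-hoc pairs (weight, age).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord, enumerate_groups, group_of
from .dynamics import simulate_legacy
from .fitting import FitConfig, FittedModel, fit, gd_fit, predict, rmae
from .params import LegacyParameters, default_legacy_parameters

__all__ = [
    "GroupErrorTable",
    "ComparisonReport",
    "FittedLegacyModel",
    "evaluate",
    "fit_no_socio",
    "fit_legacy",
    "compare_models",
    "group_contrasts",
]

logger = logging.getLogger(__name__)

_CATEGORY_FIELDS = ("age_group", "gender", "smoking", "weight_group")


@dataclass
class GroupErrorTable:
    """Per-group RMAE in long format plus marginal RMAE per category level.

    ``per_group`` has one row per socio-demographic group (72 rows; groups
    with no evaluated patients carry NaN — the analogue of an unassessable
    cell), ``marginals`` one row per category level.
    """

    per_group: pd.DataFrame
    marginals: pd.DataFrame

    def present(self) -> pd.DataFrame:
        return self.per_group.dropna(subset=["rmae"])


@dataclass
class ComparisonReport:
    """Outcome of the multi-model comparison on a common evaluation subset."""

    means: dict[str, float]
    sds: dict[str, float]
    per_sample_errors: dict[str, np.ndarray]
    anova_F: float
    anova_p: float
    pairwise_p: dict[tuple[str, str], float]
    winner: str | None
    n_samples: int
    alpha: float


def _per_record_errors(
    predictor: Callable[[PatientRecord], float], records: Sequence[PatientRecord]
) -> np.ndarray:
    errors = np.empty(len(records))
    for i, rec in enumerate(records):
        pred = predictor(rec)
        errors[i] = abs(pred - rec.T_end) / rec.T_end
    return errors


def evaluate(
    model: FittedModel | Callable[[PatientRecord], float],
    records: Sequence[PatientRecord],
) -> tuple[float, GroupErrorTable]:
    """Overall and per-group RMAE of a fitted model (or bare predictor) on records."""
    records = list(records)
    if not records:
        raise ValueError("no records to evaluate")
    predictor = model if callable(model) else (lambda rec: predict(model, rec))
    errors = _per_record_errors(predictor, records)
    overall = float(np.mean(errors))

    group_errors: dict[int, list[float]] = {}
    for rec, err in zip(records, errors):
        group_errors.setdefault(group_of(rec.profile).index, []).append(err)
    rows = []
    for key in enumerate_groups():
        errs = group_errors.get(key.index)
        rows.append({
            "group_index": key.index,
            "age_group": key.age_group,
            "gender": key.gender,
            "smoking": key.smoking,
            "weight_group": key.weight_group,
            "n": 0 if errs is None else len(errs),
            "rmae": np.nan if errs is None else float(np.mean(errs)),
        })
    per_group = pd.DataFrame(rows)

    marg_rows = []
    for fld in _CATEGORY_FIELDS:
        levels: dict[str, list[float]] = {}
        for rec, err in zip(records, errors):
            levels.setdefault(getattr(rec.profile, fld), []).append(err)
        for level, errs in levels.items():
            marg_rows.append({
                "field": fld, "level": level, "n": len(errs), "rmae": float(np.mean(errs)),
            })
    marginals = pd.DataFrame(marg_rows)
    return overall, GroupErrorTable(per_group=per_group, marginals=marginals)


def fit_no_socio(cohort: Sequence[PatientRecord], config: FitConfig) -> FittedModel:
    """The non-personalized variant: one pooled group, socio-features withheld."""
    return fit(cohort, config, pooled=True)


@dataclass
class FittedLegacyModel:
    """GD-fitted four-compartment continuous-instillation baseline."""

    params: LegacyParameters
    config: FitConfig
    e0: float
    loss_trace: list[float] = field(default_factory=list)

    def predict(self, record: PatientRecord) -> float:
        """End burden from the legacy model: integrate (B, E, T_i, T_u) to t_f."""
        init = (0.0, self.e0, 0.0, float(record.T_start))
        traj = simulate_legacy(self.params, init, record.t_f, rtol=self.config.sim_rtol, n_points=2)
        return float(traj.final_state[2] + traj.final_state[3])


#: legacy parameters exposed to the GD loss (same count as the main model's
#: comparison runs keep the fit symmetric)
LEGACY_DEFAULT_FREE = ("lambda_", "p2")


def fit_legacy(
    cohort: Sequence[PatientRecord],
    config: FitConfig,
    free: tuple[str, ...] = LEGACY_DEFAULT_FREE,
    init: LegacyParameters | None = None,
) -> FittedLegacyModel:
    """Fit the continuous-instillation baseline to the pooled cohort with the same loss.

    The legacy model is a single pooled fit (it has no personalization
    machinery): gradient descent on the RMAE of its predicted end burden, in
    log10 space with the same stencil/backtracking scheme.  The instillation
    rate ``b`` is fixed so one week of continuous instillation delivers the
    same BCG mass as one pulsed dose.
    """
    records = list(cohort)
    if not records:
        raise ValueError("empty cohort")
    init = init if init is not None else default_legacy_parameters()
    e0 = (config.init.e0 if config.init is not None else 1.0e3)

    # reuse the gradient-descent engine through a parameter adapter
    name_map = {"lambda_": "lambda_", "p2": "p2", "p3": "p3", "alpha": "alpha", "mu_E": "mu2"}
    for nm in free:
        if nm not in name_map:
            raise ValueError(f"legacy free parameter {nm!r} not supported")

    class _LegacyAdapter:
        """Duck-types the few ModelParameters attributes gd_fit touches."""

        def __init__(self, legacy: LegacyParameters):
            self._legacy = legacy

        def __getattr__(self, item):
            return getattr(self._legacy, name_map.get(item, item))

        def replace(self, **changes):
            mapped = {name_map.get(k, k): v for k, v in changes.items() if k != "T0"}
            return _LegacyAdapter(self._legacy.replace(**mapped))

        @property
        def legacy(self):
            return self._legacy

    lconfig = replace(config, free=free)

    def legacy_outcome(adapter, record, rtol=1e-6):
        model = FittedLegacyModel(params=adapter.legacy, config=config, e0=e0)
        return model.predict(record)

    fitted, trace = gd_fit(records, _LegacyAdapter(init), lconfig, outcome_fn=legacy_outcome)
    return FittedLegacyModel(params=fitted.legacy, config=config, e0=e0, loss_trace=trace)


def compare_models(
    models: dict[str, Callable[[PatientRecord], float]],
    records: Sequence[PatientRecord],
    n_samples: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> ComparisonReport:
    """Compare models on a seeded evaluation subset of profile-distinct patients.

    The subset holds at most one patient per socio-demographic profile
    (``n_samples`` of them, default 50); with fewer distinct profiles all are
    used with a warning.  Per-sample relative errors feed a one-way ANOVA
    across models and paired one-tailed t-tests for every ordered pair; the
    winner is the lowest-mean model if it beats every other model at ``alpha``.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    records = list(records)
    rng = np.random.default_rng(seed)

    by_profile: dict[tuple, list[PatientRecord]] = {}
    for rec in records:
        by_profile.setdefault(rec.profile.as_tuple(), []).append(rec)
    profiles = sorted(by_profile)
    if len(profiles) < n_samples:
        warnings.warn(
            f"only {len(profiles)} distinct profiles available; using all", stacklevel=2
        )
        chosen = profiles
    else:
        chosen = [profiles[i] for i in rng.choice(len(profiles), size=n_samples, replace=False)]
    subset = [by_profile[p][rng.integers(len(by_profile[p]))] for p in chosen]

    errors = {name: _per_record_errors(fn, subset) for name, fn in models.items()}
    names = list(errors)
    F, p_anova = stats.f_oneway(*(errors[nm] for nm in names))
    pairwise: dict[tuple[str, str], float] = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            res = stats.ttest_rel(errors[a], errors[b], alternative="less")
            pairwise[(a, b)] = float(res.pvalue)
    means = {nm: float(np.mean(errors[nm])) for nm in names}
    sds = {nm: float(np.std(errors[nm], ddof=1)) for nm in names}
    best = min(means, key=means.get)
    wins = all(pairwise[(best, other)] < alpha for other in names if other != best)
    return ComparisonReport(
        means=means, sds=sds, per_sample_errors=errors,
        anova_F=float(F), anova_p=float(p_anova),
        pairwise_p=pairwise, winner=best if wins else None,
        n_samples=len(subset), alpha=alpha,
    )


def group_contrasts(
    errors: Sequence[float],
    profiles: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Socio-demographic contrasts of per-patient errors.

    Smoking and gender: two-tailed two-sample t-test between the two levels.
    Weight and age: one-way ANOVA followed by Tukey honest-significant-
    difference pairwise tests.  Levels with fewer than two patients are
    excluded with a warning.  Returns a long table of (field, contrast,
    statistic, p_value, significant).
    """
    errors = np.asarray(errors, dtype=float)
    if len(errors) != len(profiles):
        raise ValueError("errors and profiles must align")
    rows = []
    for fld in _CATEGORY_FIELDS:
        by_level: dict[str, np.ndarray] = {}
        for err, prof in zip(errors, profiles):
            by_level.setdefault(getattr(prof, fld), []).append(err)
        usable = {}
        for level, vals in by_level.items():
            if len(vals) < 2:
                warnings.warn(
                    f"level {level!r} of {fld} has fewer than two patients; excluded",
                    stacklevel=2,
                )
                continue
            usable[level] = np.asarray(vals)
        if len(usable) < 2:
            continue
        levels = sorted(usable)
        if fld in ("smoking", "gender"):
            a, b = usable[levels[0]], usable[levels[1]]
            res = stats.ttest_ind(a, b)
            rows.append({
                "field": fld, "contrast": f"{levels[0]} vs {levels[1]}",
                "test": "t", "statistic": float(res.statistic),
                "p_value": float(res.pvalue), "significant": res.pvalue < alpha,
            })
        else:
            groups = [usable[lv] for lv in levels]
            F, p = stats.f_oneway(*groups)
            rows.append({
                "field": fld, "contrast": "all levels", "test": "anova",
                "statistic": float(F), "p_value": float(p), "significant": p < alpha,
            })
            tukey = stats.tukey_hsd(*groups)
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    rows.append({
                        "field": fld, "contrast": f"{levels[i]} vs {levels[j]}",
                        "test": "tukey", "statistic": float(tukey.statistic[i, j]),
                        "p_value": float(tukey.pvalue[i, j]),
                        "significant": tukey.pvalue[i, j] < alpha,
                    })
    return pd.DataFrame(rows, columns=["field", "contrast", "test", "statistic", "p_value", "significant"])
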