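"""Model/Results interface over the fitting and evaluation machinery.

Mirrors the statsmodels idiom: a model object is constructed from data (a
list of :class:`~bcgtx.cohort.PatientRecord`, a DataFrame in the cohort
schema, or a CSV file), ``fit()`` runs the estimation and returns a results
object carrying the per-fold estimates, error diagnostics and a ``summary()``
table, and prediction/plotting hang off the results.

    >>> model = PersonalizedBCGModel.from_csv("cohort.csv")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict(new_records)
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, fitting
from .cohort import PatientRecord, read_cohort
from .fitting import FitConfig, FittedModel
from .params import DoseSchedule

__all__ = [
    "PersonalizedBCGModel",
    "PooledBCGModel",
    "LegacyInstillationModel",
    "BCGResults",
    "LegacyResults",
    "compare",
]


def _frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    from .cohort import PatientProfile

    records = []
    for idx, row in df.iterrows():
        profile = PatientProfile(
            age_group=str(row["age_group"]), gender=str(row["gender"]),
            smoking=str(row["smoking"]), weight_group=str(row["weight_group"]),
        )
        schedule = DoseSchedule(b=float(row["b"]), N=int(row["N"]), tau=float(row["tau"]))
        records.append(PatientRecord(
            profile=profile,
            T_start=float(row["T_start_cells"]),
            T_end=float(row["T_end_cells"]) if not pd.isna(row["T_end_cells"]) else None,
            schedule=schedule,
            t_f=float(row["t_f_hours"]),
            patient_id=str(row.get("patient_id", idx)),
        ))
    return records


class PersonalizedBCGModel:
    """Socio-demographically personalized end-of-treatment burden model.

    Parameters
    ----------
    records : list of PatientRecord
        Two-timepoint clinical records (observed ``T_end`` required to fit).
    config : FitConfig, optional
        Hyper-parameters of the three-step fitting procedure.
    """

    _pooled = False
    _name = "personalized"

    def __init__(self, records: Sequence[PatientRecord], config: FitConfig | None = None):
        self.records = list(records)
        self.config = config if config is not None else FitConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: FitConfig | None = None):
        return cls(_frame_to_records(df), config)

    @classmethod
    def from_csv(cls, path: str, config: FitConfig | None = None):
        return cls(read_cohort(path), config)

    def fit(self, seed: int | None = None) -> "BCGResults":
        """Run the three-step procedure; returns a results object."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        fitted = fitting.fit(self.records, config, pooled=self._pooled)
        return BCGResults(model=self, fitted=fitted)


class PooledBCGModel(PersonalizedBCGModel):
    """The same pipeline with all patients pooled and socio-demographics withheld."""

    _pooled = True
    _name = "no-socio"


class BCGResults:
    """Fit results: fold-averaged predictions, RMAE diagnostics, summary table."""

    def __init__(self, model: PersonalizedBCGModel, fitted: FittedModel):
        self.model = model
        self.fitted = fitted
        self.rmae_, self.group_errors_ = evaluation.evaluate(fitted, model.records)

    # -- prediction ---------------------------------------------------------
    def predict_one(self, record: PatientRecord) -> float:
        return fitting.predict(self.fitted, record)

    def predict(self, records: Sequence[PatientRecord] | None = None) -> np.ndarray:
        records = self.model.records if records is None else records
        return np.array([self.predict_one(r) for r in records])

    def rmae(self, records: Sequence[PatientRecord] | None = None) -> float:
        if records is None:
            return self.rmae_
        overall, _ = evaluation.evaluate(self.fitted, records)
        return overall

    # -- diagnostics --------------------------------------------------------
    @property
    def fold_rmae(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": range(len(self.fitted.folds)),
            "train": [f.rmae_train for f in self.fitted.folds],
            "test": [f.rmae_test for f in self.fitted.folds],
            "validate": [f.rmae_val for f in self.fitted.folds],
            "pipeline": [f.pipeline_name for f in self.fitted.folds],
            "n_augmented": [f.n_augmented for f in self.fitted.folds],
        })

    def params_frame(self) -> pd.DataFrame:
        """Fold-averaged fitted free parameters per socio-demographic group."""
        free = self.fitted.config.free
        acc: dict[int | None, list[np.ndarray]] = {}
        for fold in self.fitted.folds:
            for gkey, params in fold.params_by_group.items():
                acc.setdefault(gkey, []).append(
                    np.array([getattr(params, nm) for nm in free])
                )
        rows = []
        for gkey in sorted(acc, key=lambda g: (g is None, g)):
            mean = np.mean(acc[gkey], axis=0)
            row = {"group_index": -1 if gkey is None else gkey, "n_folds": len(acc[gkey])}
            row.update({nm: mean[i] for i, nm in enumerate(free)})
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.fitted.config
        lines = [
            "=" * 72,
            f"  BCG treatment-outcome model ({self.model._name})",
            "=" * 72,
            f"  patients: {len(self.model.records):>5d}    folds (k): {cfg.k}"
            f"    free parameters: {', '.join(cfg.free)}",
            f"  overall RMAE: {self.rmae_:.4f}",
            "-" * 72,
            "  per-fold errors:",
        ]
        lines.append(self.fold_rmae.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        present = self.group_errors_.present()
        if len(present) and not self.fitted.pooled:
            lines += ["-" * 72, f"  groups with evaluated patients: {len(present)} of 72"]
        lines.append("=" * 72)
        return "\n".join(lines)

    def plot_group_errors(self, ax=None):
        """Heatmap of per-group RMAE (smoking x weight columns, age x gender rows)."""
        import matplotlib.pyplot as plt

        df = self.group_errors_.per_group
        pivot = df.pivot_table(
            index=["age_group", "gender"], columns=["smoking", "weight_group"],
            values="rmae", dropna=False,
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(pivot.shape[1]), ["/".join(c) for c in pivot.columns], rotation=90)
        ax.set_yticks(range(pivot.shape[0]), ["/".join(r) for r in pivot.index])
        ax.figure.colorbar(im, ax=ax, label="RMAE")
        ax.set_title("per-group relative mean absolute error")
        return ax


class LegacyInstillationModel:
    """The four-compartment continuous-instillation baseline, pooled GD fit."""

    _name = "legacy"

    def __init__(self, records: Sequence[PatientRecord], config: FitConfig | None = None):
        self.records = list(records)
        self.config = config if config is not None else FitConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: FitConfig | None = None):
        return cls(_frame_to_records(df), config)

    @classmethod
    def from_csv(cls, path: str, config: FitConfig | None = None):
        return cls(read_cohort(path), config)

    def fit(self, seed: int | None = None) -> "LegacyResults":
        config = self.config if seed is None else replace(self.config, seed=seed)
        fitted = evaluation.fit_legacy(self.records, config)
        return LegacyResults(model=self, fitted=fitted)


class LegacyResults:
    """Results wrapper for the continuous-instillation baseline."""

    def __init__(self, model: LegacyInstillationModel, fitted: evaluation.FittedLegacyModel):
        self.model = model
        self.fitted = fitted
        self.rmae_, self.group_errors_ = evaluation.evaluate(fitted.predict, model.records)

    def predict_one(self, record: PatientRecord) -> float:
        return self.fitted.predict(record)

    def predict(self, records: Sequence[PatientRecord] | None = None) -> np.ndarray:
        records = self.model.records if records is None else records
        return np.array([self.predict_one(r) for r in records])

    def rmae(self, records: Sequence[PatientRecord] | None = None) -> float:
        if records is None:
            return self.rmae_
        overall, _ = evaluation.evaluate(self.fitted.predict, records)
        return overall

    def summary(self) -> str:
        p = self.fitted.params
        lines = [
            "=" * 72,
            "  Continuous-instillation baseline (four compartments)",
            "=" * 72,
            f"  patients: {len(self.model.records):>5d}    overall RMAE: {self.rmae_:.4f}",
            f"  fitted parameters: " + ", ".join(
                f"{nm}={getattr(p, nm):.3e}" for nm in ("lambda_", "p2")
            ),
            "=" * 72,
        ]
        return "\n".join(lines)


def compare(
    results: dict[str, "BCGResults | LegacyResults"],
    records: Sequence[PatientRecord],
    n_samples: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> evaluation.ComparisonReport:
    """Three-way (or n-way) comparison of fitted results on profile-distinct samples."""
    predictors = {name: res.predict_one for name, res in results.items()}
    return evaluation.compare_models(predictors, records, n_samples=n_samples, alpha=alpha, seed=seed)
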