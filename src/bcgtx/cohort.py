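"""Patient socio-demographics, the 72-group partition, and cohort I/O.

Patients are described by four categorical attributes — age group, gender,
smoking status and weight group — whose Cartesian product yields 72 pairwise
disjoint socio-demographic groups (6 x 2 x 2 x 3).  Each group carries its own
model parameterization; the attributes are assumed constant over a treatment
course.  The clinical observation per patient is minimal: tumor burden at the
start and end of treatment plus the instillation protocol.

Tumor burdens are stored as cell counts; polyp volumes (mm^3) convert to cells
through a fixed average cancer-cell volume.  The bladder's cell capacity
``H_m`` is personalized through a shipped affine calibration in the age- and
weight-group midpoints with a gender offset, calibrated so that the mean over
a balanced population equals the reference capacity 1.84e9 cells.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import DoseSchedule

__all__ = [
    "AGE_GROUPS",
    "GENDERS",
    "SMOKING",
    "WEIGHT_GROUPS",
    "PatientProfile",
    "PatientRecord",
    "GroupKey",
    "HmCoefficients",
    "enumerate_groups",
    "group_of",
    "encode_features",
    "feature_names",
    "estimate_Hm",
    "volume_to_cells",
    "cells_to_volume",
    "read_cohort",
    "write_cohort",
    "records_to_frame",
    "DEFAULT_CELL_VOLUME_MM3",
]

logger = logging.getLogger(__name__)

AGE_GROUPS = ("19-25", "26-35", "36-45", "46-55", "56-65", "66+")
GENDERS = ("female", "male")
SMOKING = ("non-smoker", "smoker")
# ordered by body-mass, not alphabetically, so group order follows BMI
WEIGHT_GROUPS = ("underweight", "normal", "overweight")

#: representative ages (years) and BMI values used by the capacity model
AGE_MIDPOINTS = {"19-25": 22.0, "26-35": 30.5, "36-45": 40.5, "46-55": 50.5, "56-65": 60.5, "66+": 70.0}
WEIGHT_MIDPOINTS = {"underweight": 17.0, "normal": 22.0, "overweight": 27.5}

#: average bladder-cancer cell volume used for polyp-volume conversion (mm^3)
DEFAULT_CELL_VOLUME_MM3 = 1e-6

_REFERENCE_HM = 1.84e9


@dataclass(frozen=True)
class PatientProfile:
    """The socio-demographic tuple (age group, gender, smoking, weight group)."""

    age_group: str
    gender: str
    smoking: str
    weight_group: str

    def __post_init__(self) -> None:
        _validate_level("age_group", self.age_group, AGE_GROUPS)
        _validate_level("gender", self.gender, GENDERS)
        _validate_level("smoking", self.smoking, SMOKING)
        _validate_level("weight_group", self.weight_group, WEIGHT_GROUPS)

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.age_group, self.gender, self.smoking, self.weight_group)


def _validate_level(name: str, value: str, vocab: tuple[str, ...]) -> None:
    if value not in vocab:
        raise ValueError(f"unknown {name} {value!r}; expected one of {vocab}")


@dataclass(frozen=True)
class GroupKey:
    """One of the 72 socio-demographic groups: an index plus the four labels."""

    index: int
    age_group: str
    gender: str
    smoking: str
    weight_group: str

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.age_group, self.gender, self.smoking, self.weight_group)

    def profile(self) -> PatientProfile:
        return PatientProfile(*self.labels)


@dataclass
class PatientRecord:
    """One patient: profile, two-timepoint burdens, and the treatment protocol.

    ``T_start`` and ``T_end`` are tumor-cell counts at treatment start and end
    (``T_end`` may be None for a yet-unobserved patient); ``t_f`` is the
    observation time in hours, by default the schedule duration ``N * tau``.
    """

    profile: PatientProfile
    T_start: float
    T_end: float | None
    schedule: DoseSchedule
    t_f: float | None = None
    patient_id: str | None = None
    volume_start_mm3: float | None = None
    volume_end_mm3: float | None = None

    def __post_init__(self) -> None:
        if not self.T_start > 0:
            raise ValueError(f"T_start must be positive, got {self.T_start}")
        if self.t_f is None:
            self.t_f = self.schedule.duration
        if not self.t_f > 0:
            raise ValueError(f"t_f must be positive, got {self.t_f}")


def enumerate_groups() -> list[GroupKey]:
    """All 72 groups in deterministic lexicographic order.

    Field order is (age, gender, smoking, weight); age ascends, gender and
    smoking are alphabetical and weight ascends by body mass, so the first key
    is (19-25, female, non-smoker, underweight) and the last is
    (66+, male, smoker, overweight).
    """
    keys = []
    for i, (a, g, s, w) in enumerate(
        itertools.product(AGE_GROUPS, GENDERS, SMOKING, WEIGHT_GROUPS)
    ):
        keys.append(GroupKey(index=i, age_group=a, gender=g, smoking=s, weight_group=w))
    return keys


def group_of(profile: PatientProfile) -> GroupKey:
    """The unique group whose labels match ``profile`` (index arithmetic, O(1))."""
    ia = AGE_GROUPS.index(profile.age_group)
    ig = GENDERS.index(profile.gender)
    is_ = SMOKING.index(profile.smoking)
    iw = WEIGHT_GROUPS.index(profile.weight_group)
    index = ((ia * len(GENDERS) + ig) * len(SMOKING) + is_) * len(WEIGHT_GROUPS) + iw
    return GroupKey(index=index, **{
        "age_group": profile.age_group, "gender": profile.gender,
        "smoking": profile.smoking, "weight_group": profile.weight_group,
    })


def feature_names() -> list[str]:
    """Column names of the 13-dimensional one-hot encoding."""
    return (
        [f"age_{a}" for a in AGE_GROUPS]
        + [f"gender_{g}" for g in GENDERS]
        + [f"smoking_{s}" for s in SMOKING]
        + [f"weight_{w}" for w in WEIGHT_GROUPS]
    )


def encode_features(profile: PatientProfile) -> np.ndarray:
    """One-hot encoding of the profile over the four vocabularies (length 13)."""
    blocks = []
    for value, vocab in (
        (profile.age_group, AGE_GROUPS),
        (profile.gender, GENDERS),
        (profile.smoking, SMOKING),
        (profile.weight_group, WEIGHT_GROUPS),
    ):
        block = np.zeros(len(vocab))
        block[vocab.index(value)] = 1.0
        blocks.append(block)
    return np.concatenate(blocks)


def decode_features(zeta: np.ndarray) -> PatientProfile:
    """Nearest valid profile for an arbitrary real vector of length 13.

    Each field is taken as the argmax of its one-hot block (ties break toward
    the first level), so any real-valued vector rounds to a valid profile.
    """
    zeta = np.asarray(zeta, dtype=float)
    if zeta.shape != (13,):
        raise ValueError(f"feature vector must have length 13, got {zeta.shape}")
    offsets = [0, 6, 8, 10, 13]
    vocabs = (AGE_GROUPS, GENDERS, SMOKING, WEIGHT_GROUPS)
    levels = []
    for (lo, hi), vocab in zip(itertools.pairwise(offsets), vocabs):
        levels.append(vocab[int(np.argmax(zeta[lo:hi]))])
    return PatientProfile(*levels)


@dataclass(frozen=True)
class HmCoefficients:
    """Affine capacity model: ``H_m = intercept + age_slope*age + weight_slope*bmi + male_offset*[male]``.

    The default intercept is calibrated analytically so that the mean capacity
    over a balanced population (all 72 groups equally frequent) equals the
    reference 1.84e9 cells.
    """

    age_slope: float = -6.0e6      # cells per year of age
    weight_slope: float = 2.5e7    # cells per BMI unit
    male_offset: float = 8.0e7     # cells
    intercept: float | None = None

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        mean_age = float(np.mean(list(AGE_MIDPOINTS.values())))
        mean_bmi = float(np.mean(list(WEIGHT_MIDPOINTS.values())))
        return (
            _REFERENCE_HM
            - self.age_slope * mean_age
            - self.weight_slope * mean_bmi
            - 0.5 * self.male_offset
        )


DEFAULT_HM_COEFFS = HmCoefficients()


def estimate_Hm(profile: PatientProfile, coeffs: HmCoefficients = DEFAULT_HM_COEFFS) -> float:
    """Personalized bladder cell capacity (cells) from age, weight and gender."""
    value = (
        coeffs.resolved_intercept()
        + coeffs.age_slope * AGE_MIDPOINTS[profile.age_group]
        + coeffs.weight_slope * WEIGHT_MIDPOINTS[profile.weight_group]
        + (coeffs.male_offset if profile.gender == "male" else 0.0)
    )
    if not value > 0:
        raise ValueError(f"estimated capacity is non-positive ({value}) for {profile}")
    return float(value)


def volume_to_cells(volume_mm3: float, cell_volume: float = DEFAULT_CELL_VOLUME_MM3) -> int:
    """Convert polyp volume (mm^3) to a cell count, rounding to the nearest cell."""
    if volume_mm3 < 0:
        raise ValueError(f"volume must be non-negative, got {volume_mm3}")
    if not cell_volume > 0:
        raise ValueError(f"cell volume must be positive, got {cell_volume}")
    return int(round(volume_mm3 / cell_volume))


def cells_to_volume(cells: float, cell_volume: float = DEFAULT_CELL_VOLUME_MM3) -> float:
    """Inverse of :func:`volume_to_cells` (exact up to the rounding to whole cells)."""
    if cells < 0:
        raise ValueError(f"cell count must be non-negative, got {cells}")
    if not cell_volume > 0:
        raise ValueError(f"cell volume must be positive, got {cell_volume}")
    return float(cells) * cell_volume


# ---------------------------------------------------------------------------
# cohort CSV I/O

_REQUIRED_COLUMNS = [
    "patient_id", "age_group", "gender", "smoking", "weight_group",
    "T_start_cells", "T_end_cells", "t_f_hours", "b", "N", "tau",
]
_OPTIONAL_COLUMNS = ["volume_start_mm3", "volume_end_mm3"]


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        rows.append({
            "patient_id": r.patient_id if r.patient_id is not None else f"P{i:04d}",
            "age_group": r.profile.age_group,
            "gender": r.profile.gender,
            "smoking": r.profile.smoking,
            "weight_group": r.profile.weight_group,
            "T_start_cells": r.T_start,
            "T_end_cells": r.T_end,
            "t_f_hours": r.t_f,
            "b": r.schedule.b,
            "N": r.schedule.N,
            "tau": r.schedule.tau,
            "volume_start_mm3": r.volume_start_mm3,
            "volume_end_mm3": r.volume_end_mm3,
        })
    return pd.DataFrame(rows, columns=_REQUIRED_COLUMNS + _OPTIONAL_COLUMNS)


def write_cohort(records: list[PatientRecord], path: str) -> None:
    """Write records as the documented one-row-per-patient UTF-8 CSV."""
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path: str) -> list[PatientRecord]:
    """Read a cohort CSV, validating every row; errors name the row and column.

    An empty file yields an empty list with a logged warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("cohort file %s is empty; returning no records", path)
        warnings.warn(f"cohort file {path} is empty", stacklevel=2)
        return []
    if df.empty:
        logger.warning("cohort file %s has a header but no rows", path)
        warnings.warn(f"cohort file {path} has no rows", stacklevel=2)
        return []
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            profile = PatientProfile(
                age_group=str(row["age_group"]),
                gender=str(row["gender"]),
                smoking=str(row["smoking"]),
                weight_group=str(row["weight_group"]),
            )
            schedule = DoseSchedule(b=float(row["b"]), N=int(row["N"]), tau=float(row["tau"]))
            t_end = row["T_end_cells"]
            record = PatientRecord(
                profile=profile,
                T_start=float(row["T_start_cells"]),
                T_end=None if pd.isna(t_end) else float(t_end),
                schedule=schedule,
                t_f=float(row["t_f_hours"]),
                patient_id=str(row["patient_id"]),
                volume_start_mm3=_opt_float(row.get("volume_start_mm3")),
                volume_end_mm3=_opt_float(row.get("volume_end_mm3")),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"cohort file {path}, row {idx}: {exc}") from exc
        records.append(record)
    return records


def _opt_float(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    return float(value)
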