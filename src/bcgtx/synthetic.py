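"""Virtual-patient cohort generation with known ground truth.

Real BCG-treatment records carry only two tumor-burden observations per
patient (treatment start and end), four socio-demographic attributes, and the
instillation protocol.  This module generates cohorts with exactly that
structure, but from a *known* ground truth, so that every stage of the fitting
and evaluation pipeline can be validated: group membership perturbs the rate
constants multiplicatively, presentation burden is drawn log-uniformly, and
the observed end-of-treatment burden is the simulated one corrupted by
multiplicative lognormal measurement noise.

What the generator emulates and what it does not is discussed in
docs/methods.md; in brief it reproduces unbalanced group frequencies, sparse
two-timepoint sampling, and positive multiplicative noise, but not schedule
non-adherence, measurement censoring, or within-group biological variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    AGE_GROUPS,
    GENDERS,
    SMOKING,
    WEIGHT_GROUPS,
    PatientProfile,
    PatientRecord,
    enumerate_groups,
    estimate_Hm,
)
from .dynamics import simulate_final
from .params import DoseSchedule, ModelParameters, default_parameters, default_schedule

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "sample_profiles",
    "personalize_params",
    "generate_cohort",
    "strong_scenario",
    "homogeneous_scenario",
    "marginal_weights",
]

_FIELDS = ("age_group", "gender", "smoking", "weight_group")
_VOCABS = {"age_group": AGE_GROUPS, "gender": GENDERS, "smoking": SMOKING, "weight_group": WEIGHT_GROUPS}


@dataclass(frozen=True)
class GroundTruth:
    """Hidden data-generating process for a synthetic cohort.

    ``effects`` maps socio-demographic field -> level -> parameter-name ->
    multiplier; multipliers are applied to the baseline rates for every level
    the patient belongs to.  ``sigma`` is the lognormal measurement noise on
    observed end burdens (0 = noise free).  ``weights`` are the 72 group
    frequencies (sum to 1).  ``T_start_range`` bounds the log-uniform draw of
    presentation burden.  ``personalize_capacity`` routes ``H_m`` through the
    affine capacity model (age/weight/gender), which is also what the fitting
    side uses, so capacity is treated as observed rather than fitted.
    """

    baseline: ModelParameters = field(default_factory=default_parameters)
    effects: dict = field(default_factory=dict)
    sigma: float = 0.1
    weights: np.ndarray | None = None
    T_start_range: tuple[float, float] = (1e4, 1e7)
    personalize_capacity: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        lo, hi = self.T_start_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid T_start_range {self.T_start_range}")
        for fld, levels in self.effects.items():
            if fld not in _FIELDS:
                raise ValueError(f"unknown socio-demographic field {fld!r}")
            for level, mults in levels.items():
                if level not in _VOCABS[fld]:
                    raise ValueError(f"unknown level {level!r} for field {fld!r}")
                for pname, m in mults.items():
                    if not m > 0:
                        raise ValueError(f"multiplier {fld}/{level}/{pname} must be > 0, got {m}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (72,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be 72 non-negative values summing to 1")


@dataclass
class SyntheticCohort:
    """Generated records plus the hidden truth used to make them.

    ``true_params`` and ``noise_free_end`` are test-only side channels aligned
    with ``records``: re-simulating record ``i`` under ``true_params[i]``
    reproduces ``noise_free_end[i]`` to solver tolerance.
    """

    records: list[PatientRecord]
    truth: GroundTruth
    true_params: list[ModelParameters]
    noise_free_end: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.records)


def marginal_weights(
    age=None, gender=None, smoking=None, weight=None
) -> np.ndarray:
    """Build a 72-vector of group weights from independent per-field marginals.

    Missing marginals default to uniform.  The shipped non-uniform marginals
    (see :func:`strong_scenario`) emulate a clinically realistic skew: older,
    more male, more smokers.
    """
    margins = {
        "age_group": np.asarray(age if age is not None else np.ones(6) / 6, dtype=float),
        "gender": np.asarray(gender if gender is not None else np.ones(2) / 2, dtype=float),
        "smoking": np.asarray(smoking if smoking is not None else np.ones(2) / 2, dtype=float),
        "weight_group": np.asarray(weight if weight is not None else np.ones(3) / 3, dtype=float),
    }
    for name, m in margins.items():
        if np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise ValueError(f"marginal for {name} must be non-negative and sum to 1")
    weights = np.empty(72)
    for key in enumerate_groups():
        w = 1.0
        for fld in _FIELDS:
            vocab = _VOCABS[fld]
            w *= margins[fld][vocab.index(getattr(key, fld))]
        weights[key.index] = w
    return weights / weights.sum()


def strong_scenario(sigma: float = 0.1) -> GroundTruth:
    """The shipped heterogeneous scenario used by the end-to-end evaluations.

    Smoking raises the cancer growth rate (x1.6); age accelerates effector
    decay (0.85 -> 1.45 across age groups); male gender raises effector
    recruitment (x1.25).  Weight acts on capacity through the affine ``H_m``
    model.  Group frequencies skew older, male and smoker.
    """
    effects = {
        "smoking": {"smoker": {"lambda_": 1.6}},
        "age_group": {
            "19-25": {"mu_E": 0.85},
            "26-35": {"mu_E": 0.95},
            "36-45": {"mu_E": 1.05},
            "46-55": {"mu_E": 1.15},
            "56-65": {"mu_E": 1.30},
            "66+": {"mu_E": 1.45},
        },
        "gender": {"male": {"alpha": 1.25}},
    }
    weights = marginal_weights(
        age=[0.04, 0.08, 0.13, 0.20, 0.30, 0.25],
        gender=[0.35, 0.65],
        smoking=[0.45, 0.55],
        weight=[0.12, 0.53, 0.35],
    )
    return GroundTruth(effects=effects, sigma=sigma, weights=weights)


def homogeneous_scenario(sigma: float = 0.1) -> GroundTruth:
    """A null scenario: every group shares the baseline parameters."""
    return GroundTruth(effects={}, sigma=sigma, weights=None, personalize_capacity=False)


def sample_profiles(n: int, weights: np.ndarray | None, seed) -> list[PatientProfile]:
    """Draw ``n`` profiles from the weighted 72-group categorical distribution."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    keys = enumerate_groups()
    if weights is None:
        weights = np.ones(72) / 72
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (72,) or np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be 72 non-negative values summing to 1")
    idx = rng.choice(72, size=n, p=weights / weights.sum())
    return [keys[i].profile() for i in idx]


def personalize_params(truth: GroundTruth, profile: PatientProfile) -> ModelParameters:
    """Ground-truth parameters for one profile: baseline times its level multipliers."""
    changes: dict[str, float] = {}
    for fld in _FIELDS:
        level = getattr(profile, fld)
        mults = truth.effects.get(fld, {}).get(level, {})
        for pname, m in mults.items():
            current = changes.get(pname, getattr(truth.baseline, pname))
            changes[pname] = current * m
    if truth.personalize_capacity:
        changes["H_m"] = estimate_Hm(profile)
    return truth.baseline.replace(**changes) if changes else truth.baseline


def generate_cohort(
    truth: GroundTruth,
    n: int,
    seed,
    schedule: DoseSchedule | None = None,
) -> SyntheticCohort:
    """Generate ``n`` two-timepoint records from the ground truth.

    For each sampled profile the presentation burden is drawn log-uniformly
    from ``truth.T_start_range``, the personalized model is integrated over a
    full course, and the observed end burden is the simulated one times a
    ``lognormal(0, sigma)`` draw.  Fully reproducible given ``seed``.
    """
    schedule = schedule if schedule is not None else default_schedule()
    rng = np.random.default_rng(seed)
    profiles = sample_profiles(n, truth.weights, rng)
    lo, hi = truth.T_start_range
    T_starts = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    noise = np.exp(rng.normal(0.0, truth.sigma, size=n)) if truth.sigma > 0 else np.ones(n)

    records: list[PatientRecord] = []
    true_params: list[ModelParameters] = []
    noise_free = np.empty(n)
    for i, (profile, T0) in enumerate(zip(profiles, T_starts)):
        params = personalize_params(truth, profile).replace(T0=float(T0))
        try:
            y_end = simulate_final(params, schedule)
        except Exception as exc:  # pragma: no cover - solver failures are rare
            raise RuntimeError(f"simulation failed for synthetic patient {i}: {exc}") from exc
        burden = float(y_end[2] + y_end[3])
        noise_free[i] = burden
        records.append(
            PatientRecord(
                profile=profile,
                T_start=float(T0),
                T_end=burden * float(noise[i]),
                schedule=schedule,
                t_f=schedule.duration,
                patient_id=f"S{i:04d}",
            )
        )
        true_params.append(params)
    return SyntheticCohort(
        records=records, truth=truth, true_params=true_params,
        noise_free_end=noise_free, seed=int(np.asarray(seed).item()) if np.isscalar(seed) else -1,
    )
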