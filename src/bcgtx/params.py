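"""Parameter containers and shipped defaults for the intravesical BCG treatment model.

The model tracks six populations inside the bladder: intravesical BCG (``B``),
effector immune cells (``E``), BCG-infected and uninfected cancer cells
(``T_i``, ``T_u``) and BCG-infected and uninfected healthy urothelial cells
(``H_i``, ``H_u``).  All rates are per hour; time is measured in hours
throughout the package.

The protocol constants shipped as defaults are the standard weekly induction
course: ``N = 6`` instillations of ``b = 2.8e6`` BCG units, one every
``tau = 168`` hours, with first-order BCG decay ``mu_B = 4.16e-3`` per hour and
a healthy-bladder cell capacity ``H_m = 1.84e9`` cells.  The interaction rates
have no consensus literature values at this granularity; the shipped baseline
was chosen so that, for a typical presentation (1e4-1e7 tumor cells), a full
induction course produces a moderate reduction of tumor burden while untreated
tumors grow several-fold over the same horizon (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Any

import yaml

__all__ = [
    "ModelParameters",
    "LegacyParameters",
    "DoseSchedule",
    "default_parameters",
    "default_schedule",
    "default_legacy_parameters",
    "load_config",
    "dump_config",
]

#: compartment order used everywhere in the package
STATE_NAMES = ("B", "E", "T_i", "T_u", "H_u", "H_i")

_RATE_FIELDS = (
    "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9",
    "mu_B", "mu_E", "alpha", "lambda_",
)


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and per-patient constants of the six-compartment model.

    Parameters
    ----------
    p1 : BCG elimination by effector cells (per effector cell per hour).
    p2 : BCG infection rate of uninfected cancer cells (per BCG unit per hour).
    p3 : effector-cell killing of cancer cells, infected and uninfected alike
        (per effector cell per hour).
    p4 : effector recruitment by intravesical bacteria (per BCG unit per hour).
    p5 : effector loss while destroying infected cancer cells.
    p6 : effector loss while destroying infected healthy cells.
    p7 : healthy urothelium logistic regrowth rate (per hour).
    p8 : BCG infection rate of healthy cells (per BCG unit per hour).
    p9 : effector-cell killing of infected healthy cells.
    mu_B : first-order BCG decay rate (per hour).
    mu_E : effector-cell decay rate (per hour).
    alpha : effector recruitment per infected (cancer or healthy) cell.
    lambda_ : cancer-cell net growth rate (per hour).
    H_m : healthy-bladder carrying capacity (cells).
    e0 : effector-cell count at treatment start (cells).
    T0 : tumor-cell count at treatment start (cells).
    """

    p1: float = 1.25e-8
    p2: float = 2.50e-10
    p3: float = 3.00e-7
    p4: float = 1.20e-9
    p5: float = 1.00e-9
    p6: float = 1.00e-9
    p7: float = 1.50e-3
    p8: float = 2.00e-14
    p9: float = 1.00e-7
    mu_B: float = 4.16e-3
    mu_E: float = 5.00e-3
    alpha: float = 3.00e-4
    lambda_: float = 2.00e-3
    H_m: float = 1.84e9
    e0: float = 1.0e3
    T0: float = 1.0e5

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (value >= 0.0):  # also catches NaN
                raise ValueError(f"rate {name!r} must be non-negative, got {value}")
        if not self.H_m > 0:
            raise ValueError(f"H_m must be positive, got {self.H_m}")
        if self.T0 > self.H_m:
            raise ValueError(f"T0={self.T0} exceeds the capacity H_m={self.H_m}")
        if self.e0 < 0 or self.T0 < 0:
            raise ValueError("e0 and T0 must be non-negative")

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class LegacyParameters:
    """Constants of the four-compartment continuous-instillation baseline.

    The baseline has no healthy-cell compartments; BCG is instilled at a
    constant rate ``b`` (units per hour) instead of in weekly pulses, and
    uninfected cancer cells are removed only through BCG infection.  ``mu1``
    and ``mu2`` are the BCG and effector decay rates.
    """

    p1: float = 1.25e-8
    p2: float = 2.50e-10
    p3: float = 3.00e-7
    p4: float = 1.20e-9
    p5: float = 1.00e-9
    alpha: float = 3.00e-4
    lambda_: float = 2.00e-3
    b: float = 2.8e6 / 168.0  # same weekly BCG mass as one pulsed dose
    mu1: float = 4.16e-3
    mu2: float = 5.00e-3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not (value >= 0.0):
                raise ValueError(f"legacy parameter {f.name!r} must be non-negative, got {value}")

    def replace(self, **changes: float) -> "LegacyParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DoseSchedule:
    """An impulsive instillation schedule: ``N`` doses of ``b`` units every ``tau`` hours.

    ``mode`` selects how the impulses enter the integrator:

    - ``"jump"`` (default): each dose is a state discontinuity ``B -> B + b``
      at ``t = m*tau``, implemented by restarting the integration at each dose
      time.  Robust and fast; no stiff 1/epsilon forcing.
    - ``"pulse"``: the literal triangular unit-integral approximation of the
      Dirac impulse with half-width ``epsilon`` hours enters the rhs.  The two
      modes agree in the limit ``epsilon -> 0``.
    """

    b: float = 2.8e6
    N: int = 6
    tau: float = 168.0
    epsilon: float = 0.5
    mode: str = "jump"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if not (0 < self.epsilon < self.tau / 2):
            raise ValueError(
                f"epsilon must lie in (0, tau/2)=(0, {self.tau / 2}), got {self.epsilon}"
            )
        if self.b < 0:
            raise ValueError(f"dose b must be non-negative, got {self.b}")
        if self.mode not in ("jump", "pulse"):
            raise ValueError(f"mode must be 'jump' or 'pulse', got {self.mode!r}")

    @property
    def duration(self) -> float:
        """Length of a full course, ``N * tau`` hours (one dwell interval per dose)."""
        return self.N * self.tau

    def dose_times(self, t_end: float | None = None) -> list[float]:
        t_end = self.duration if t_end is None else t_end
        return [m * self.tau for m in range(self.N) if m * self.tau <= t_end]

    def replace(self, **changes: Any) -> "DoseSchedule":
        return replace(self, **changes)


def default_parameters(**overrides: float) -> ModelParameters:
    """The shipped baseline parameter set (see module docstring)."""
    return ModelParameters(**overrides)


def default_schedule(**overrides: Any) -> DoseSchedule:
    """The standard weekly induction protocol (6 x 2.8e6 units, 168 h apart)."""
    return DoseSchedule(**overrides)


def default_legacy_parameters(**overrides: float) -> LegacyParameters:
    return LegacyParameters(**overrides)


def load_config(path: str) -> tuple[ModelParameters, DoseSchedule]:
    """Read a YAML config with optional ``parameters:`` and ``schedule:`` blocks."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    params = ModelParameters(**(raw.get("parameters") or {}))
    schedule = DoseSchedule(**(raw.get("schedule") or {}))
    return params, schedule


def dump_config(params: ModelParameters, schedule: DoseSchedule, path: str) -> None:
    payload = {"parameters": params.to_dict(), "schedule": dataclasses.asdict(schedule)}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
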