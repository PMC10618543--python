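"""Equilibria, Jacobian and linear stability of the six-compartment model.

Outside the dosing pulses the system is autonomous and admits exactly two
equilibria: the trivial state (everything zero) and the healthy state in which
the urothelium sits at its carrying capacity and no BCG, immune, or cancer
cells are present.  Both are non-hyperbolic — each Jacobian has a zero
eigenvalue (the infected-cancer row vanishes identically at both points) — and
whenever the cancer growth rate ``lambda_`` is positive both are unstable,
because the uninfected-cancer direction carries the eigenvalue ``lambda_``.
Biologically: a cancer-free bladder is not a robust state of this model; a
single surviving cancer cell regrows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import _core_jacobian, _pack, rhs
from .params import ModelParameters

__all__ = [
    "EquilibriumState",
    "StabilityReport",
    "find_equilibria",
    "jacobian",
    "classify_stability",
    "tabulated_jacobians",
]

_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumState:
    """A fixed point of the undosed flow; ``label`` is ``"trivial"`` or ``"healthy"``."""

    state: np.ndarray
    label: str


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues of the Jacobian at an equilibrium and their sign classification.

    ``classification`` is ``"unstable"`` if some eigenvalue has real part above
    the tolerance, ``"non-hyperbolic"`` if none does but some real part sits
    within the tolerance of zero, and ``"stable"`` otherwise.
    """

    equilibrium: EquilibriumState
    eigenvalues: np.ndarray
    classification: str
    tol: float


def _rate_scale(params: ModelParameters) -> float:
    rates = (
        params.mu_B, params.mu_E, params.alpha, params.lambda_,
        params.p7, params.p3 * params.e0,
    )
    return max(max(abs(r) for r in rates), 1e-12)


def find_equilibria(params: ModelParameters) -> list[EquilibriumState]:
    """The two equilibria of the undosed system, verified by substitution.

    Returns the trivial state ``(0,0,0,0,0,0)`` and the healthy state
    ``(0,0,0,0,H_m,0)``.  Each candidate is substituted into the rhs (dosing
    off) and its residual checked against ``1e-9 * H_m`` before being returned.
    """
    trivial = np.zeros(6)
    healthy = np.array([0.0, 0.0, 0.0, 0.0, params.H_m, 0.0])
    out = []
    for state, label in ((trivial, "trivial"), (healthy, "healthy")):
        residual = np.max(np.abs(rhs(0.0, state, params)))
        if residual > _RESIDUAL_TOL * params.H_m:
            raise AssertionError(
                f"candidate {label} equilibrium has rhs residual {residual}"
            )
        out.append(EquilibriumState(state=state, label=label))
    return out


def jacobian(params: ModelParameters, y) -> np.ndarray:
    """Exact Jacobian of the undosed rhs at state ``y`` (analytic partials)."""
    y = np.asarray(y, dtype=float)
    if y.shape != (6,):
        raise ValueError(f"state must have 6 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to jacobian")
    return _core_jacobian(y, _pack(params))


def classify_stability(
    params: ModelParameters,
    eq: EquilibriumState,
    tol: float | None = None,
) -> StabilityReport:
    """Eigenvalue classification of an equilibrium.

    ``tol`` defaults to ``1e-9`` times the largest rate magnitude, so an
    eigenvalue within that band of zero counts as zero (non-hyperbolic
    direction) rather than as growth or decay.
    """
    if tol is None:
        tol = 1e-9 * _rate_scale(params)
    eig = np.linalg.eigvals(jacobian(params, eq.state))
    re = eig.real
    if np.any(re > tol):
        cls = "unstable"
    elif np.any(np.abs(re) <= tol):
        cls = "non-hyperbolic"
    else:
        cls = "stable"
    return StabilityReport(equilibrium=eq, eigenvalues=eig, classification=cls, tol=tol)


def tabulated_jacobians(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """Hand-tabulated linearizations at the two equilibria, kept as fixtures.

    These matrices reproduce an earlier hand derivation of the trivial and
    healthy linearizations verbatim, including entries that are dimensionally
    inconsistent with the implemented dynamics (bare ``-1/H_m`` terms without
    the ``p7`` factor, and a ``p7 + 2`` diagonal entry in the healthy case).
    They are retained purely as regression fixtures and are never used for
    classification — :func:`jacobian` is.  Their qualitative conclusions (a
    zero row for infected cancer cells, hence a zero eigenvalue; instability
    for ``lambda_ > 0``) agree with the exact Jacobian.
    """
    p = params
    Hm = p.H_m
    J_trivial = np.array([
        [-p.mu_B, 0, 0, 0, 0, 0],
        [0, -p.mu_E, p.alpha, 0, 0, p.alpha],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, p.lambda_, 0, 0],
        [0, 0, -1.0 / Hm, -1.0 / Hm, p.p7, -1.0 / Hm],
        [0, 0, 0, 0, 0, 0],
    ])
    J_healthy = np.array([
        [-p.mu_B, 0, 0, 0, 0, 0],
        [0, -p.mu_E, p.alpha, 0, 0, p.alpha],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, p.lambda_, 0, 0],
        [-p.p8 * Hm, 0, -1.0 / Hm, -1.0 / Hm, p.p7 + 2.0, -1.0 / Hm],
        [p.p8 * Hm, 0, 0, 0, 0, 0],
    ])
    return J_trivial, J_healthy
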