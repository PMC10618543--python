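"""Integration of the impulsive six-compartment BCG treatment model.

The system couples intravesical BCG ``B``, effector cells ``E``, infected and
uninfected cancer cells ``T_i``/``T_u`` and infected and uninfected healthy
urothelial cells ``H_i``/``H_u``:

    dB/dt   = sum_m b*delta(t - m*tau) - p1*E*B - p2*B*T_u - p8*B*H_u - mu_B*B
    dE/dt   = -mu_E*E + alpha*(T_i + H_i) + p4*E*B - p5*E*T_i - p6*E*H_i
    dT_i/dt = p2*B*T_u - p3*T_i*E
    dT_u/dt = lambda*T_u - p2*B*T_u - p3*T_u*E
    dH_u/dt = p7*H_u*(1 - (H_u + H_i + T_u + T_i)/H_m) - p8*B*H_u
    dH_i/dt = p8*B*H_u - p9*E*H_i

Instillations are impulsive: dose ``m`` raises ``B`` by ``b`` units at
``t = m*tau``.  Two administrations are implemented (see
:class:`~bcgtx.params.DoseSchedule`): state jumps at the dose times (default),
or the literal triangular epsilon-approximation of the Dirac impulse entering
the rhs.  In pulse mode integration starts at ``-epsilon`` so that the full
first pulse is delivered.

The production integrator is LSODA (stiff/non-stiff switching) with the
analytic Jacobian supplied; a fixed-step RK4 reference integrator is provided
as an independent numerical oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .params import DoseSchedule, LegacyParameters, ModelParameters

__all__ = [
    "Trajectory",
    "dose_input",
    "rhs",
    "rhs_legacy",
    "initial_state",
    "simulate",
    "simulate_final",
    "simulate_legacy",
    "simulate_rk4",
    "tumor_burden",
]

_DEFAULT_RTOL = 1e-8


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: `times` (hours, increasing) and `states` (len(times) x 6)."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def state_at(self, t: float) -> np.ndarray:
        """Interpolated state at time ``t`` (must lie inside the span).

        Uses local cubic (Lagrange) interpolation within the continuous run
        containing ``t``; duplicated time stamps mark dose discontinuities and
        are never bridged.  At a dose time the post-dose state is returned.
        """
        times, states = self.times, self.states
        t0, t1 = times[0], times[-1]
        if not (t0 <= t <= t1):
            raise ValueError(f"time {t} outside trajectory span [{t0}, {t1}]")
        jumps = np.flatnonzero(np.diff(times) == 0.0)
        run_starts = np.concatenate(([0], jumps + 1))
        run_ends = np.concatenate((jumps, [len(times) - 1]))
        # the latest run starting at or before t (post-jump state at dose times)
        run = int(np.searchsorted(times[run_starts], t, side="right")) - 1
        a, b = int(run_starts[run]), int(run_ends[run])
        if a == b:
            return states[a].copy()
        k = int(np.searchsorted(times[a: b + 1], t)) + a
        w0 = max(a, k - 2)
        w1 = min(b, w0 + 3)
        w0 = max(a, w1 - 3)
        ts = times[w0: w1 + 1] - t
        ys = states[w0: w1 + 1]
        coeffs = np.polyfit(ts, ys, deg=len(ts) - 1)
        return np.asarray(coeffs[-1], dtype=float)


def dose_input(t: float, schedule: DoseSchedule) -> float:
    """Instillation rate at time ``t``: sum of triangular unit-integral pulses.

    Each pulse is centred at ``m*tau`` (``m = 0..N-1``), has half-width
    ``epsilon``, peak height ``b/epsilon`` and time-integral ``b``.
    """
    if not math.isfinite(t):
        raise ValueError(f"time must be finite, got {t}")
    eps, tau = schedule.epsilon, schedule.tau
    m = round(t / tau)
    if m < 0 or m >= schedule.N:
        return 0.0
    s = abs(t - m * tau)
    if s >= eps:
        return 0.0
    return schedule.b * (eps - s) / (eps * eps)


def _core_deriv(y, c, dose):
    """Derivatives of the six-compartment system; ``c`` is the packed rate tuple."""
    B, E, Ti, Tu, Hu, Hi = y
    p1, p2, p3, p4, p5, p6, p7, p8, p9, muB, muE, alpha, lam, Hm = c
    dB = dose - p1 * E * B - p2 * B * Tu - p8 * B * Hu - muB * B
    dE = -muE * E + alpha * (Ti + Hi) + p4 * E * B - p5 * E * Ti - p6 * E * Hi
    dTi = p2 * B * Tu - p3 * Ti * E
    dTu = lam * Tu - p2 * B * Tu - p3 * Tu * E
    dHu = p7 * Hu * (1.0 - (Hu + Hi + Tu + Ti) / Hm) - p8 * B * Hu
    dHi = p8 * B * Hu - p9 * E * Hi
    return (dB, dE, dTi, dTu, dHu, dHi)


def _core_jacobian(y, c):
    """Analytic Jacobian of :func:`_core_deriv` with dosing off (6x6 array)."""
    B, E, Ti, Tu, Hu, Hi = y
    p1, p2, p3, p4, p5, p6, p7, p8, p9, muB, muE, alpha, lam, Hm = c
    J = np.zeros((6, 6))
    J[0, 0] = -p1 * E - p2 * Tu - p8 * Hu - muB
    J[0, 1] = -p1 * B
    J[0, 3] = -p2 * B
    J[0, 4] = -p8 * B
    J[1, 0] = p4 * E
    J[1, 1] = -muE + p4 * B - p5 * Ti - p6 * Hi
    J[1, 2] = alpha - p5 * E
    J[1, 5] = alpha - p6 * E
    J[2, 0] = p2 * Tu
    J[2, 1] = -p3 * Ti
    J[2, 2] = -p3 * E
    J[2, 3] = p2 * B
    J[3, 0] = -p2 * Tu
    J[3, 1] = -p3 * Tu
    J[3, 3] = lam - p2 * B - p3 * E
    J[4, 0] = -p8 * Hu
    J[4, 2] = -p7 * Hu / Hm
    J[4, 3] = -p7 * Hu / Hm
    J[4, 4] = p7 * (1.0 - (Hu + Hi + Tu + Ti) / Hm) - p7 * Hu / Hm - p8 * B
    J[4, 5] = -p7 * Hu / Hm
    J[5, 0] = p8 * Hu
    J[5, 1] = -p9 * Hi
    J[5, 4] = p8 * B
    J[5, 5] = -p9 * E
    return J


def _pack(params: ModelParameters) -> tuple:
    return (
        params.p1, params.p2, params.p3, params.p4, params.p5, params.p6,
        params.p7, params.p8, params.p9, params.mu_B, params.mu_E,
        params.alpha, params.lambda_, params.H_m,
    )


def rhs(t: float, y, params: ModelParameters, schedule: DoseSchedule | None = None):
    """Right-hand side of the six-compartment system at ``(t, y)``.

    The dosing term is the triangular pulse input when ``schedule`` is given in
    pulse mode; in jump mode (or without a schedule) doses are applied as state
    discontinuities by the integrator and the rhs carries no dosing term.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (6,):
        raise ValueError(f"state must have 6 components, got shape {y.shape}")
    if not (math.isfinite(t) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to rhs")
    dose = 0.0
    if schedule is not None and schedule.mode == "pulse":
        dose = dose_input(t, schedule)
    return np.array(_core_deriv(y, _pack(params), dose))


def rhs_legacy(t: float, y, params: LegacyParameters):
    """Right-hand side of the four-compartment continuous-instillation baseline."""
    y = np.asarray(y, dtype=float)
    if y.shape != (4,):
        raise ValueError(f"legacy state must have 4 components, got shape {y.shape}")
    if not (math.isfinite(t) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to rhs_legacy")
    B, E, Ti, Tu = y
    p = params
    dB = -p.p1 * E * B - p.p2 * B * Tu - p.mu1 * B + p.b
    dE = -p.mu2 * E + p.alpha * Ti + p.p4 * E * B - p.p5 * E * Ti
    dTi = p.p2 * B * Tu - p.p3 * Ti * E
    dTu = p.lambda_ * Tu - p.p2 * B * Tu
    return np.array([dB, dE, dTi, dTu])


def initial_state(params: ModelParameters) -> np.ndarray:
    """Pre-treatment state: no BCG, ``e0`` effectors, ``T0`` uninfected tumor cells.

    ``(B, E, T_i, T_u, H_u, H_i) = (0, e0, 0, T0, H_m - T0, 0)``; requires
    ``0 < T0 < H_m`` and ``e0 > 0``.
    """
    if not params.e0 > 0:
        raise ValueError(f"initial effector level e0 must be positive, got {params.e0}")
    if not 0 < params.T0 < params.H_m:
        raise ValueError(
            f"initial tumor burden T0 must satisfy 0 < T0 < H_m, got T0={params.T0}, H_m={params.H_m}"
        )
    return np.array([0.0, params.e0, 0.0, params.T0, params.H_m - params.T0, 0.0])


def _atol(params: ModelParameters, schedule: DoseSchedule | None) -> np.ndarray:
    """Component-wise absolute tolerance, 1e-6 of each compartment's typical scale."""
    b = schedule.b if schedule is not None else 1.0
    t_scale = max(params.T0, 1.0)
    return 1e-6 * np.array(
        [max(b, 1.0), max(params.e0, 1.0), t_scale, t_scale, params.H_m, t_scale]
    )


def _check_nonnegative(y: np.ndarray, atol: np.ndarray) -> None:
    if np.any(y < -10.0 * atol):
        raise RuntimeError(f"state went significantly negative: {y}")


def _integrate_segments(deriv, jac, y0, breakpoints, jumps, rtol, atol,
                        points_per_segment, hmax_by_segment=None):
    """Integrate over consecutive ``breakpoints``; ``jumps[i]`` is added to the
    state before segment ``i`` starts.  Returns (times, states) arrays."""
    times = [breakpoints[0]]
    y = np.array(y0, dtype=float)
    if jumps and jumps[0] is not None:
        y = y + jumps[0]
    states = [y.copy()]
    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if i > 0 and jumps and jumps[i] is not None:
            y = y + jumps[i]
            times.append(t0)
            states.append(y.copy())
        if t1 <= t0:
            continue
        n_pts = max(points_per_segment, 2)
        t_grid = np.linspace(t0, t1, n_pts)
        hmax = 0.0
        if hmax_by_segment is not None and hmax_by_segment[i]:
            hmax = hmax_by_segment[i]
        sol = odeint(
            deriv, y, t_grid, Dfun=jac, tfirst=True,
            rtol=rtol, atol=atol, hmax=hmax, mxstep=50000,
        )
        if not np.all(np.isfinite(sol)):
            raise RuntimeError("ODE integration produced non-finite values")
        _check_nonnegative(sol[-1], np.asarray(atol, dtype=float) * np.ones(len(y)))
        times.extend(t_grid[1:].tolist())
        states.extend(list(sol[1:]))
        y = sol[-1]
    return np.array(times), np.array(states)


def simulate(
    params: ModelParameters,
    schedule: DoseSchedule,
    t_end: float | None = None,
    *,
    rtol: float = _DEFAULT_RTOL,
    points_per_segment: int = 40,
) -> Trajectory:
    """Integrate the model from the pre-treatment state to ``t_end``.

    ``t_end`` defaults to the schedule duration ``N * tau``.  In jump mode the
    integration restarts at every dose time with ``B`` incremented by ``b``; in
    pulse mode the triangular impulses enter the rhs and the integration starts
    at ``-epsilon`` so the first pulse is fully delivered.  States are reported
    clipped to zero (tiny negative solver excursions only); a significant
    negative excursion raises ``RuntimeError``.
    """
    t_end = schedule.duration if t_end is None else float(t_end)
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    y0 = initial_state(params)
    c = _pack(params)
    atol = _atol(params, schedule)

    if schedule.mode == "jump":
        deriv = lambda t, y: _core_deriv(y, c, 0.0)  # noqa: E731
        jac = lambda t, y: _core_jacobian(y, c)  # noqa: E731
        dose_times = [t for t in schedule.dose_times(t_end) if t < t_end]
        breakpoints = [0.0] + [t for t in dose_times if t > 0.0] + [t_end]
        breakpoints = sorted(set(breakpoints))
        jump_vec = np.array([schedule.b, 0, 0, 0, 0, 0], dtype=float)
        jumps = [jump_vec if bp in dose_times else None for bp in breakpoints[:-1]]
        times, states = _integrate_segments(
            deriv, jac, y0, breakpoints, jumps, rtol, atol, points_per_segment
        )
    else:  # pulse mode
        deriv = lambda t, y: _core_deriv(y, c, dose_input(t, schedule))  # noqa: E731
        jac = lambda t, y: _core_jacobian(y, c)  # noqa: E731
        eps = schedule.epsilon
        edges: set[float] = {-eps, t_end}
        for m in range(schedule.N):
            tc = m * schedule.tau
            if tc - eps < t_end:
                edges.add(max(tc - eps, -eps))
                edges.add(min(tc + eps, t_end))
        breakpoints = sorted(edges)
        hmax_by_segment = []
        for i in range(len(breakpoints) - 1):
            mid = 0.5 * (breakpoints[i] + breakpoints[i + 1])
            in_pulse = dose_input(np.clip(mid, 0.0, None), schedule) > 0 or dose_input(mid, schedule) > 0
            hmax_by_segment.append(eps / 5.0 if in_pulse else 0.0)
        times, states = _integrate_segments(
            deriv, jac, y0, breakpoints, [None] * (len(breakpoints) - 1),
            rtol, atol, points_per_segment, hmax_by_segment,
        )

    states = np.where(states < 0.0, 0.0, states)  # clip for reporting only
    return Trajectory(times=times, states=states)


def simulate_final(
    params: ModelParameters,
    schedule: DoseSchedule,
    t_end: float | None = None,
    *,
    rtol: float = 1e-6,
) -> np.ndarray:
    """Fast path: final state only, coarse output grid, looser default rtol.

    Used by the fitting loop where only the end-of-treatment burden is needed.
    """
    traj = simulate(params, schedule, t_end, rtol=rtol, points_per_segment=2)
    return traj.final_state


def simulate_legacy(
    params: LegacyParameters,
    init,
    t_end: float,
    *,
    rtol: float = _DEFAULT_RTOL,
    n_points: int = 200,
) -> Trajectory:
    """Integrate the continuous-instillation four-compartment baseline."""
    if not t_end > 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (4,):
        raise ValueError("legacy initial state must have 4 components")
    p = params
    atol = 1e-6 * np.maximum(np.abs(y0), 1.0)

    def deriv(t, y):
        B, E, Ti, Tu = y
        return (
            -p.p1 * E * B - p.p2 * B * Tu - p.mu1 * B + p.b,
            -p.mu2 * E + p.alpha * Ti + p.p4 * E * B - p.p5 * E * Ti,
            p.p2 * B * Tu - p.p3 * Ti * E,
            p.lambda_ * Tu - p.p2 * B * Tu,
        )

    t_grid = np.linspace(0.0, t_end, max(n_points, 2))
    sol = odeint(deriv, y0, t_grid, tfirst=True, rtol=rtol, atol=atol, mxstep=50000)
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("legacy ODE integration produced non-finite values")
    _check_nonnegative(sol[-1], atol)
    sol = np.where(sol < 0.0, 0.0, sol)
    return Trajectory(times=t_grid, states=sol)


def simulate_rk4(
    params: ModelParameters,
    schedule: DoseSchedule,
    t_end: float | None = None,
    *,
    step: float = 0.05,
) -> Trajectory:
    """Fixed-step classical RK4 reference integrator (jump-mode dosing).

    Deliberately independent of the LSODA production path; used as a numerical
    oracle in the test-suite.  ``step`` is the nominal step in hours; each
    inter-dose segment uses a whole number of equal steps.
    """
    t_end = schedule.duration if t_end is None else float(t_end)
    c = _pack(params)
    y = initial_state(params)
    dose_times = set(schedule.dose_times(t_end))
    breakpoints = sorted({0.0, t_end} | {t for t in dose_times if t < t_end})
    times = [0.0]
    if 0.0 in dose_times:
        y = y + np.array([schedule.b, 0, 0, 0, 0, 0])
    states = [y.copy()]

    def f(yv):
        return np.array(_core_deriv(yv, c, 0.0))

    for i in range(len(breakpoints) - 1):
        t0, t1 = breakpoints[i], breakpoints[i + 1]
        if i > 0 and t0 in dose_times:
            y = y + np.array([schedule.b, 0, 0, 0, 0, 0])
            times.append(t0)
            states.append(y.copy())
        n = max(int(math.ceil((t1 - t0) / step)), 1)
        h = (t1 - t0) / n
        for _ in range(n):
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        times.append(t1)
        states.append(y.copy())
    return Trajectory(times=np.array(times), states=np.array(states))


def tumor_burden(traj: Trajectory, t: float) -> float:
    """Total cancer-cell count ``T_i(t) + T_u(t)`` by interpolation on the trajectory."""
    state = traj.state_at(t)
    return float(state[2] + state[3])
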