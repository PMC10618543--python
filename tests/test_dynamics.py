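"""Core ODE system: dosing input, right-hand sides, integration invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from bcgtx.dynamics import (
    dose_input,
    initial_state,
    rhs,
    rhs_legacy,
    simulate,
    simulate_final,
    simulate_legacy,
    simulate_rk4,
    tumor_burden,
)
from bcgtx.params import (
    DoseSchedule,
    LegacyParameters,
    ModelParameters,
    default_parameters,
    default_schedule,
)

ZERO_RATES = dict(
    p1=0, p2=0, p3=0, p4=0, p5=0, p6=0, p7=0, p8=0, p9=0,
    mu_B=0, mu_E=0, alpha=0, lambda_=0,
)


def zero_params(**overrides):
    return ModelParameters(**{**ZERO_RATES, **overrides})


class TestDoseInput:
    def test_peak_height_is_b_over_epsilon(self, schedule):
        for m in range(schedule.N):
            assert dose_input(m * schedule.tau, schedule) == pytest.approx(
                schedule.b / schedule.epsilon
            )

    def test_zero_outside_pulse_support(self, schedule):
        eps = schedule.epsilon
        assert dose_input(2 * eps, schedule) == 0.0
        assert dose_input(schedule.tau + 2 * eps, schedule) == 0.0
        assert dose_input(schedule.tau / 2, schedule) == 0.0
        # pulses beyond the N-th dose do not exist
        assert dose_input(schedule.N * schedule.tau, schedule) == 0.0

    def test_pulse_integral_equals_dose(self, schedule):
        # one instillation raises B by exactly b units
        eps = schedule.epsilon
        for m in (0, 3):
            integral, _ = quad(
                dose_input, m * schedule.tau - eps, m * schedule.tau + eps,
                args=(schedule,), points=[m * schedule.tau],
            )
            assert integral == pytest.approx(schedule.b, rel=1e-6)

    def test_nonfinite_time_rejected(self, schedule):
        with pytest.raises(ValueError):
            dose_input(np.nan, schedule)


class TestRhs:
    def test_zero_state_is_stationary_outside_pulses(self, params, schedule):
        d = rhs(schedule.tau / 2, np.zeros(6), params, schedule)
        assert np.all(d == 0.0)

    def test_isolated_tumor_grows_exponentially(self, params, schedule):
        y = np.array([0, 0, 0, 5e4, 0, 0], dtype=float)
        d = rhs(schedule.tau / 2, y, params, schedule)
        assert d[3] == pytest.approx(params.lambda_ * 5e4)
        assert np.all(d[[0, 1, 2, 4, 5]] == 0.0)

    def test_healthy_equilibrium_is_stationary(self, params, schedule):
        y = np.array([0, 0, 0, 0, params.H_m, 0], dtype=float)
        d = rhs(schedule.tau / 2, y, params, schedule)
        assert np.allclose(d, 0.0)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(ValueError):
            rhs(0.0, [np.inf, 0, 0, 0, 0, 0], params)


class TestRhsLegacy:
    def test_empty_bladder_gets_constant_instillation(self):
        p = LegacyParameters()
        d = rhs_legacy(0.0, np.zeros(4), p)
        assert d[0] == pytest.approx(p.b)
        assert np.all(d[1:] == 0.0)

    def test_pure_bcg_decay(self):
        p = LegacyParameters(b=0.0)
        d = rhs_legacy(0.0, [2e6, 0, 0, 0], p)
        assert d[0] == pytest.approx(-p.mu1 * 2e6)

    def test_isolated_tumor_growth(self):
        p = LegacyParameters()
        d = rhs_legacy(0.0, [0, 0, 0, 1e5], p)
        assert d[3] == pytest.approx(p.lambda_ * 1e5)


class TestInitialState:
    def test_matches_protocol_start(self):
        p = default_parameters(e0=1e3, T0=1e5)
        y = initial_state(p)
        assert np.allclose(y, [0, 1e3, 0, 1e5, 1.84e9 - 1e5, 0])

    def test_tumor_at_capacity_rejected(self):
        p = default_parameters(T0=1.84e9)
        with pytest.raises(ValueError):
            initial_state(p)

    def test_zero_effectors_rejected(self):
        p = default_parameters(e0=0.0)
        with pytest.raises(ValueError):
            initial_state(p)


class TestSimulate:
    def test_exponential_growth_closed_form(self):
        # with B = E = 0 the tumor equation decouples: T_u(t) = T0 e^{lambda t}
        p = zero_params(lambda_=2e-3, e0=1e-12, T0=1e5)
        s = DoseSchedule(b=0.0, N=6, tau=168.0)
        traj = simulate(p, s)
        for t in (100.0, 500.0, s.duration):
            expected = 1e5 * np.exp(2e-3 * t)
            assert tumor_burden(traj, t) == pytest.approx(expected, rel=1e-6)

    def test_single_dose_exponential_decay(self):
        # all interactions off, one dose at t=0, first-order decay of B
        p = zero_params(mu_B=4.16e-3, e0=1.0, T0=1.0)
        s = DoseSchedule(b=2.8e6, N=1, tau=168.0)
        traj = simulate(p, s)
        for t in (10.0, 84.0, 168.0):
            assert traj.state_at(t)[0] == pytest.approx(2.8e6 * np.exp(-4.16e-3 * t), rel=1e-4)

    def test_dose_conservation_without_elimination(self):
        # no elimination: after all N pulses, B = N*b in both modes
        p = zero_params(e0=1.0, T0=1.0)
        for mode in ("jump", "pulse"):
            s = DoseSchedule(b=2.8e6, N=6, tau=168.0, mode=mode)
            traj = simulate(p, s)
            assert traj.final_state[0] == pytest.approx(6 * 2.8e6, rel=1e-4)

    def test_jump_and_pulse_modes_agree_for_small_epsilon(self, params):
        s_jump = default_schedule()
        s_pulse = default_schedule(mode="pulse", epsilon=1e-3 * 168.0)
        bj = tumor_burden(simulate(params, s_jump), s_jump.duration)
        bp = tumor_burden(simulate(params, s_pulse), s_jump.duration)
        assert bp == pytest.approx(bj, rel=0.01)

    def test_production_solver_matches_rk4_reference(self, params, schedule):
        traj = simulate(params, schedule)
        ref = simulate_rk4(params, schedule, step=0.05)
        b_prod = tumor_burden(traj, schedule.duration)
        b_ref = float(ref.final_state[2] + ref.final_state[3])
        assert b_prod == pytest.approx(b_ref, rel=1e-4)

    @pytest.mark.parametrize("seed", range(4))
    def test_nonnegativity_for_random_parameters(self, seed):
        # random non-negative rates around the defaults; protocol start state
        rng = np.random.default_rng(seed)
        base = default_parameters()
        scales = 10 ** rng.uniform(-0.7, 0.7, 13)
        names = ["p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9",
                 "mu_B", "mu_E", "alpha", "lambda_"]
        p = base.replace(**{n: getattr(base, n) * s for n, s in zip(names, scales)},
                         T0=float(10 ** rng.uniform(4, 7)))
        traj = simulate(p, default_schedule())
        assert np.all(traj.states >= 0.0)

    @pytest.mark.parametrize("T0", [1e4, 1e6, 1e7])
    def test_total_tissue_respects_capacity(self, T0):
        # healthy regrowth is logistic in total tissue, so the sum of the four
        # tissue compartments stays at the carrying capacity (tumor growth over
        # a course is orders of magnitude below H_m for realistic rates)
        p = default_parameters(T0=T0)
        traj = simulate(p, default_schedule())
        total_tissue = traj.states[:, 2:].sum(axis=1)
        assert np.all(total_tissue <= p.H_m * (1 + 1e-3))

    def test_fast_final_path_matches_dense(self, params, schedule):
        dense = tumor_burden(simulate(params, schedule), schedule.duration)
        fast = simulate_final(params, schedule)
        assert float(fast[2] + fast[3]) == pytest.approx(dense, rel=1e-3)

    def test_invalid_horizon_rejected(self, params, schedule):
        with pytest.raises(ValueError):
            simulate(params, schedule, t_end=-1.0)


class TestTumorBurden:
    def test_initial_burden_is_T0(self, params, schedule):
        traj = simulate(params, schedule)
        assert tumor_burden(traj, 0.0) == pytest.approx(params.T0)

    def test_constant_when_all_rates_zero(self):
        p = zero_params(e0=1.0, T0=1e5)
        traj = simulate(p, DoseSchedule(b=0.0, N=2, tau=168.0), t_end=336.0)
        for t in (0.0, 100.0, 336.0):
            assert tumor_burden(traj, t) == pytest.approx(1e5, rel=1e-9)

    def test_monotone_decrease_under_pure_killing(self):
        # lambda = 0 and constant-ish killing: burden never increases
        p = zero_params(p2=2.5e-10, p3=3e-7, e0=5e3, T0=1e5)
        traj = simulate(p, default_schedule())
        burden = traj.states[:, 2] + traj.states[:, 3]
        assert np.all(np.diff(burden) <= 1e-6 * burden[:-1] + 1e-9)

    def test_out_of_span_time_rejected(self, params, schedule):
        traj = simulate(params, schedule)
        with pytest.raises(ValueError):
            tumor_burden(traj, schedule.duration + 1.0)


class TestSimulateLegacy:
    def test_self_consistent_tumor_growth(self):
        p = LegacyParameters(b=0.0, p1=0, p2=0, p3=0, p4=0, p5=0, alpha=0, mu1=0, mu2=0)
        traj = simulate_legacy(p, (0, 0, 0, 1e5), 500.0)
        assert traj.final_state[3] == pytest.approx(1e5 * np.exp(p.lambda_ * 500.0), rel=1e-6)

    def test_four_compartments_returned(self):
        traj = simulate_legacy(LegacyParameters(), (0, 1e3, 0, 1e5), 336.0)
        assert traj.states.shape[1] == 4
        assert np.all(traj.states >= 0.0)
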