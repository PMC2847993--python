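import warnings

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ribodyn.core_models import NonlinearParams, integrate
from ribodyn.nonlinear_asymptotics import (
    StageAssumptionError,
    acap_regime,
    compare_to_numeric,
    glue,
    is_acap,
    numeric_transition_times,
    stage1_solution,
    stage2_scalar_rhs,
    stage2_solution,
    stage3_solution,
)
from ribodyn.nonlinear_steady import classify_regime, steady_state_exact
from ribodyn.signatures import measure_relaxation_time


@pytest.fixture(scope="module")
def efficient_reference(efficient_params):
    """Numeric trajectory, relaxation time and crossings for k4 = 0.1."""
    tau, traj = measure_relaxation_time(efficient_params)
    return tau, traj, numeric_transition_times(traj)


class TestStage1:
    def test_starts_exactly_at_free_pools(self, efficient_params):
        s1 = stage1_solution(efficient_params)
        assert s1.evaluate(0.0)[0] == pytest.approx(
            efficient_params.free_init(), abs=1e-9
        )

    def test_quasiequilibrium_plateaus_track_numeric(
        self, efficient_params, efficient_reference
    ):
        """eIF4F, mRNA:40S and AUG sit on their plateaus while 80S is
        still small; agreement within 20% before the drift onset t'."""
        _, traj, _ = efficient_reference
        s1 = stage1_solution(efficient_params)
        grid = np.geomspace(1e-3, s1.info["t_prime"] / 3.0, 40)
        approx = s1.evaluate(grid)
        scale = np.abs(traj.states).max(axis=0)
        for j in (2, 3, 4):  # eIF4F, mRNA:40S, AUG
            exact = np.interp(grid, traj.times, traj.states[:, j])
            err = np.abs(approx[:, j] - exact) / np.maximum(
                np.abs(exact), 0.02 * scale[j]
            )
            assert err.max() <= 0.20

    def test_stage_end_estimate_close_to_numeric_crossing(
        self, efficient_params, efficient_reference
    ):
        _, _, crossings = efficient_reference
        t_dprime = stage1_solution(efficient_params).info["t_dprime"]
        assert 0.5 <= t_dprime / crossings.t_dprime <= 2.0

    def test_refuses_weak_cap_start(self, efficient_params):
        with pytest.raises(StageAssumptionError, match="weak-cap"):
            stage1_solution(efficient_params.replace(k1=0.01))


class TestStage2:
    def test_conserved_quantity_of_the_reduction(self, efficient_params):
        """[40S] + [AUG] is (approximately) invariant along the reduced
        Stage-2 dynamics once the ribosome pool has filled."""
        sol = glue(efficient_params)
        s2 = sol.stages[1]
        A = s2.info["stage2_params"].A
        tt = np.linspace(s2.t_start * 1.1, s2.t_end * 0.95, 50)
        states = s2.evaluate(tt)
        drift = np.abs(states[:, 0] + states[:, 4] - A) / A
        assert drift.max() < 0.10

    def test_closed_form_descent_matches_scalar_ode(self, efficient_params):
        """The piecewise linear/exponential [40S] descent vs the direct
        integration of the unsimplified scalar reduction; error normalized
        by the stage amplitude (the descent spans two orders of magnitude)."""
        sol = glue(efficient_params)
        s2 = sol.stages[1]
        sp = s2.info["stage2_params"]
        u0 = float(s2.evaluate(s2.t_start)[0, 0])
        ode = solve_ivp(
            lambda t, y: [stage2_scalar_rhs(efficient_params, y[0], sp.A)],
            (s2.t_start, s2.t_end), [u0],
            dense_output=True, rtol=1e-10, atol=1e-12,
        )
        grid = np.linspace(s2.t_start, s2.t_end, 120)
        u23 = ode.sol(grid)[0]
        u26 = s2.info["closed_form_40S"](grid)
        assert np.abs(u26 - u23).max() / np.abs(u23).max() <= 0.15

    def test_descent_monotone_toward_quasi_steady_value(self, efficient_params):
        sol = glue(efficient_params)
        s2 = sol.stages[1]
        sp = s2.info["stage2_params"]
        assert sp.K1 > 0 and sp.K2 > 0 and sp.c40S_s2 > 0
        grid = np.linspace(s2.t_start, s2.t_end * 3.0, 200)
        u = s2.info["closed_form_40S"](grid)
        assert np.all(np.diff(u) <= 1e-9)
        assert u[-1] == pytest.approx(sp.c40S_s2, rel=0.05)

    def test_handoff_violation_raises_with_diagnostic(self, efficient_params):
        bad = np.array([1.0, 20.0, 5.0, 1.0, 0.1, 5.0])  # 40S << eIF4F etc.
        with pytest.raises(StageAssumptionError, match=r"\[40S\]"):
            stage2_solution(efficient_params, bad, 1.0)


class TestStage3:
    def test_terminal_values_equal_exact_steady_state(self, efficient_params):
        sol = glue(efficient_params)
        target = steady_state_exact(efficient_params).state_array()
        final = sol.evaluate(1e6)[0]
        assert final == pytest.approx(target, rel=0.02, abs=1e-9)

    def test_limit_independent_of_handoff_transients(self, efficient_params):
        sol = glue(efficient_params)
        s3 = sol.stages[2]
        assert np.isfinite(s3.info["B"])
        state = s3.evaluate(s3.t_start)[0]
        perturbed = state.copy()
        perturbed[0] *= 1.2  # nudge the handed-over 40S value
        perturbed[4] -= 0.2 * state[0]
        s3b = stage3_solution(efficient_params, perturbed, s3.t_start)
        target = steady_state_exact(efficient_params).state_array()
        assert s3b.evaluate(1e6)[0] == pytest.approx(target, rel=0.02, abs=1e-9)

    def test_stage_relaxation_time_close_to_numeric_chain_band(
        self, efficient_params, efficient_reference
    ):
        """Stage-3 relaxation vs the numeric 10%-band time of the relaxing
        chain species (40S, mRNA:40S), measured from the numeric t'''."""
        tau, traj, crossings = efficient_reference
        sol = glue(efficient_params)
        target = steady_state_exact(efficient_params).state_array()
        tol = 0.1 * np.maximum(np.abs(target), 1e-4)
        numeric = 0.0
        for j in (0, 3):
            out = np.where(
                (np.abs(traj.states[:, j] - target[j]) > tol[j])
                & (traj.times >= crossings.t_tprime)
            )[0]
            if len(out):
                numeric = max(numeric, traj.times[out[-1]] - crossings.t_tprime)
        stage_relax = sol.stages[2].info["stage_relaxation_time"]
        assert 0.5 <= stage_relax / numeric <= 2.0


class TestGlue:
    def test_single_stage_route_for_inefficient_baseline(self, default_params):
        sol = glue(default_params)
        assert sol.route == "single_stage"
        assert len(sol.stages) == 1
        # qualitative agreement with the numeric relaxation
        tau, traj = measure_relaxation_time(default_params)
        errs = compare_to_numeric(default_params, sol)
        assert max(errs.values()) <= 0.25
        assert 0.2 <= sol.relaxation_time / tau <= 2.0

    def test_three_stage_tracking_slow_recycling(self, efficient_params):
        errs = compare_to_numeric(efficient_params)
        assert max(errs.values()) <= 0.25

    def test_three_stage_tracking_strong_separation(
        self, strong_separation_params
    ):
        errs = compare_to_numeric(strong_separation_params)
        assert max(errs.values()) <= 0.15

    def test_gluing_continuity_on_the_40S_variable(self, efficient_params):
        sol = glue(efficient_params)
        for earlier, later in zip(sol.stages, sol.stages[1:]):
            t_switch = later.t_start
            left = earlier.evaluate(t_switch)[0, 0]
            right = later.evaluate(t_switch)[0, 0]
            assert abs(left - right) / max(abs(left), 1e-12) < 1e-6

    def test_transition_ordering_and_factor_two_accuracy(
        self, efficient_params, efficient_reference
    ):
        _, _, numeric = efficient_reference
        sol = glue(efficient_params)
        tr = sol.transitions
        assert 0 < tr.t_prime <= tr.t_dprime < tr.t_tprime
        closed = sol.stages[1].info["t_tprime_closed_form"]
        for analytic, exact in (
            (tr.t_prime, numeric.t_prime),
            (tr.t_dprime, numeric.t_dprime),
            (closed, numeric.t_tprime),
        ):
            assert 0.5 <= analytic / exact <= 2.0

    def test_route_agrees_with_regime_classification(
        self, default_params, efficient_params, strong_separation_params
    ):
        for p in (default_params, efficient_params, strong_separation_params):
            sol = glue(p)
            expected = (
                "three_stage" if classify_regime(p) == "efficient"
                else "single_stage"
            )
            assert sol.route == expected

    def test_boundary_band_falls_back_to_numerics(self, default_params):
        p = default_params.replace(k4=0.48)  # beta exactly 1
        with pytest.warns(UserWarning, match="boundary"):
            sol = glue(p)
        assert sol.route == "numeric"

    def test_oracle_convergence_with_separation(self):
        """Sweeping the elongation/recycling separation x10 -> x1000: the
        species slaved to the separated fast reactions converge
        monotonically; the glued solution stays within 15% overall."""
        errs = [
            compare_to_numeric(NonlinearParams(2.0, 2.0, 0.5 * s, 1.0 / s))
            for s in (10.0, 100.0, 1000.0)
        ]
        for species in ("c60S", "c80S"):
            seq = [e[species] for e in errs]
            assert seq[0] >= seq[1] >= seq[2]
        assert max(max(e.values()) for e in errs) <= 0.15


class TestAcapRegime:
    def test_detection_predicate(self, default_params):
        assert not is_acap(default_params)
        assert is_acap(default_params.replace(k1=0.01))

    def test_weak_cap_lowers_steady_rate(self):
        wt = NonlinearParams(k1=2.0, k2=3.0, k3=50.0, k4=0.1)
        acap = wt.replace(k1=0.01)
        sol = acap_regime(acap)
        assert sol.meta["acap"]
        assert (
            steady_state_exact(acap).prsynth < steady_state_exact(wt).prsynth
        )

    def test_numeric_stages_inherit_conservation(self, default_params):
        acap = default_params.replace(k1=0.01)
        sol = acap_regime(acap)
        traj = sol.meta["trajectory"]
        assert traj.conservation_residuals().max() <= 1e-6
        # stage windows partition the time axis
        assert sol.stages[0].t_start == 0.0
        assert np.isinf(sol.stages[-1].t_end)
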