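"""Single-plasmid models: right-hand sides, thresholds, equilibria, stability."""
import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidsim import (
    NO_INVASION,
    ConjugationParams,
    CopyNumberParams,
    SystemState,
    TransformationParams,
    classify_stability,
    conjugation_invasion_threshold,
    conjugation_rhs,
    conjugative_invasion_barrier,
    find_equilibria,
    integrate,
    integrate_to_steady_state,
    optimal_copy_number,
    phase_diagram,
    plasmid_free_equilibrium,
    transformation_invasion_threshold,
    transformation_rhs,
)
from plasmidsim.dynamics import (
    _conjugation_rhs_arr,
    _rhs_and_jac,
    _transformation_rhs_arr,
    conjugation_jacobian,
    continuous_optimal_copy_number,
    transformation_jacobian,
)


def _numeric_jacobian(f, y, eps=1e-6):
    n = len(y)
    J = np.zeros((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = eps
        J[:, j] = (f(y + e) - f(y - e)) / (2 * eps)
    return J


class TestRightHandSides:
    def test_plasmid_free_state_is_a_fixed_point(self):
        p = ConjugationParams(S=1, delta=0.1, alpha=1)
        assert conjugation_rhs([10, 0, 0.1], p) == pytest.approx([0, 0, 0])
        tp = TransformationParams(S=1, delta=0.1, alpha=1)
        assert transformation_rhs([10, 0, 0.1, 0], tp) == pytest.approx([0, 0, 0, 0])

    def test_conjugation_derivatives_by_direct_substitution(self):
        p = ConjugationParams(alpha=1, Delta=0.1, gamma_c=0.2, p_ell=0, delta=0.1, S=1)
        np.testing.assert_allclose(
            conjugation_rhs([1, 1, 1], p), [0.7, 1.0, -0.9], rtol=1e-12
        )

    def test_transformation_release_term(self):
        tp = TransformationParams(Delta=0.2, n_eff=0.6, delta=0.1, delta_p=0.3)
        dy = transformation_rhs([0, 1, 0, 0], tp)
        assert dy[3] == pytest.approx(0.06)

    @pytest.mark.parametrize("rho", [0.0, 1.0, 7.3])
    def test_no_spontaneous_plasmid_creation(self, rho):
        p = ConjugationParams(Delta=0.2, gamma_c=0.5, p_ell=0.1)
        assert conjugation_rhs([rho, 0.0, 0.8], p)[1] == 0.0
        tp = TransformationParams(Delta=0.2, gamma_t=0.5, p_ell=0.1)
        dy = transformation_rhs([rho, 0.0, 0.8, 0.0], tp)
        assert dy[1] == 0.0 and dy[3] == 0.0

    def test_negative_state_rejected(self):
        p = ConjugationParams()
        with pytest.raises(ValueError):
            conjugation_rhs([-1, 0, 1], p)

    def test_missing_free_plasmid_component_rejected(self):
        tp = TransformationParams()
        with pytest.raises(ValueError):
            transformation_rhs(SystemState(1, 1, 1), tp)

    @pytest.mark.parametrize("mech", ["conjugation", "transformation"])
    def test_analytic_jacobian_matches_central_differences(self, mech):
        rng = np.random.default_rng(42)
        if mech == "conjugation":
            p = ConjugationParams(Delta=0.2, gamma_c=0.3, p_ell=0.1, delta=0.5, S=1.2, alpha=0.8)
            f = lambda y: _conjugation_rhs_arr(y, p)
            jac = lambda y: conjugation_jacobian(y, p)
            dim = 3
        else:
            p = TransformationParams(
                Delta=0.2, gamma_t=0.3, p_ell=0.1, delta=0.5, S=1.2,
                alpha=0.8, n_eff=0.7, delta_p=0.2,
            )
            f = lambda y: _transformation_rhs_arr(y, p)
            jac = lambda y: transformation_jacobian(y, p)
            dim = 4
        for _ in range(5):
            y = rng.uniform(0.1, 2.0, size=dim)
            np.testing.assert_allclose(jac(y), _numeric_jacobian(f, y), atol=1e-6)


class TestEquilibriaAndThresholds:
    @pytest.mark.parametrize(
        "S,delta,alpha,rho,C", [(1, 0.1, 1, 10, 0.1), (1, 1, 1, 1, 1)]
    )
    def test_plasmid_free_equilibrium_closed_form(self, S, delta, alpha, rho, C):
        eq = plasmid_free_equilibrium(ConjugationParams(S=S, delta=delta, alpha=alpha))
        assert (eq.rho, eq.C, eq.rho_p) == pytest.approx((rho, C, 0.0))

    def test_plasmid_free_equilibrium_zeroes_rhs(self):
        tp = TransformationParams(S=2.0, delta=0.4, alpha=1.3)
        eq = plasmid_free_equilibrium(tp)
        np.testing.assert_allclose(transformation_rhs(eq, tp), 0.0, atol=1e-14)

    def test_zero_death_rate_rejected(self):
        with pytest.raises(ValueError):
            plasmid_free_equilibrium(ConjugationParams(delta=0.0))

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(Delta=0.0, p_ell=0.0), 0.0),
            (dict(delta=0.1, S=1, Delta=0.5, p_ell=0.0), 0.005),
            (dict(delta=1, S=1, Delta=0.1, p_ell=0.05), 0.145),
        ],
    )
    def test_conjugation_threshold_values(self, kwargs, expected):
        assert conjugation_invasion_threshold(
            ConjugationParams(**kwargs)
        ) == pytest.approx(expected)

    def test_conjugation_threshold_requires_supply(self):
        with pytest.raises(ValueError):
            conjugation_invasion_threshold(ConjugationParams(S=0.0, Delta=0.1))

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(n_eff=0.1, Delta=0.2, p_ell=0.0), NO_INVASION),
            (dict(delta=0.1, S=1, delta_p=0.3, n_eff=0.6, Delta=0.2, p_ell=0.0), 0.015),
            (dict(Delta=0.0, p_ell=0.0, n_eff=0.5), 0.0),
        ],
    )
    def test_transformation_threshold_values(self, kwargs, expected):
        got = transformation_invasion_threshold(TransformationParams(**kwargs))
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        d1=st.floats(0.01, 0.9),
        d2=st.floats(0.01, 0.9),
        p1=st.floats(0.0, 0.9),
        p2=st.floats(0.0, 0.9),
    )
    def test_threshold_increases_with_cost_and_loss(self, d1, d2, p1, p2):
        lo_d, hi_d = sorted((d1, d2))
        lo_p, hi_p = sorted((p1, p2))
        base = dict(delta=0.5, S=1.0)
        t_low = conjugation_invasion_threshold(ConjugationParams(Delta=lo_d, p_ell=lo_p, **base))
        t_hi_cost = conjugation_invasion_threshold(ConjugationParams(Delta=hi_d, p_ell=lo_p, **base))
        t_hi_loss = conjugation_invasion_threshold(ConjugationParams(Delta=lo_d, p_ell=hi_p, **base))
        assert t_hi_cost >= t_low and t_hi_loss >= t_low
        if hi_d > lo_d:
            assert t_hi_cost > t_low
        if hi_p > lo_p:
            assert t_hi_loss > t_low

    def test_threshold_sign_matches_linearization(self):
        """The closed-form invasion thresholds agree with the leading eigenvalue of the
        plasmid-free state across random parameter draws."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            Delta = rng.uniform(0.05, 0.5)
            p_ell = rng.uniform(0.0, 0.2)
            delta = rng.uniform(0.5, 2.0)
            S = rng.uniform(0.5, 2.0)
            alpha = rng.uniform(0.5, 2.0)
            base = ConjugationParams(Delta=Delta, p_ell=p_ell, delta=delta, S=S, alpha=alpha)
            gstar = conjugation_invasion_threshold(base)
            burden = Delta + p_ell * (1 - Delta)
            n_eff = burden + rng.uniform(0.1, 0.5)
            tbase = TransformationParams(
                Delta=Delta, p_ell=p_ell, delta=delta, S=S, alpha=alpha,
                n_eff=n_eff, delta_p=rng.uniform(0.1, 1.0),
            )
            tstar = transformation_invasion_threshold(tbase)
            for mult, expect_unstable in ((1.05, True), (0.95, False)):
                pc = replace(base, gamma_c=mult * gstar)
                eq = classify_stability(
                    find_equilibria(pc)[0].__class__(plasmid_free_equilibrium(pc), "no_plasmid"), pc
                )
                assert (eq.stability == "unstable") is expect_unstable
                pt = replace(tbase, gamma_t=mult * tstar)
                eqt = classify_stability(
                    eq.__class__(plasmid_free_equilibrium(pt), "no_plasmid"), pt
                )
                assert (eqt.stability == "unstable") is expect_unstable

    def test_threshold_sign_matches_invasion_integration(self):
        """A tiny inoculum grows just above gamma_c* and shrinks just below,
        measured by direct RK4 integration for random chemostats."""
        rng = np.random.default_rng(11)
        for _ in range(6):
            base = ConjugationParams(
                Delta=rng.uniform(0.1, 0.5),
                p_ell=rng.uniform(0.0, 0.1),
                delta=rng.uniform(0.8, 1.5),
                S=rng.uniform(0.8, 1.5),
            )
            gstar = conjugation_invasion_threshold(base)
            for mult, grows in ((1.05, True), (0.95, False)):
                p = replace(base, gamma_c=mult * gstar)
                rhs, _, _ = _rhs_and_jac(p)
                y0 = plasmid_free_equilibrium(p).to_array()
                y0[1] = 1e-6
                traj = integrate(rhs, y0, 100.0, step=0.02, record_stride=5000)
                assert bool(traj.final_state[1] > 1e-6) is grows


class TestCopyNumber:
    @pytest.mark.parametrize(
        "n_p,Delta_p,delta,expected",
        [(1, 0.05, 1.0, 1.0), (4, 0.05, 1.0, 0.3), (7, 0.1, 0.0, 0.0)],
    )
    def test_barrier_values(self, n_p, Delta_p, delta, expected):
        assert conjugative_invasion_barrier(n_p, Delta_p, delta) == pytest.approx(expected)

    def test_barrier_rejects_overspent_budget(self):
        with pytest.raises(ValueError):
            conjugative_invasion_barrier(25, 0.05, 1.0)

    def test_transformative_optimum_is_full_budget(self):
        assert optimal_copy_number(CopyNumberParams(Delta_p=0.01), "transformation") == 100

    def test_transformative_optimum_needs_viable_release(self):
        got = optimal_copy_number(CopyNumberParams(Delta_p=0.2, p_v=0.1), "transformation")
        assert math.isinf(got)

    def test_conjugative_optimum_against_grid_search(self):
        for Dp, lo, hi in [(0.05, 5, 5), (0.4, 1, 2)]:
            grid = np.arange(1, int((1 - 1e-9) / Dp) + 1)
            vals = [conjugative_invasion_barrier(int(n), Dp, 1.0) for n in grid]
            brute = int(grid[int(np.argmin(vals))])
            assert lo <= brute <= hi
            assert optimal_copy_number(CopyNumberParams(Delta_p=Dp), "conjugation") == brute

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(Dp=st.floats(0.01, 0.19))
    def test_barrier_has_interior_minimum(self, Dp):
        """Moderate copy number is optimal: the barrier dips strictly below
        both the single-copy and the budget-exhausting ends."""
        n_max = min(50, int((1 - 1e-9) / Dp))
        vals = np.array([conjugative_invasion_barrier(n, Dp, 1.0) for n in range(1, n_max + 1)])
        k = int(np.argmin(vals))
        assert 0 < k < n_max - 1
        assert vals[k] < vals[0] and vals[k] < vals[-1]
        n_cont = continuous_optimal_copy_number(CopyNumberParams(Delta_p=Dp))
        assert abs(n_cont - (k + 1)) <= 1.0


class TestIntegration:
    def test_fixed_point_is_preserved(self, chemostat_conjugation):
        p = replace(chemostat_conjugation, Delta=0.3, gamma_c=0.001)
        rhs, _, _ = _rhs_and_jac(p)
        y0 = plasmid_free_equilibrium(p).to_array()
        traj = integrate(rhs, y0, 50.0, record_stride=100)
        np.testing.assert_allclose(traj.final_state, y0, atol=1e-9)

    def test_rk4_accuracy_on_exponential_decay(self):
        traj = integrate(lambda y: -y, np.array([1.0]), 5.0, step=0.01, record_stride=500)
        assert traj.final_state[0] == pytest.approx(math.exp(-5.0), abs=1e-10)

    def test_large_negative_excursion_raises(self):
        with pytest.raises(RuntimeError, match="step"):
            integrate(lambda y: np.array([-100.0]), np.array([0.1]), 1.0, step=0.5)

    def test_steady_state_detection(self, chemostat_conjugation):
        p = replace(chemostat_conjugation, Delta=0.3, gamma_c=0.001)
        rhs, _, _ = _rhs_and_jac(p)
        y0 = plasmid_free_equilibrium(p).to_array() * 1.3
        y, _, converged = integrate_to_steady_state(rhs, y0, step=0.02, t_max=2000)
        assert converged
        np.testing.assert_allclose(y, plasmid_free_equilibrium(p).to_array(), atol=1e-6)


class TestEquilibriaInventory:
    def test_coexistence_band_has_three_equilibria(self, chemostat_conjugation):
        p = replace(chemostat_conjugation, Delta=0.5, gamma_c=0.0075)
        eqs = find_equilibria(p)
        kinds = {e.kind for e in eqs}
        assert kinds == {"no_plasmid", "plasmid_only", "coexistence"}
        rhs, _, _ = _rhs_and_jac(p)
        for e in eqs:
            assert np.max(np.abs(rhs(e.state.to_array()))) < 1e-10
        stable = {e.kind for e in eqs if e.stability == "stable"}
        assert stable == {"coexistence"}

    def test_nutrient_balance_at_steady_states(self, chemostat_conjugation):
        p = replace(chemostat_conjugation, Delta=0.5, gamma_c=0.0075)
        for e in find_equilibria(p):
            s = e.state
            supply = p.alpha * s.C * s.rho + (1 - p.Delta) * p.alpha * s.C * s.rho_p
            assert supply == pytest.approx(p.S, abs=1e-8)

    def test_no_transfer_means_no_coexistence(self, chemostat_conjugation):
        p = replace(chemostat_conjugation, Delta=0.3, gamma_c=0.0)
        kinds = [e.kind for e in find_equilibria(p)]
        assert "no_plasmid" in kinds and "coexistence" not in kinds

    def test_finite_loss_plasmid_only_branch_keeps_free_cells(self):
        p = ConjugationParams(Delta=0.3, delta=0.1, S=1, gamma_c=0.02, p_ell=0.1)
        eqs = find_equilibria(p)
        po = [e for e in eqs if e.kind == "plasmid_only"]
        assert po and po[0].state.rho > 0
        kinds = [e.kind for e in eqs]
        assert kinds.count("coexistence") <= 1  # branch not double-reported

    def test_bistable_point_has_two_stable_boundary_states(self):
        tp = TransformationParams(
            Delta=0.647, gamma_t=0.569, delta=0.1, S=1, n_eff=0.6, delta_p=0.3
        )
        verdict = {e.kind: e.stability for e in find_equilibria(tp)}
        assert verdict["no_plasmid"] == "stable"
        assert verdict["plasmid_only"] == "stable"


class TestPhaseDiagram:
    def test_small_conjugation_grid_labels(self, chemostat_conjugation):
        deltas = np.linspace(0.1, 0.9, 8)
        gammas = np.geomspace(1e-4, 0.5, 8)
        diag = phase_diagram(deltas, gammas, "conjugation", chemostat_conjugation)
        assert diag.labels.shape == (8, 8)
        allowed = {"no_plasmid", "coexistence", "plasmid_only", "bistable"}
        assert set(diag.labels.ravel()) <= allowed
        assert "bistable" not in set(diag.labels.ravel())
        order = {"no_plasmid": 0, "coexistence": 1, "plasmid_only": 2}
        for row in diag.labels:
            idx = [order[v] for v in row]
            assert idx == sorted(idx)

    def test_empty_axis_rejected(self, chemostat_conjugation):
        with pytest.raises(ValueError):
            phase_diagram([], [0.1], "conjugation", chemostat_conjugation)

    def test_classification_matches_long_time_integration(self):
        """Basin membership: trajectories from a mixed inoculum settle on a
        stable equilibrium consistent with the grid label."""
        base = ConjugationParams(delta=1.0, S=1.0, alpha=1.0, p_ell=0.0)
        for D in (0.2, 0.5, 0.8):
            for mult in (0.5, 1.5, 3.0):
                p = replace(base, Delta=D, gamma_c=mult * D)
                stable = [e for e in find_equilibria(p) if e.stability == "stable"]
                rhs, _, _ = _rhs_and_jac(p)
                y, _, conv = integrate_to_steady_state(
                    rhs, np.array([1.0, 1e-3, 1.0]), step=0.02, t_max=3000
                )
                assert conv
                dist = min(np.max(np.abs(e.state.to_array() - y)) for e in stable)
                assert dist < 1e-5
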