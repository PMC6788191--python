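"""Replicator flows, interior equilibrium and trajectory integration."""

import numpy as np
import pytest

from precautiongame import (
    CORNERS,
    DegenerateEquilibriumError,
    GameParams,
    ParameterError,
    StateProfile,
    build_payoff_matrix,
    expected_gains,
    generic_bimatrix_flow,
    integrate,
    interior_equilibrium,
    rest_points,
    school_flow,
    student_flow,
)

from conftest import draw_params, draw_state, make_params


class TestExpectedGains:
    def test_hand_evaluated_school_gains(self):
        g = expected_gains(make_params(cc=10, cs=6, p=5, a=1.0, b=0.5), (0.5, 1.0))
        assert g.ea == -10.0
        assert g.en == -8.0

    def test_careless_students_leave_school_with_loss_share(self, rng):
        for _ in range(50):
            params = draw_params(rng)
            g = expected_gains(params, (rng.uniform(), 0.0))
            assert g.en == pytest.approx(-params.a * params.p, rel=1e-12)

    def test_cautious_school_forces_full_loss_on_careless_students(self, rng):
        for _ in range(50):
            params = draw_params(rng)
            g = expected_gains(params, (1.0, rng.uniform()))
            assert g.sn == pytest.approx(-params.p, rel=1e-12)

    def test_population_average_identities(self, rng):
        for _ in range(200):
            params, (alpha, beta) = draw_params(rng), draw_state(rng)
            g = expected_gains(params, (alpha, beta))
            assert g.ec == pytest.approx(alpha * g.ea + (1 - alpha) * g.en, rel=1e-12, abs=1e-12)
            assert g.sc == pytest.approx(beta * g.sa + (1 - beta) * g.sn, rel=1e-12, abs=1e-12)


class TestClosedFormFlows:
    def test_hand_evaluated_school_flow(self):
        params = make_params(cc=10, cs=6, p=5, a=1.0, b=0.5)
        assert school_flow(params, (0.5, 1.0)) == pytest.approx(-0.5)

    def test_hand_evaluated_student_flow(self):
        params = make_params(cc=8, cs=4, p=12, a=0.5, b=0.5)
        assert student_flow(params, (0.0, 0.5)) == pytest.approx(1.0)

    def test_flows_vanish_on_all_corners(self, rng):
        for _ in range(100):
            params = draw_params(rng)
            for corner in CORNERS:
                assert school_flow(params, corner) == 0.0
                assert student_flow(params, corner) == 0.0

    def test_flow_equals_gain_advantage_form(self, rng):
        """The flow is frequency x (1 - frequency) x payoff advantage of
        caution — the defining identity of the replicator equation."""
        for _ in range(1000):
            params, (alpha, beta) = draw_params(rng), draw_state(rng)
            g = expected_gains(params, (alpha, beta))
            assert school_flow(params, (alpha, beta)) == pytest.approx(
                alpha * (1 - alpha) * (g.ea - g.en), rel=1e-12, abs=1e-12
            )
            assert student_flow(params, (alpha, beta)) == pytest.approx(
                beta * (1 - beta) * (g.sa - g.sn), rel=1e-12, abs=1e-12
            )

    def test_time_rescaling_of_costs_rescales_flows(self, rng):
        """Scaling all monetary quantities by k > 0 multiplies the vector
        field by k: rest points and convergence targets are unchanged, only
        the clock speeds up."""
        for _ in range(200):
            params, state = draw_params(rng), draw_state(rng)
            k = float(rng.uniform(0.1, 10.0))
            scaled = make_params(cc=k * params.cc, cs=k * params.cs, p=k * params.p,
                                 a=params.a, b=params.b)
            assert school_flow(scaled, state) == pytest.approx(
                k * school_flow(params, state), rel=1e-9, abs=1e-12)
            assert student_flow(scaled, state) == pytest.approx(
                k * student_flow(params, state), rel=1e-9, abs=1e-12)
        base = make_params(cc=10, cs=6, p=5, a=1.0, b=0.5)
        scaled = make_params(cc=30, cs=18, p=15, a=1.0, b=0.5)
        assert rest_points(base) == rest_points(scaled)
        assert integrate(base, (0.5, 0.5)).verdict == integrate(scaled, (0.5, 0.5)).verdict


class TestBimatrixOracle:
    def test_closed_forms_match_generic_replicator(self, rng):
        """Central oracle: the closed-form flows must equal the generic
        two-population replicator flow built directly from the payoff cells."""
        for _ in range(1000):
            params, state = draw_params(rng), draw_state(rng)
            matrix = build_payoff_matrix(params)
            dalpha, dbeta = generic_bimatrix_flow(matrix, state)
            assert abs(dalpha - school_flow(params, state)) < 1e-12
            assert abs(dbeta - student_flow(params, state)) < 1e-12

    def test_identical_cells_give_zero_flow(self):
        from precautiongame import PayoffBimatrix

        matrix = PayoffBimatrix(student=np.full((2, 2), -3.0), school=np.full((2, 2), -7.0))
        assert generic_bimatrix_flow(matrix, (0.3, 0.8)) == (0.0, 0.0)

    def test_strict_override_flow_differs_from_closed_forms(self):
        params = GameParams.strict(cc=10, cs=6, p=5)
        matrix = build_payoff_matrix(params)
        state = (0.4, 0.6)
        dalpha, dbeta = generic_bimatrix_flow(matrix, state)
        assert dalpha != pytest.approx(school_flow(params, state))
        assert dbeta != pytest.approx(student_flow(params, state))


class TestInteriorEquilibrium:
    def test_hand_evaluated_interior_point(self):
        eq = interior_equilibrium(make_params(cc=10, cs=6, p=5, a=0.0, b=1.0))
        assert eq.alpha == pytest.approx(5 / 6, rel=1e-12)
        assert eq.beta == pytest.approx(10 / 11, rel=1e-12)
        assert eq.valid

    def test_two_printed_forms_of_alpha_agree(self, rng):
        """alpha* = ((1-a)p - (1-b)cs)/(b cs - a p) equals
        1 - (cs - p)/(b cs - a p) identically."""
        checked = 0
        while checked < 1000:
            params = draw_params(rng)
            denom = params.b * params.cs - params.a * params.p
            if denom == 0.0 or (1 - params.a) * params.p + params.b * params.cs == 0.0:
                continue
            eq = interior_equilibrium(params)
            alt = 1 - (params.cs - params.p) / denom
            assert abs(eq.alpha - alt) < 1e-12 * max(1.0, abs(alt))
            checked += 1

    def test_school_gain_boundary_puts_beta_star_at_zero(self):
        eq = interior_equilibrium(make_params(cc=2.5, cs=6, p=5, a=0.5, b=0.5))
        assert eq.beta == 0.0
        assert not eq.valid

    def test_degenerate_denominators_are_named(self):
        with pytest.raises(DegenerateEquilibriumError, match="b\\*cs - a\\*p"):
            interior_equilibrium(make_params(cc=10, cs=5, p=5, a=0.5, b=0.5))
        with pytest.raises(DegenerateEquilibriumError, match="\\(1-a\\)\\*p \\+ b\\*cs"):
            interior_equilibrium(make_params(cc=10, cs=5, p=5, a=1.0, b=0.0))

    def test_rest_point_enumeration(self):
        pts = rest_points(make_params(cc=10, cs=6, p=5, a=0.0, b=1.0))
        assert len(pts) == 5
        assert set(pts[:4]) == set(CORNERS)
        pts_no_interior = rest_points(make_params(cc=10, cs=6, p=5, a=1.0, b=0.5))
        assert len(pts_no_interior) == 4


class TestIntegration:
    def test_corner_starts_are_constant(self, rng):
        for corner in CORNERS:
            traj = integrate(draw_params(rng), corner, t_max=50.0)
            assert np.allclose(traj.alpha, corner[0])
            assert np.allclose(traj.beta, corner[1])

    def test_high_cost_case_converges_to_mutual_carelessness(self):
        traj = integrate(make_params(cc=10, cs=6, p=5, a=1.0, b=0.5), (0.5, 0.5))
        assert traj.verdict == "corner (0,0)"

    def test_high_loss_case_converges_to_mutual_caution(self):
        traj = integrate(make_params(cc=8, cs=10, p=12, a=0.5, b=0.9), (0.5, 0.5))
        assert traj.verdict == "corner (1,1)"

    @pytest.mark.parametrize(
        "kwargs, start, expected",
        [
            (dict(cc=10, cs=6, p=5, a=1.0, b=0.5), (0.5, 0.5), (0.0, 0.0)),
            (dict(cc=8, cs=10, p=12, a=0.5, b=0.9), (0.5, 0.5), (1.0, 1.0)),
        ],
    )
    def test_against_fixed_step_euler(self, kwargs, start, expected):
        """Independent oracle: plain forward Euler at dt = 1e-3 must reach
        the same corner as the adaptive integrator."""
        params = make_params(**kwargs)
        state = np.array(start, dtype=float)
        for _ in range(200_000):  # t = 200
            dalpha = school_flow(params, state)
            dbeta = student_flow(params, state)
            state = np.clip(state + 1e-3 * np.array([dalpha, dbeta]), 0.0, 1.0)
        assert np.allclose(state, expected, atol=1e-6)
        traj = integrate(params, start)
        assert traj.verdict == f"corner ({expected[0]:g},{expected[1]:g})"

    def test_times_strictly_increasing_and_states_bounded(self, rng):
        for _ in range(5):
            traj = integrate(draw_params(rng), draw_state(rng))
            assert np.all(np.diff(traj.t) > 0)
            assert traj.alpha.min() >= 0.0 and traj.alpha.max() <= 1.0
            assert traj.beta.min() >= 0.0 and traj.beta.max() <= 1.0

    def test_forward_invariance_of_unit_square(self, rng):
        worst = 0.0
        for _ in range(25):
            traj = integrate(draw_params(rng), draw_state(rng))
            worst = max(worst, traj.max_boundary_violation)
        assert worst <= 1e-9

    def test_invalid_inputs_rejected(self):
        params = make_params(cc=10, cs=6, p=5, a=0.5, b=0.5)
        with pytest.raises(ParameterError):
            integrate(params, (1.5, 0.5))
        with pytest.raises(ParameterError):
            integrate(params, (0.5, 0.5), t_max=-1.0)


def test_state_profile_bounds():
    with pytest.raises(ParameterError):
        StateProfile(alpha=1.2, beta=0.5)
    assert StateProfile(alpha=0.25, beta=0.75).as_tuple() == (0.25, 0.75)
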