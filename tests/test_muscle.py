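"""Hill-model unit tests: force curves, dynamics laws and their contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from torquesyn import muscle as mm
from torquesyn.muscle import MuscleParams


class TestTendon:
    def test_slack_tendon_carries_no_force(self, default_params):
        assert mm.tendon_force(-0.01, default_params) == 0.0
        assert mm.tendon_force(0.0, default_params) == 0.0

    def test_force_equals_fmax_at_reference_strain(self):
        p = MuscleParams(f_max=1000.0, eps_t_max=0.04)
        assert mm.tendon_force(0.04, p) == pytest.approx(1000.0, rel=1e-6)

    def test_midtoe_regression_value(self):
        # frozen from symbolic evaluation of the exponential-toe curve:
        # c*(exp(k_toe*eps/eps_toe)-1)*f_max with eps=0.02, eps_toe=0.02436
        p = MuscleParams(f_max=1000.0, eps_t_max=0.04)
        eps_toe = 0.609 * 0.04
        c = p.f_toe / (np.exp(p.k_toe) - 1.0)
        expected = 1000.0 * c * np.expm1(p.k_toe * 0.02 / eps_toe)
        assert mm.tendon_force(0.02, p) == pytest.approx(expected, rel=1e-12)
        assert mm.tendon_force(0.02, p) == pytest.approx(185.711459, rel=1e-6)

    def test_continuous_and_nondecreasing(self, default_params):
        eps = np.linspace(-0.02, 0.10, 4001)
        f = mm.tendon_force_norm(eps, default_params)
        assert np.all(np.diff(f) >= 0)
        assert np.max(np.abs(np.diff(f))) < 2e-3  # no jumps on a dense grid

    def test_stiffness_matches_slope(self, default_params):
        eps = np.linspace(0.001, 0.08, 50)
        h = 1e-8
        fd = (mm.tendon_force_norm(eps + h, default_params)
              - mm.tendon_force_norm(eps - h, default_params)) / (2 * h)
        np.testing.assert_allclose(
            mm.tendon_stiffness_norm(eps, default_params), fd, rtol=1e-4)


class TestActivation:
    def test_steady_state_rate_is_zero(self, default_params):
        assert mm.activation_derivative(0.3, 0.3, default_params) == 0.0

    def test_sign_follows_drive(self, default_params):
        assert mm.activation_derivative(0.1, 0.9, default_params) > 0
        assert mm.activation_derivative(0.9, 0.1, default_params) < 0

    def test_deactivation_rate_regression(self):
        # far below steady state the smoothed two-regime law reduces to
        # (u - a)/tau_deact
        p = MuscleParams(tau_deact=0.05)
        rate = mm.activation_derivative(0.5, 0.2, p)
        assert rate == pytest.approx(-0.3 / 0.05, rel=1e-8)

    def test_out_of_bounds_raises_with_value(self, default_params):
        with pytest.raises(ValueError, match="0.001"):
            mm.activation_derivative(0.001, 0.5, default_params)
        with pytest.raises(ValueError, match="1.5"):
            mm.activation_derivative(0.5, 1.5, default_params)

    @pytest.mark.parametrize("u", [0.05, 0.35, 0.9])
    def test_converges_to_constant_drive(self, default_params, u):
        p = default_params
        T = 10 * max(p.tau_act, p.tau_deact)
        sol = solve_ivp(lambda t, a: mm.activation_rate(a, u, p), (0, T),
                        [0.5], rtol=1e-9, atol=1e-12)
        assert abs(sol.y[0, -1] - u) < 1e-4

    def test_partials_match_finite_differences(self, default_params):
        a, u = 0.4, 0.55
        da, du = mm.activation_rate_partials(a, u, default_params)
        h = 1e-7
        fd_a = (mm.activation_rate(a + h, u, default_params)
                - mm.activation_rate(a - h, u, default_params)) / (2 * h)
        fd_u = (mm.activation_rate(a, u + h, default_params)
                - mm.activation_rate(a, u - h, default_params)) / (2 * h)
        assert da == pytest.approx(fd_a, rel=1e-6)
        assert du == pytest.approx(fd_u, rel=1e-6)


class TestFiberEquilibriumForce:
    def test_definitional_composition(self):
        p = MuscleParams(alpha_opt=0.0)
        L = p.l_opt + p.l_slack * (1 + p.eps_t_max)
        assert mm.fiber_equilibrium_force(p.l_opt, L, p) == \
            pytest.approx(p.f_max, rel=1e-9)

    def test_zero_strain_zero_force(self, default_params):
        p = default_params
        assert mm.fiber_equilibrium_force(p.l_opt, p.l_opt + p.l_slack, p) == \
            pytest.approx(0.0, abs=1e-9)

    def test_pennated_geometry_hand_computed(self):
        p = MuscleParams(alpha_opt=0.1)
        l = 0.9 * p.l_opt
        L = 0.32
        # independent geometry: constant-thickness pennation
        sin_a = p.l_opt * np.sin(0.1) / l
        lt = L - l * np.sqrt(1 - sin_a ** 2)
        eps = (lt - p.l_slack) / p.l_slack
        expected = mm.tendon_force(eps, p)
        assert mm.fiber_equilibrium_force(l, L, p) == \
            pytest.approx(float(expected), rel=1e-12)

    def test_impossible_geometry_raises(self, default_params):
        p = default_params
        with pytest.raises(ValueError, match="tendon"):
            mm.fiber_equilibrium_force(1.1 * p.l_opt, 0.5 * p.l_opt, p)


class TestFiberVelocity:
    def test_isometric_equilibrium_velocity_zero(self, default_params):
        p = default_params
        L = p.l_opt + p.l_slack * 1.02
        leq = mm.equilibrium_fiber_length(0.7, L, p)
        assert abs(mm.fiber_velocity(0.7, leq, L, p)) < 1e-10

    def test_low_tendon_force_means_shortening(self, default_params):
        p = default_params
        v = mm.fiber_velocity(0.9, p.l_opt, p.l_opt + p.l_slack * 1.001, p)
        assert v < 0

    def test_inversion_consistent_with_forward_hyperbola(self):
        """The returned velocity satisfies the forward force-velocity law.

        Independent oracle: bisection on the forward (force-from-velocity)
        hyperbola of the same curve family.
        """
        p = MuscleParams()
        a, l = 0.6, 0.98 * p.l_opt
        L = p.l_opt * 0.98 + p.l_slack * 1.015

        ln = l / p.l_opt
        fl = float(mm.active_force_length(ln, p))
        fpe = float(mm.passive_force_length(ln, p))
        ft = float(mm.fiber_equilibrium_force(l, L, p)) / p.f_max
        cosa = float(mm.cos_pennation(l, p))
        fm = ft / cosa - fpe
        fa = a * fl

        def forward_force(v_norm):
            # concentric branch of the hyperbolic relation
            vs = (0.25 + 0.75 * a) * p.v_max
            return fa * (1 + v_norm / vs) / (1 - v_norm / (vs * p.a_f))

        assert fm < fa  # concentric regime for this state
        v_oracle = bisect(lambda v: forward_force(v) - fm, -p.v_max * 0.99,
                          0.0, xtol=1e-12)
        v = mm.fiber_velocity(a, l, L, p) / p.l_opt
        assert v == pytest.approx(v_oracle, abs=1e-8)

    def test_velocity_bounded(self, default_params):
        p = default_params
        rng = np.random.default_rng(3)
        for _ in range(200):
            a = rng.uniform(0.01, 1)
            l = rng.uniform(0.3, 1.7) * p.l_opt
            L = rng.uniform(0.9, 1.1) * (p.l_opt + p.l_slack)
            v = mm.fiber_velocity(a, l, L, p)
            assert np.isfinite(v)
            assert abs(v) <= 1.6 * p.v_max * p.l_opt + 1e-12

    def test_forward_integration_reaches_fixed_point(self, default_params):
        """Constant drive and geometry relax to a state with zero velocity."""
        p = default_params
        u = 0.5
        L = p.l_opt + p.l_slack * 1.01

        def rhs(t, y):
            return [mm.activation_rate(y[0], u, p),
                    mm.fiber_velocity(y[0], np.clip(y[1], 0.3 * p.l_opt,
                                                    1.7 * p.l_opt), L, p)]

        sol = solve_ivp(rhs, (0, 2.0), [0.2, p.l_opt], rtol=1e-9, atol=1e-12)
        a_end, l_end = sol.y[:, -1]
        assert a_end == pytest.approx(u, abs=1e-6)
        assert abs(mm.fiber_velocity(a_end, l_end, L, p)) < 1e-6


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=st.floats(0.01, 1.0),
    ln=st.floats(0.3, 1.7),
    lmt_scale=st.floats(0.95, 1.08),
    alpha=st.floats(0.0, 0.4),
)
def test_all_outputs_finite_over_state_space(a, ln, lmt_scale, alpha):
    """Dynamics and force evaluations stay finite over admissible states."""
    p = MuscleParams(alpha_opt=alpha)
    l = ln * p.l_opt
    L = lmt_scale * (p.l_opt * np.cos(alpha) + p.l_slack)
    assert np.isfinite(mm.fiber_equilibrium_force(l, L, p))
    assert np.isfinite(mm.fiber_velocity(a, l, L, p))
    assert np.isfinite(mm.activation_rate(a, 0.5, p))


class TestParams:
    @pytest.mark.parametrize("field,value", [
        ("f_max", -1.0), ("l_opt", 0.0), ("eps_t_max", 1.5),
        ("alpha_opt", 2.0), ("tau_act", 0.0), ("v_max", -3.0),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            MuscleParams(**{field: value})

    def test_muscle_state_bounds(self):
        with pytest.raises(ValueError):
            mm.MuscleState(a=0.0, l=0.1)
        with pytest.raises(ValueError):
            mm.MuscleState(a=0.5, l=-0.1)

    def test_params_csv_round_trip(self, tmp_path, small_plant):
        path = tmp_path / "muscles.csv"
        mm.save_muscle_params(small_plant.muscles, path)
        back = mm.load_muscle_params(path)
        assert back.names == small_plant.muscles.names
        np.testing.assert_allclose(back.f_max, small_plant.muscles.f_max)
        np.testing.assert_allclose(back.l_slack, small_plant.muscles.l_slack)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,f_max,bogus\nm0,100,1\n")
        with pytest.raises(ValueError, match="bogus"):
            mm.load_muscle_params(path)
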