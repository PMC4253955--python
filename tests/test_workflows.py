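"""NRMSE metric and limits, selection rules and the dimensionality check."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torquesyn import (NrmseLimits, choose_effort_weight, delta_threshold,
                       moment_dimensionality, nrmse, nrmse_lower_limit,
                       nrmse_upper_limit, select_num_synergies)
from tests.conftest import make_trial


class TestNrmse:
    def test_zero_for_identical_moments(self):
        M = {"c": np.random.default_rng(0).normal(size=(10, 3))}
        assert nrmse(M, M) == 0.0

    def test_uniform_error_closed_form(self):
        """Uniform error e over a range D gives exactly 100*e/D percent."""
        t = np.linspace(-10, 10, 50)
        M_star = {"c": t[:, None]}          # range exactly 20
        M = {"c": t[:, None] + 1.0}
        assert nrmse(M, M_star) == pytest.approx(100.0 * 1.0 / 20.0)

    def test_node_order_invariance(self):
        rng = np.random.default_rng(1)
        M_star = rng.normal(size=(30, 2)) * 10
        M = M_star + rng.normal(size=(30, 2))
        perm = rng.permutation(30)
        assert nrmse({"c": M}, {"c": M_star}) == \
            pytest.approx(nrmse({"c": M[perm]}, {"c": M_star[perm]}))

    def test_constant_moments_rejected(self):
        with pytest.raises(ValueError, match="range"):
            nrmse({"c": np.ones((5, 2))}, {"c": np.ones((5, 2))})


class TestLimits:
    def test_upper_is_five_percent_for_homogeneous_ranges(self):
        """When every DOF/condition spans the global range the 5%-of-range
        recipe reduces to exactly 5%."""
        t = np.linspace(0, 1, 40)
        tr = make_trial(P=40)
        tr.moments = np.stack([20 * np.sin(2 * np.pi * t),
                               20 * np.cos(2 * np.pi * t)], axis=1)
        assert nrmse_upper_limit([tr]) == pytest.approx(5.0, rel=1e-3)

    def test_upper_two_dof_closed_form(self):
        """Ranges {D, D/2} with equal node counts give
        5% * sqrt((1 + 1/4)/2) = 3.953%."""
        P = 64
        t = np.linspace(0, 1, P)
        tr = make_trial(P=P)
        tr.moments = np.stack([10 * np.sin(2 * np.pi * t),
                               5 * np.sin(2 * np.pi * t)], axis=1)
        expected = 5.0 * np.sqrt((1 + 0.25) / 2)
        assert nrmse_upper_limit([tr]) == pytest.approx(expected, rel=1e-3)

    def test_lower_equals_inverse_range(self):
        tr = make_trial(P=30)
        rng_ = tr.moments.max() - tr.moments.min()
        assert nrmse_lower_limit([tr]) == pytest.approx(100.0 / rng_)

    @given(scale=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_lower_closed_form_property(self, scale):
        tr = make_trial(P=25, seed=2)
        tr = tr.resample(tr.time)  # fresh copy
        tr.moments = tr.moments * scale
        rng_ = tr.moments.max() - tr.moments.min()
        assert nrmse_lower_limit([tr]) == pytest.approx(100.0 / rng_,
                                                        rel=1e-9)

    def test_limits_independent_of_time_rescaling(self):
        tr = make_trial(P=40, duration=1.0)
        tr2 = make_trial(P=40, duration=2.5)
        tr2.moments = tr.moments.copy()
        assert nrmse_upper_limit([tr]) == pytest.approx(
            nrmse_upper_limit([tr2]))
        assert nrmse_lower_limit([tr]) == pytest.approx(
            nrmse_lower_limit([tr2]))

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            NrmseLimits(upper=0.5, lower=1.0)


class TestSelection:
    LIMITS = NrmseLimits(upper=2.38, lower=0.51)

    def test_highest_admissible_count_wins(self):
        assert select_num_synergies({3: 3.1, 4: 1.43, 5: 0.45},
                                    self.LIMITS) == 4
        assert select_num_synergies({3: 3.1, 4: 1.43, 5: 0.60},
                                    self.LIMITS) == 5

    def test_no_admissible_count_raises(self):
        with pytest.raises(ValueError, match="admissible"):
            select_num_synergies({3: 5.0}, self.LIMITS)

    def test_key_order_invariance(self):
        table = {5: 0.60, 3: 3.1, 4: 1.43}
        assert select_num_synergies(table, self.LIMITS) == \
            select_num_synergies(dict(sorted(table.items())), self.LIMITS)


class TestDelta:
    @staticmethod
    def _result(a_values):
        return SimpleNamespace(states={"c": {"a": np.asarray(a_values)}})

    def test_zero_at_lower_bound(self):
        assert delta_threshold(self._result(np.full((7, 3), 0.01))) == 0.0

    def test_single_active_muscle_value(self):
        a = np.full((1, 4), 0.01)
        a[0, 2] = 0.5
        assert delta_threshold(self._result(a)) == \
            pytest.approx(0.25 - 0.49 ** 2)

    @given(a=st.floats(0.02, 1.0), bump=st.floats(1e-4, 0.2))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_activation(self, a, bump):
        lo = delta_threshold(self._result(np.array([[a]])))
        hi = delta_threshold(self._result(np.array([[min(a + bump, 1.2)]])))
        assert hi >= lo - 1e-12


class TestEffortWeightRule:
    def test_rule_fires_at_small_improvement(self):
        costs = {0.0: 10.0, 100.0: 6.0, 200.0: 5.95}
        deltas = {0.0: 0.5, 100.0: 0.2, 200.0: 0.2}
        K, exhausted = choose_effort_weight(costs, deltas,
                                            [0.0, 100.0, 200.0])
        assert K == 100.0 and not exhausted

    def test_rule_never_fires_exhausts_grid(self):
        costs = {0.0: 10.0, 100.0: 5.0, 200.0: 1.0}
        deltas = {k: 0.1 for k in costs}
        K, exhausted = choose_effort_weight(costs, deltas,
                                            [0.0, 100.0, 200.0])
        assert K == 200.0 and exhausted


class TestFixedWeightValidation:
    def test_weightings_pass_through_unchanged(self, small_problem):
        """The frozen-weightings solve returns exactly the supplied W and
        tracks a condition that the weightings can explain."""
        from torquesyn import validate_fixed_weights
        plant = small_problem["plant"]
        trials = small_problem["trials"]
        W = small_problem["truth"].structure.W
        res = validate_fixed_weights(trials, W, plant.muscles, seed=0,
                                     n_starts=2,
                                     options={"max_nfev": 120})
        np.testing.assert_array_equal(res.structure.W, W)
        assert res.nrmse < 10.0


class TestDimensionality:
    def test_rank_deficient_data(self):
        # two equal-variance latent directions in a 5-D moment space
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        latent = np.stack([np.sin(t), np.cos(t)], axis=1)
        basis, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(5, 2)))
        tr = make_trial(P=100, NJ=5)
        tr.moments = latent @ basis.T
        assert moment_dimensionality([tr], 0.9) == 2

    def test_isotropic_noise_needs_all_components(self):
        rng = np.random.default_rng(1)
        tr = make_trial(P=4000, NJ=5)
        tr.moments = rng.normal(size=(4000, 5))
        assert moment_dimensionality([tr], 0.9) == 5

    def test_threshold_one_gives_full_rank(self):
        rng = np.random.default_rng(2)
        tr = make_trial(P=50, NJ=3)
        tr.moments = rng.normal(size=(50, 3))
        assert moment_dimensionality([tr], 1.0) == 3

    def test_too_few_samples_rejected(self):
        tr = make_trial(P=3, NJ=5)
        with pytest.raises(ValueError, match="samples"):
            moment_dimensionality([tr], 0.9)

    def test_spectrum_sums_to_one(self):
        tr = make_trial(P=60, NJ=3, seed=9)
        _, spec = moment_dimensionality([tr], 0.9, return_spectrum=True)
        assert np.sum(spec) == pytest.approx(1.0)
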