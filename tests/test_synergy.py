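"""Synergy combination, factorization and initial-guess generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torquesyn import CollocationGrid, combine, make_initial_guess, nnmf
from torquesyn.synergy import (SynergyStructure, excitation_patterns,
                               static_optimization_patterns)


class TestCombine:
    def test_zero_controls_give_zero_excitation(self):
        W = np.random.default_rng(0).uniform(0, 1, (5, 2))
        np.testing.assert_array_equal(combine(W, np.zeros(2)), np.zeros(5))

    def test_hand_computed_product(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        u = combine(W, np.array([0.4, 0.2]))
        np.testing.assert_allclose(u, [0.4, 0.2, 0.3])

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_exchange_invariance(self, c):
        rng = np.random.default_rng(1)
        W = rng.uniform(0, 1, (6, 3))
        h = rng.uniform(0, 1, 3)
        np.testing.assert_allclose(combine(W * c, h / c), combine(W, h),
                                   rtol=1e-12)

    def test_shape_and_sign_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine(np.ones((3, 2)), np.ones(3))
        with pytest.raises(ValueError, match="non-negative"):
            combine(-np.ones((3, 2)), np.ones(2))


class TestNnmf:
    def test_rank_one_exact(self):
        w = np.array([1.0, 2.0, 0.5])
        h = np.array([0.3, 0.6, 0.9, 1.2])
        W, H, err = nnmf(np.outer(w, h), 1, seed=0)
        assert err < 1e-6

    def test_rank_two_round_trip(self):
        rng = np.random.default_rng(5)
        U = rng.uniform(0, 1, (6, 2)) @ rng.uniform(0, 1, (2, 30))
        _, _, err = nnmf(U, 2, seed=3)
        assert err < 1e-4

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        U = rng.uniform(0, 1, (5, 12))
        W1, H1, _ = nnmf(U, 3, seed=42)
        W2, H2, _ = nnmf(U, 3, seed=42)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nnmf(np.zeros((3, 4)), 1, seed=0)

    def test_error_nonincreasing_in_components(self):
        rng = np.random.default_rng(9)
        U = rng.uniform(0, 1, (8, 40))
        errs = [nnmf(U, n, seed=0)[2] for n in (1, 2, 3, 4)]
        assert all(e2 <= e1 + 1e-6 for e1, e2 in zip(errs, errs[1:]))


class TestStructure:
    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            SynergyStructure(-np.ones((3, 2)), {"c": np.ones((2, 5))})
        with pytest.raises(ValueError):
            SynergyStructure(np.ones((3, 2)), {"c": -np.ones((2, 5))})

    def test_normalized_preserves_excitations(self):
        rng = np.random.default_rng(2)
        s = SynergyStructure(rng.uniform(0, 1, (4, 2)),
                             {"c": rng.uniform(0, 1, (2, 9))})
        n = s.normalized()
        np.testing.assert_allclose(n.excitations("c"), s.excitations("c"),
                                   rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(n.W, axis=0), 1.0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        s = SynergyStructure(rng.uniform(0, 1, (4, 2)),
                             {"a": rng.uniform(0, 1, (2, 7)),
                              "b": rng.uniform(0, 1, (2, 9))})
        s.save(tmp_path)
        back = SynergyStructure.load(tmp_path)
        np.testing.assert_allclose(back.W, s.W)
        for c in ("a", "b"):
            np.testing.assert_allclose(back.H[c], s.H[c])


class TestInitialGuess:
    def test_constant_pattern_reconstructs_level(self, small_problem):
        plant = small_problem["plant"]
        trials = small_problem["trials"]
        guess = make_initial_guess("constant", trials, 2, seed=0,
                                   muscles=plant.muscles, level=0.2)
        for c, H in guess["H"].items():
            u = guess["W"] @ H
            np.testing.assert_allclose(u, 0.2, atol=5e-3)

    def test_deterministic_given_seed(self, small_problem):
        plant = small_problem["plant"]
        trials = small_problem["trials"]
        g1 = make_initial_guess("sine-pulses", trials, 2, seed=5,
                                muscles=plant.muscles)
        g2 = make_initial_guess("sine-pulses", trials, 2, seed=5,
                                muscles=plant.muscles)
        np.testing.assert_array_equal(g1["W"], g2["W"])
        for c in g1["H"]:
            np.testing.assert_array_equal(g1["H"][c], g2["H"][c])
            np.testing.assert_array_equal(g1["a"][c], g2["a"][c])
            np.testing.assert_array_equal(g1["l"][c], g2["l"][c])

    @pytest.mark.parametrize("pattern", ["constant", "sine-pulses", "static"])
    def test_guess_states_satisfy_invariants(self, small_problem, pattern):
        plant = small_problem["plant"]
        trials = small_problem["trials"]
        guess = make_initial_guess(pattern, trials, 2, seed=1,
                                   muscles=plant.muscles)
        for c in guess["a"]:
            a, l = guess["a"][c], guess["l"][c]
            assert np.all(a >= 0.005 - 1e-12) and np.all(a <= 1.0 + 1e-12)
            assert np.all(l >= 0.25 * plant.muscles.l_opt - 1e-12)
            assert np.all(l <= 1.78 * plant.muscles.l_opt + 1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            excitation_patterns("fourier", 3, np.linspace(0, 1, 5), 1.0,
                                np.random.default_rng(0))

    def test_static_patterns_track_moment_demand(self, small_problem):
        """Static-optimization excitations reproduce the moments they were
        fit to (through the linearized static model)."""
        plant = small_problem["plant"]
        tr = small_problem["trials"][0]
        U = static_optimization_patterns(tr, tr.time, plant.muscles)
        assert U.shape == (4, len(tr.time))
        assert np.all(U >= 0.02) and np.all(U <= 0.95)
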