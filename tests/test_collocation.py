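"""Transcription structure, cost function, condensed solver contracts."""

import numpy as np
import pytest

from torquesyn import (CollocationGrid, OcpSpec, cost_function, joint_moments,
                       make_initial_guess, nrmse, solve, transcribe)
from torquesyn.plant import Condition, PlantSpec, generate_trials, \
    make_ground_truth, make_plant
from tests.conftest import make_trial


class TestJointMoments:
    def test_zero_forces_zero_moments(self):
        R = np.random.default_rng(0).normal(size=(4, 2))
        np.testing.assert_array_equal(joint_moments(np.zeros(4), R),
                                      np.zeros(2))

    def test_hand_computed_dot_product(self):
        F = np.array([100.0, 50.0])
        R = np.array([[0.05], [-0.02]])
        assert joint_moments(F, R)[0] == pytest.approx(4.0)

    def test_linear_in_single_muscle_force(self):
        rng = np.random.default_rng(1)
        R = rng.normal(size=(3, 2))
        F = np.array([10.0, 0.0, 0.0])
        np.testing.assert_allclose(joint_moments(3 * F, R),
                                   3 * joint_moments(F, R))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            joint_moments(np.ones(3), np.ones((4, 2)))


class TestCostFunction:
    def test_perfect_tracking_zero_cost(self):
        M = np.random.default_rng(0).normal(size=(5, 2))
        a = np.random.default_rng(1).uniform(0.1, 1, (5, 3))
        assert cost_function(M, M, a, K=0.0) == 0.0

    def test_single_node_hand_value(self):
        # one DOF error of 2 N*m plus one muscle at a=0.5 with K=200
        M = np.array([[3.0]])
        M_star = np.array([[1.0]])
        a = np.array([[0.5]])
        assert cost_function(M, M_star, a, K=200.0) == pytest.approx(54.0)

    def test_effort_term_only_adds(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(6, 2))
        M_star = rng.normal(size=(6, 2))
        a = rng.uniform(0.1, 1, (6, 4))
        assert cost_function(M, M_star, a, 0.0) <= \
            cost_function(M, M_star, a, 100.0)


class TestTranscriptionStructure:
    def _tiny_nlp(self, scheme="trapezoidal"):
        tr = make_trial(condition="c", P=2, NJ=1, m=1, duration=0.1)
        from torquesyn.muscle import MuscleParams, MuscleSet
        mset = MuscleSet([MuscleParams(name="m0")])
        spec = OcpSpec(trials=[tr], muscles=mset, n_syn=1, scheme=scheme,
                       n_substeps=1)
        return transcribe(spec)

    def test_decision_vector_and_defect_counts(self):
        """1 muscle, 1 synergy, 2 nodes: W(1) + h(2) + a(2) + l(2) = 7
        variables and 2 defect equations."""
        nlp = self._tiny_nlp()
        assert nlp.n_vars == 7
        assert nlp.n_defects == 2

    def test_pack_unpack_round_trip(self):
        nlp = self._tiny_nlp()
        rng = np.random.default_rng(0)
        W = rng.uniform(0.1, 1, (1, 1))
        H = {"c": rng.uniform(0.1, 1, (1, 2))}
        A = {"c": rng.uniform(0.1, 1, (2, 1))}
        L = {"c": rng.uniform(0.08, 0.12, (2, 1))}
        z = nlp.pack(W, H, A, L)
        W2, H2, A2, L2 = nlp.unpack(z)
        np.testing.assert_allclose(W2, W)
        np.testing.assert_allclose(H2["c"], H["c"])
        np.testing.assert_allclose(A2["c"], A["c"])
        np.testing.assert_allclose(L2["c"], L["c"])

    def test_conditions_share_only_weightings(self, small_plant):
        """Per-condition blocks are disjoint; only W is common."""
        truth = make_ground_truth(small_plant, n_syn=2)
        trials = generate_trials(truth, small_plant)
        two = [trials[0],
               make_trial(condition="other", P=12, NJ=2, m=4, duration=1.0)]
        spec = OcpSpec(trials=two, muscles=small_plant.muscles, n_syn=2)
        nlp = transcribe(spec)
        spans = [nlp._layout[("h", c)] + nlp._layout[("a", c)]
                 + nlp._layout[("l", c)] for c in nlp.conditions]
        s0 = set(range(spans[0][0], spans[0][1])) \
            | set(range(spans[0][2], spans[0][3])) \
            | set(range(spans[0][4], spans[0][5]))
        s1 = set(range(spans[1][0], spans[1][1])) \
            | set(range(spans[1][2], spans[1][3])) \
            | set(range(spans[1][4], spans[1][5]))
        assert not (s0 & s1)
        assert nlp._layout["W"] == (0, nlp.nW)

    def test_invalid_spec_rejected(self, small_plant):
        tr = make_trial(m=4)
        with pytest.raises(ValueError):
            OcpSpec(trials=[tr], muscles=small_plant.muscles, n_syn=2,
                    K=-1.0)
        with pytest.raises(ValueError):
            OcpSpec(trials=[tr], muscles=small_plant.muscles, n_syn=2,
                    scheme="collatz")


class TestGrid:
    def test_from_trials_spans_window(self):
        tr = make_trial(P=33, duration=2.0)
        grid = CollocationGrid.from_trials([tr], n_points=17)
        t = grid.times["c"]
        assert len(t) == 17
        assert t[0] == tr.time[0] and t[-1] == tr.time[-1]
        assert grid.dt("c") == pytest.approx(2.0 / 16)

    def test_target_dt(self):
        tr = make_trial(P=60, duration=3.0)
        grid = CollocationGrid.from_trials([tr], target_dt=0.1)
        assert grid.n_points("c") == 31

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            CollocationGrid({"c": np.array([0.0, 0.1, 0.3])})


@pytest.fixture(scope="module")
def parity_setup(small_plant):
    truth = make_ground_truth(small_plant, n_syn=2)
    trials = generate_trials(truth, small_plant)
    grid = CollocationGrid.from_trials(trials, n_points=10)
    spec = OcpSpec(trials=trials, muscles=small_plant.muscles, n_syn=2,
                   n_substeps=1)
    nlp = transcribe(spec, grid)
    guess = make_initial_guess("sine-pulses", trials, 2, 3,
                               small_plant.muscles, grid=grid)
    x = nlp.reduced_from_guess(guess)
    return nlp, x


class TestKernelParity:
    """The compiled propagation must match the numpy reference."""

    @pytest.mark.parametrize("scheme", ["hermite-simpson", "trapezoidal"])
    def test_states_and_sensitivities_match(self, small_plant, scheme):
        truth = make_ground_truth(small_plant, n_syn=2)
        trials = generate_trials(truth, small_plant)
        grid = CollocationGrid.from_trials(trials, n_points=10)
        spec = OcpSpec(trials=trials, muscles=small_plant.muscles, n_syn=2,
                       scheme=scheme, n_substeps=1)
        nlp = transcribe(spec, grid)
        guess = make_initial_guess("constant", trials, 2, 1,
                                   small_plant.muscles, grid=grid)
        W, H, a0, l0 = nlp.split_reduced(nlp.reduced_from_guess(guess))
        c = nlp.conditions[0]
        cp = nlp.cond[c]
        fast = cp.propagate(W, H[c], a0[c], l0[c], True, nlp.nW)
        ref = cp.propagate_py(W, H[c], a0[c], l0[c], True, nlp.nW)
        np.testing.assert_allclose(fast["a"], ref["a"], atol=1e-10)
        np.testing.assert_allclose(fast["l"], ref["l"], atol=1e-12)
        np.testing.assert_allclose(fast["Sa"], ref["Sa"], atol=1e-8)
        np.testing.assert_allclose(fast["Sl"], ref["Sl"], atol=5e-4)

    def test_jacobian_matches_finite_differences(self, parity_setup):
        nlp, x = parity_setup
        lo, hi = nlp.reduced_bounds()
        x = np.clip(x, lo, hi)
        _, J, _ = nlp._eval(x, need_jac=True)
        rng = np.random.default_rng(0)
        for i in rng.choice(len(x), size=12, replace=False):
            # step large enough to dominate the inner Newton tolerance noise
            h = 1e-5 * max(abs(x[i]), 0.1)
            xp = x.copy(); xp[i] += h
            xm = x.copy(); xm[i] -= h
            fd = (nlp._eval(xp, False)[0] - nlp._eval(xm, False)[0]) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-8)
            # tolerance covers excitation-clamp curvature and inner Newton
            # noise at pulse-like guess states; indexing or chain-rule bugs
            # would show as order-one errors
            assert np.abs(fd - J[:, i]).max() / scale < 1e-2


@pytest.fixture(scope="module")
def problem(small_plant):
    truth = make_ground_truth(small_plant, n_syn=2)
    trials = generate_trials(truth, small_plant)
    grid = CollocationGrid.from_trials(trials, n_points=12)
    spec = OcpSpec(trials=trials, muscles=small_plant.muscles, n_syn=2)
    return transcribe(spec, grid), trials, small_plant


class TestSolve:

    def test_deterministic_given_guess(self, problem):
        nlp, trials, plant = problem
        guess = make_initial_guess("constant", trials, 2, 9, plant.muscles,
                                   grid=nlp.grid)
        r1 = solve(nlp, guess, options={"max_nfev": 40})
        r2 = solve(nlp, guess, options={"max_nfev": 40})
        np.testing.assert_array_equal(r1.structure.W, r2.structure.W)
        assert r1.summary() == r2.summary()

    def test_objective_descends_from_guess(self, problem):
        nlp, trials, plant = problem
        guess = make_initial_guess("sine-pulses", trials, 2, 2, plant.muscles,
                                   grid=nlp.grid)
        res = solve(nlp, guess, options={"max_nfev": 60})
        assert res.objective <= res.guess_objective + 1e-9

    def test_self_consistent_data_is_a_fixed_point(self, problem):
        """Data manufactured from the guess itself solves in few iterations
        with near-zero objective."""
        nlp, trials, plant = problem
        guess = make_initial_guess("constant", trials, 2, 4, plant.muscles,
                                   grid=nlp.grid)
        x0 = nlp.reduced_from_guess(guess)
        _, _, traj = nlp._eval(x0, need_jac=False)
        doctored = []
        for tr in trials:
            t2 = tr.resample(nlp.grid.times[tr.condition])
            t2.moments = traj[tr.condition]["M"]
            doctored.append(t2)
        spec2 = OcpSpec(trials=doctored, muscles=plant.muscles, n_syn=2)
        nlp2 = transcribe(spec2, nlp.grid)
        res = solve(nlp2, guess, options={"max_nfev": 25})
        assert res.objective < 1e-10
        assert res.nrmse < 1e-4

    def test_defects_vanish_at_solution(self, problem):
        nlp, trials, plant = problem
        guess = make_initial_guess("constant", trials, 2, 8, plant.muscles,
                                   grid=nlp.grid)
        res = solve(nlp, guess, options={"max_nfev": 40})
        assert res.max_defect < 1e-8

    def test_objective_recomputable_from_trajectories(self, problem):
        nlp, trials, plant = problem
        guess = make_initial_guess("sine-pulses", trials, 2, 6, plant.muscles,
                                   grid=nlp.grid)
        res = solve(nlp, guess, options={"max_nfev": 30})
        recomputed = cost_function(
            res.moments, res.exp_moments,
            {c: res.states[c]["a"] for c in res.states}, res.K)
        assert res.objective == pytest.approx(recomputed, rel=1e-8)
        assert res.nrmse == pytest.approx(nrmse(res.moments, res.exp_moments),
                                          rel=1e-10)

    def test_bounds_hold_at_solution(self, problem):
        nlp, trials, plant = problem
        guess = make_initial_guess("constant", trials, 2, 12, plant.muscles,
                                   grid=nlp.grid)
        res = solve(nlp, guess, options={"max_nfev": 40})
        assert np.all(res.structure.W >= 0)
        for c in res.structure.conditions:
            assert np.all(res.structure.H[c] >= 0)
            a = res.states[c]["a"]
            assert np.all(a >= 0.005 - 1e-9) and np.all(a <= 1.0 + 1e-9)
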