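import numpy as np
import pytest

from torquesyn import (MuscleParams, MuscleSet, TrialData, make_ground_truth,
                       make_plant)
from torquesyn.plant import Condition, PlantSpec, generate_trials


@pytest.fixture(scope="session")
def default_params() -> MuscleParams:
    return MuscleParams()


@pytest.fixture(scope="session")
def small_plant():
    """Desk-scale plant: 4 muscles, 2 DOFs, one short condition."""
    spec = PlantSpec(n_muscles=4, n_dofs=2,
                     conditions=(Condition("walk", 1.0, 1),), seed=11)
    return make_plant(spec)


@pytest.fixture(scope="session")
def small_problem(small_plant):
    """Tiny ground-truth recovery problem for solver-level tests."""
    truth = make_ground_truth(small_plant, n_syn=2)
    trials = generate_trials(truth, small_plant)
    return {"plant": small_plant, "truth": truth, "trials": trials}


def make_trial(condition="c", P=20, NJ=2, m=3, seed=0, duration=1.0,
               n_cycles=1):
    """Hand-built TrialData with smooth random series (no dynamics)."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, duration, P)
    w = 2 * np.pi / (duration / n_cycles)
    moments = np.stack(
        [10 * rng.normal() + 30 * np.sin(w * t + rng.uniform(0, 6))
         for _ in range(NJ)], axis=1)
    lengths = np.stack(
        [0.3 + 0.01 * np.sin(w * t + rng.uniform(0, 6)) for _ in range(m)],
        axis=1)
    arms = 0.03 * rng.standard_normal((1, m, NJ)) \
        * (1 + 0.2 * np.sin(w * t)[:, None, None])
    return TrialData(condition=condition, time=t, moments=moments,
                     mt_lengths=lengths, moment_arms=arms,
                     cycle_times=np.linspace(0, duration, n_cycles + 1))
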