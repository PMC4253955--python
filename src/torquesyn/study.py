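"""End-to-end recovery study on the synthetic plant.

Builds the default desk-scale fixture (8 muscles, 3 DOFs, two conditions of
three gait cycles, 3 true synergies, noise-free moments), runs the
decomposition protocols against it and collects every headline quantity:
the NRMSE admissibility limits, per-count multi-start NRMSE, the selected
synergy count, recovery similarity/correlation against the known truth, the
forward-dynamic consistency error, the effort-weight sweep, and the
joint-moment PCA dimensionality.

Protocol sizes are chosen for a single-workstation run: six multi-starts
per synergy count (alternating pattern families) with a 300-evaluation
trust-region budget per start, the winner then polished with a deeper
budget, on a ~0.1 s collocation grid (about 35 nodes per condition). The
paper-scale protocol (15 starts, counts 3-7) is available through the same
functions.
"""

from __future__ import annotations

import numpy as np

from .collocation import CollocationGrid
from .plant import Condition
from .comparison import compare_structures
from .forward import consistency_check
from .plant import PlantSpec, generate_trials, make_ground_truth, make_plant
from .synergy import SynergyStructure
from .workflows import (moment_dimensionality, nrmse_limits,
                        optimal_synergy_sweep, pure_synergy_solve,
                        select_num_synergies, validate_fixed_weights)

__all__ = ["default_fixture", "run_recovery_study"]

TARGET_DT = 0.1          # collocation spacing, s (~35 nodes per condition)
TRUE_N_SYN = 3


TRAIN_CONDITIONS = (Condition("slow", 1.25, 3), Condition("fast", 1.0, 3))
HELD_OUT_CONDITION = Condition("intermediate", 1.1, 3)


def default_fixture(seed: int = 0, noise: float = 0.0) -> dict:
    """Deterministic synthetic fixture: plant, truth, trials, grid, limits.

    The plant carries three conditions sharing the true weightings: slow
    and fast form the training set the decomposition sees; the
    intermediate condition is held out for the frozen-weightings
    validation protocol.
    """
    spec = PlantSpec(seed=seed, noise=noise,
                     conditions=TRAIN_CONDITIONS + (HELD_OUT_CONDITION,))
    plant = make_plant(spec)
    truth = make_ground_truth(plant, n_syn=TRUE_N_SYN)
    all_trials = generate_trials(truth, plant)
    train_labels = {c.label for c in TRAIN_CONDITIONS}
    trials = [t for t in all_trials if t.condition in train_labels]
    heldout = [t for t in all_trials if t.condition not in train_labels]
    grid = CollocationGrid.from_trials(trials, target_dt=TARGET_DT)
    heldout_grid = CollocationGrid.from_trials(heldout, target_dt=TARGET_DT)
    truth_on_grid = SynergyStructure(
        truth.structure.W,
        {c: np.stack([np.interp(grid.times[c], truth.times[c],
                                truth.structure.H[c][k])
                      for k in range(TRUE_N_SYN)])
         for c in (t.condition for t in trials)},
    )
    return {
        "plant": plant,
        "truth": truth,
        "truth_on_grid": truth_on_grid,
        "trials": trials,
        "heldout_trials": heldout,
        "grid": grid,
        "heldout_grid": heldout_grid,
        "limits": nrmse_limits(trials, grid),
    }


def run_recovery_study(seed: int = 0, nsyn_range=(2, 3, 4), n_starts: int = 6,
                       k_grid=(0.0, 100.0, 200.0, 300.0, 400.0, 500.0),
                       options: dict | None = None, fixture: dict | None = None,
                       polish_nfev: int = 1200, verbose: bool = False) -> dict:
    """Run the full protocol suite on the synthetic fixture.

    Returns a dict with the fixture, per-count results and all headline
    statistics. All randomness descends from ``seed``.
    """
    fx = fixture or default_fixture(seed)
    plant, truth = fx["plant"], fx["truth"]
    trials, grid, limits = fx["trials"], fx["grid"], fx["limits"]

    def say(msg):
        if verbose:
            print(msg, flush=True)

    results = {}
    nrmse_by_nsyn = {}
    for n in nsyn_range:
        res = pure_synergy_solve(trials, plant.muscles, n, n_starts=n_starts,
                                 seed=seed, grid=grid, options=options,
                                 polish_nfev=polish_nfev)
        results[n] = res
        nrmse_by_nsyn[n] = res.nrmse
        say(f"  n_syn={n}: NRMSE {res.nrmse:.3f}% "
            f"(starts: {['%.2f' % v for v in res.per_start_nrmse]})")

    try:
        selected = select_num_synergies(nrmse_by_nsyn, limits)
        selection_error = None
    except ValueError as exc:
        selected = None
        selection_error = str(exc)

    best = results[TRUE_N_SYN]
    times = {c: grid.times[c] for c in best.structure.conditions}
    cycles = {tr.condition: tr.cycle_times for tr in trials}
    report = compare_structures(best.structure, fx["truth_on_grid"],
                                times, cycles)
    say(f"  recovery: SI {report.si_mean:.3f}, rho {report.rho_mean:.3f}")

    consistency = consistency_check(best, trials, plant.muscles)
    say(f"  forward check: vs collocation {consistency['nrmse_vs_collocation']:.4f}%")

    sweep = optimal_synergy_sweep(trials, plant.muscles, TRUE_N_SYN,
                                  K_grid=list(k_grid), seed=seed, grid=grid,
                                  options=options, base_result=best)
    say(f"  K sweep: chosen K={sweep.chosen_K:g}, "
        f"costs {{{', '.join('%g: %.1f' % kv for kv in sweep.activation_costs.items())}}}")

    validation = validate_fixed_weights(fx["heldout_trials"], best.structure.W,
                                        plant.muscles, seed=seed, n_starts=3,
                                        grid=fx["heldout_grid"], options=options)
    say(f"  held-out validation: NRMSE {validation.nrmse:.3f}%")

    dim, spectrum = moment_dimensionality(trials, 0.9, return_spectrum=True)

    return {
        "fixture": fx,
        "limits": limits,
        "results_by_nsyn": results,
        "nrmse_by_nsyn": nrmse_by_nsyn,
        "selected_n_syn": selected,
        "selection_error": selection_error,
        "comparison": report,
        "consistency": {k: v for k, v in consistency.items()
                        if k != "trajectories"},
        "sweep": sweep,
        "validation": validation,
        "dimensionality": dim,
        "variance_spectrum": spectrum,
    }
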