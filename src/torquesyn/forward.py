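"""Forward integration of the muscle dynamics under a synergy structure.

This is the dynamic-consistency oracle: given weightings, controls and
initial states, the activation and contraction ODEs are integrated with an
explicit adaptive Runge-Kutta method, and moments are produced through the
same force and moment-arm mapping the collocation uses. Agreement between
these moments and the collocation solution verifies that the transcribed
solution adheres to the continuous dynamics.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from . import muscle as mm
from .muscle import MuscleSet
from .synergy import SynergyStructure
from .trial import TrialData

__all__ = ["integrate", "consistency_check"]


def _u_interp(structure: SynergyStructure, cond: str, h_times: np.ndarray,
              u_min: float, u_max: float):
    """Clamped excitation function of time (controls linearly interpolated)."""
    H = structure.H[cond]
    W = structure.W

    def u_of_t(t):
        h = np.array([np.interp(t, h_times, H[k]) for k in range(H.shape[0])])
        return np.clip(W @ h, u_min, u_max)

    return u_of_t


def integrate(structure: SynergyStructure, trials: list[TrialData],
              initial_states: dict[str, dict[str, np.ndarray]],
              muscles: MuscleSet, control_times: dict[str, np.ndarray] | None = None,
              rtol: float = 1e-7, atol: float = 1e-9,
              u_min: float = 0.01, u_max: float = 1.0) -> dict[str, dict[str, np.ndarray]]:
    """Integrate (a, l) per muscle per condition; sample on the trial grid.

    ``initial_states[cond]`` holds ``a0`` and ``l0`` arrays of length m.
    ``control_times[cond]`` gives the node times of the control trajectories
    (defaults to the trial's own time grid, which requires matching sample
    counts). Returns per condition: times, a, l (P, m), F (P, m), M (P, NJ),
    and the count of excitation clamps outside [u_min, u_max].
    """
    out = {}
    m = len(muscles)
    for tr in trials:
        cond = tr.condition
        h_times = (control_times or {}).get(cond, tr.time)
        if len(h_times) != structure.H[cond].shape[1]:
            raise ValueError(
                f"control trajectory for {cond!r} has "
                f"{structure.H[cond].shape[1]} samples but {len(h_times)} times"
            )
        u_of_t = _u_interp(structure, cond, h_times, u_min, u_max)
        u_raw_of_t = _u_interp(structure, cond, h_times, -np.inf, np.inf)
        a0 = np.asarray(initial_states[cond]["a0"], dtype=float)
        l0 = np.asarray(initial_states[cond]["l0"], dtype=float)
        if a0.shape != (m,) or l0.shape != (m,):
            raise ValueError("initial state arrays must have one entry per muscle")

        lmt_t = lambda t: np.array(
            [np.interp(t, tr.time, tr.mt_lengths[:, i]) for i in range(m)]
        )

        lo_l, hi_l = 0.2 * muscles.l_opt, 1.9 * muscles.l_opt

        def rhs(t, y):
            # clamp: explicit trial stages may transiently leave the
            # admissible region even when the solution itself does not
            a = np.clip(y[:m], 0.005, 1.0)
            l = np.clip(y[m:], lo_l, hi_l)
            u = u_of_t(t)
            da = mm.activation_rate(a, u, muscles)
            dl = mm.fiber_velocity(a, l, lmt_t(t), muscles)
            return np.concatenate([da, dl])

        sol = solve_ivp(rhs, (tr.time[0], tr.time[-1]),
                        np.concatenate([a0, l0]), t_eval=tr.time,
                        rtol=rtol, atol=atol, method="RK45")
        if not sol.success:
            raise RuntimeError(
                f"integration failed for condition {cond!r}: {sol.message}"
            )
        a = sol.y[:m].T                            # (P, m)
        l = sol.y[m:].T
        bad = np.argwhere((l < lo_l[None, :]) | (l > hi_l[None, :]))
        if bad.size:
            n_, i_ = bad[0]
            raise RuntimeError(
                f"state left admissible region: muscle {muscles.names[i_]} "
                f"fiber length {l[n_, i_]:.4g} m at t={tr.time[n_]:.3f} s "
                f"(condition {cond!r})"
            )
        F = mm.fiber_equilibrium_force(l, tr.mt_lengths, muscles)
        M = np.einsum("pm,pmj->pj", F, tr.moment_arms)
        u_raw = np.stack([u_raw_of_t(t) for t in tr.time])
        n_clamped = int(np.count_nonzero((u_raw < u_min - 1e-12) |
                                         (u_raw > u_max + 1e-12)))
        out[cond] = {"times": tr.time, "a": a, "l": l, "F": F, "M": M,
                     "n_excitation_clamps": n_clamped}
    return out


def consistency_check(solution, trials: list[TrialData], muscles: MuscleSet,
                      rtol: float = 1e-7) -> dict:
    """Forward-integrate a collocation solution and score the agreement.

    Returns NRMSE (percent) of the forward moments against the experimental
    moments, and against the collocation moments — the latter measures pure
    transcription error.
    """
    from .workflows import nrmse

    grids = {c: solution.times[c] for c in solution.structure.conditions}
    init = {c: {"a0": solution.states[c]["a"][0], "l0": solution.states[c]["l"][0]}
            for c in solution.structure.conditions}
    trials_on_grid = [tr.resample(grids[tr.condition]) for tr in trials]
    fwd = integrate(solution.structure, trials_on_grid, init, muscles,
                    control_times=grids, rtol=rtol)
    M_fwd = {c: fwd[c]["M"] for c in fwd}
    return {
        "nrmse_vs_experimental": nrmse(M_fwd, solution.exp_moments),
        "nrmse_vs_collocation": nrmse(M_fwd, solution.moments),
        "trajectories": fwd,
    }
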