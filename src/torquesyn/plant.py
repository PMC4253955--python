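"""Synthetic gait-like plant: muscles, geometry and ground-truth synergies.

The plant stands in for a scaled musculoskeletal model driven through
motion capture: it supplies smooth, periodic muscle-tendon lengths and
signed moment arms per condition, a set of Hill-type muscles with
lower-limb-scale parameters, and a known ground-truth synergy structure
(shared weightings, condition-specific bump-train controls). Forward
integration of the muscle dynamics under the truth produces joint-moment
"experimental" data whose decomposition can be validated by parameter
recovery — no external download required.

The default scale (8 muscles, 3 degrees of freedom, two conditions of three
gait cycles) keeps the full recovery loop at desk scale while producing
moments of the magnitude seen in adult walking (peak joint moments of order
100 N*m), so the 1 N*m lower-limit recipe lands near its literature value.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import muscle as mm
from .muscle import MuscleParams, MuscleSet
from .synergy import SynergyStructure, nnmf
from .trial import TrialData

__all__ = ["Condition", "PlantSpec", "Plant", "GroundTruth",
           "make_plant", "make_ground_truth", "generate_trials"]


@dataclass(frozen=True)
class Condition:
    label: str
    cycle_period: float
    n_cycles: int = 3


DEFAULT_CONDITIONS = (Condition("slow", 1.25, 3), Condition("fast", 1.0, 3))


@dataclass
class PlantSpec:
    """Size, conditions and noise level of the synthetic plant."""

    n_muscles: int = 8
    n_dofs: int = 3
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    seed: int = 0
    noise: float = 0.0    # moment noise, relative to the global moment range

    def __post_init__(self) -> None:
        if self.n_muscles <= self.n_dofs:
            raise ValueError("need more muscles than DOFs")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if not self.conditions:
            raise ValueError("need at least one condition")


@dataclass
class Plant:
    """Muscle set plus per-condition geometry functions."""

    spec: PlantSpec
    muscles: MuscleSet
    _lmt_coef: dict          # cond -> (mean, amps (m,2), phases (m,2))
    _arm_coef: dict          # cond -> (base (m,NJ), amp (m,NJ), phase (m,NJ))
    _dof_map: np.ndarray     # (m, NJ) bool actuation mask

    def conditions(self) -> list[Condition]:
        return list(self.spec.conditions)

    def _cond(self, label: str) -> Condition:
        for c in self.spec.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    def mt_lengths(self, label: str, t) -> np.ndarray:
        """(len(t), m) muscle-tendon lengths, smooth and cycle-periodic."""
        c = self._cond(label)
        mean, amps, phases = self._lmt_coef[label]
        t = np.atleast_1d(np.asarray(t, dtype=float))
        w = 2 * np.pi / c.cycle_period
        out = mean[None, :] + sum(
            amps[:, k][None, :] * np.sin((k + 1) * w * t[:, None] + phases[:, k][None, :])
            for k in range(amps.shape[1])
        )
        return out

    def moment_arms(self, label: str, t) -> np.ndarray:
        """(len(t), m, NJ) signed moment arms, smooth and cycle-periodic."""
        c = self._cond(label)
        base, amp, phase = self._arm_coef[label]
        t = np.atleast_1d(np.asarray(t, dtype=float))
        w = 2 * np.pi / c.cycle_period
        osc = np.sin(w * t[:, None, None] + phase[None, :, :])
        return (base[None, :, :] + amp[None, :, :] * osc) * self._dof_map[None, :, :]


def _draw_muscles(rng: np.random.Generator, m: int) -> MuscleSet:
    """Lower-limb-scale Hill parameters, drawn once per plant seed."""
    muscles = []
    for i in range(m):
        l_opt = rng.uniform(0.08, 0.12)
        muscles.append(MuscleParams(
            name=f"mus{i}",
            f_max=float(rng.uniform(1000.0, 3000.0)),
            l_opt=float(l_opt),
            alpha_opt=float(rng.uniform(0.0, 0.25)),
            l_slack=float(l_opt * rng.uniform(1.6, 2.4)),
            eps_t_max=0.04,
            v_max=10.0,
            tau_act=0.020,
            tau_deact=0.050,
        ))
    return MuscleSet(muscles)


def make_plant(spec: PlantSpec) -> Plant:
    """Build the deterministic plant for a spec (geometry seeded by spec.seed).

    Muscle-tendon lengths are a mean plus two seeded harmonics of the gait
    cycle with excursions that keep the resting normalized fiber length
    roughly in [0.6, 1.3]; moment arms are seeded sinusoids with magnitudes
    within 0.06 m, sparse so each muscle spans 1-2 DOFs, and resampled (up
    to 100 draws) until every DOF is actuated in both directions.
    """
    rng = np.random.default_rng(spec.seed)
    m, nj = spec.n_muscles, spec.n_dofs
    muscles = _draw_muscles(rng, m)

    for _attempt in range(100):
        dof_map = np.zeros((m, nj), dtype=bool)
        signs = np.zeros((m, nj))
        for i in range(m):
            todo = rng.choice(nj, size=rng.integers(1, 3), replace=False)
            dof_map[i, todo] = True
            signs[i, todo] = rng.choice([-1.0, 1.0], size=len(todo))
        ok = all(
            np.any(signs[:, j] > 0) and np.any(signs[:, j] < 0) for j in range(nj)
        )
        if ok:
            break
    else:
        raise RuntimeError("could not satisfy bidirectional actuation in 100 draws")

    lmt_coef, arm_coef = {}, {}
    for c in spec.conditions:
        # per-condition kinematic variation on a shared layout
        cond_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, zlib.crc32(c.label.encode()) % (2 ** 31)])
        )
        rest_strain = 0.25 * muscles.eps_t_max
        mean = muscles.l_opt * np.cos(muscles.alpha_opt) \
            + muscles.l_slack * (1.0 + rest_strain)
        amp1 = muscles.l_opt * cond_rng.uniform(0.04, 0.10, size=m)
        amp2 = muscles.l_opt * cond_rng.uniform(0.01, 0.04, size=m)
        phases = cond_rng.uniform(0, 2 * np.pi, size=(m, 2))
        lmt_coef[c.label] = (mean, np.stack([amp1, amp2], axis=1), phases)

        base = signs * cond_rng.uniform(0.025, 0.05, size=(m, nj))
        amp = np.abs(base) * cond_rng.uniform(0.1, 0.35, size=(m, nj))
        phase = cond_rng.uniform(0, 2 * np.pi, size=(m, nj))
        arm_coef[c.label] = (base, amp, phase)

    return Plant(spec=spec, muscles=muscles, _lmt_coef=lmt_coef,
                 _arm_coef=arm_coef, _dof_map=dof_map)


@dataclass
class GroundTruth:
    """Known synergy structure and the states it starts from."""

    structure: SynergyStructure
    times: dict[str, np.ndarray]          # dense sample times per condition
    initial_states: dict[str, dict[str, np.ndarray]]
    muscles: MuscleSet


def _bump_train(phase: np.ndarray, bumps) -> np.ndarray:
    """Sum of raised-cosine bumps on cycle phase in [0, 1)."""
    out = np.zeros_like(phase)
    for onset, width, amp in bumps:
        x = (phase - onset) % 1.0
        mask = x < width
        out[mask] += amp * 0.5 * (1 - np.cos(2 * np.pi * x[mask] / width))
    return out


def make_ground_truth(plant: Plant, n_syn: int = 3,
                      seed: int | None = None,
                      samples_per_cycle: int = 80) -> GroundTruth:
    """Draw a sparse shared W and per-condition bump-train controls.

    Each synergy is dominated by 2-4 muscles; controls are smooth
    non-negative bump trains phase-locked to the gait cycle, different
    across conditions. Candidate structures are rejection-resampled until
    every excitation lies in (0.02, 0.95).
    """
    spec = plant.spec
    if n_syn >= spec.n_muscles:
        raise ValueError("n_syn must be below the muscle count")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    m = spec.n_muscles

    times = {}
    for c in spec.conditions:
        P = samples_per_cycle * c.n_cycles + 1
        times[c.label] = np.linspace(0.0, c.cycle_period * c.n_cycles, P)

    for _attempt in range(200):
        W = np.zeros((m, n_syn))
        for k in range(n_syn):
            dom = rng.choice(m, size=rng.integers(2, 5), replace=False)
            W[dom, k] = rng.uniform(0.5, 1.0, size=len(dom))
        W += rng.uniform(0.0, 0.08, size=W.shape)
        if np.any(W.sum(axis=1) < 0.3):   # every muscle must receive drive
            continue
        H = {}
        ok = True
        for c in spec.conditions:
            t = times[c.label]
            phase = (t / c.cycle_period) % 1.0
            h = np.empty((n_syn, len(t)))
            for k in range(n_syn):
                bumps = [
                    (rng.uniform(0, 1), rng.uniform(0.35, 0.7),
                     rng.uniform(0.25, 0.6))
                    for _ in range(rng.integers(1, 3))
                ]
                h[k] = 0.08 + _bump_train(phase, bumps)
            H[c.label] = h
        # rescale controls so the peak excitation sits safely below 1
        peak = max(float((W @ H[c.label]).max()) for c in spec.conditions)
        scale = 0.85 / peak
        H = {k: v * scale for k, v in H.items()}
        u_lo = min(float((W @ H[c.label]).min()) for c in spec.conditions)
        u_hi = max(float((W @ H[c.label]).max()) for c in spec.conditions)
        if not (0.02 < u_lo and u_hi < 0.95):
            ok = False
        if ok:
            break
    else:
        raise RuntimeError("ground-truth rejection budget exhausted")

    structure = SynergyStructure(W, H)
    init = {}
    for c in spec.conditions:
        u0 = np.clip(W @ H[c.label][:, 0], 0.01, 1.0)
        lmt0 = plant.mt_lengths(c.label, 0.0)[0]
        l0 = mm.equilibrium_fiber_length(u0, lmt0, plant.muscles)
        init[c.label] = {"a0": u0, "l0": np.asarray(l0)}
    return GroundTruth(structure=structure, times=times,
                       initial_states=init, muscles=plant.muscles)


def generate_trials(truth: GroundTruth, plant: Plant,
                    noise: float | None = None,
                    seed: int | None = None,
                    rtol: float = 1e-8) -> list[TrialData]:
    """Forward-integrate the truth and emit noisy (or clean) TrialData.

    Moments, lengths and arms are sampled on the dense ground-truth grid;
    seeded Gaussian noise of amplitude ``noise`` times the global moment
    range is added to the moments only.
    """
    from .forward import integrate

    spec = plant.spec
    if noise is None:
        noise = spec.noise
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)

    bare_trials = []
    for c in spec.conditions:
        t = truth.times[c.label]
        lmt = plant.mt_lengths(c.label, t)
        arms = plant.moment_arms(c.label, t)
        bare_trials.append(TrialData(
            condition=c.label, time=t,
            moments=np.zeros((len(t), spec.n_dofs)),
            mt_lengths=lmt, moment_arms=arms,
            cycle_times=np.arange(c.n_cycles + 1) * c.cycle_period,
        ))

    sim = integrate(truth.structure, bare_trials, truth.initial_states,
                    plant.muscles, control_times=truth.times, rtol=rtol,
                    atol=rtol * 1e-2)
    moments = {c: sim[c]["M"] for c in sim}
    g_lo = min(float(Ms.min()) for Ms in moments.values())
    g_hi = max(float(Ms.max()) for Ms in moments.values())

    out = []
    for tr in bare_trials:
        M = moments[tr.condition].copy()
        if noise > 0:
            M = M + rng.normal(0.0, noise * (g_hi - g_lo), size=M.shape)
        out.append(TrialData(
            condition=tr.condition, time=tr.time, moments=M,
            mt_lengths=tr.mt_lengths, moment_arms=tr.moment_arms,
            cycle_times=tr.cycle_times,
        ))
    return out
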