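"""Linear synergy combination, non-negative matrix factorization and the
arbitrary-pattern initial-guess generator.

A synergy is a fixed non-negative muscle weighting vector (column of ``W``)
driven by a non-negative time-varying control signal; muscle excitations are
their linear combination ``u = W @ h``. ``W`` is shared across movement
conditions, the controls are condition-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

__all__ = ["SynergyStructure", "combine", "nnmf", "constant_patterns",
           "sine_pulse_patterns", "excitation_patterns",
           "static_optimization_patterns", "make_initial_guess"]


@dataclass
class SynergyStructure:
    """Shared weighting matrix and per-condition synergy controls.

    Attributes
    ----------
    W : (m, n_syn) non-negative weighting matrix, shared across conditions.
    H : dict mapping condition label -> (n_syn, P_s) non-negative controls.
    """

    W: np.ndarray
    H: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be 2-D (muscles x synergies)")
        if np.any(self.W < 0):
            raise ValueError("W must be non-negative")
        self.H = {k: np.asarray(v, dtype=float) for k, v in self.H.items()}
        for k, h in self.H.items():
            if h.ndim != 2 or h.shape[0] != self.n_syn:
                raise ValueError(
                    f"H[{k!r}] must be (n_syn, P); got {h.shape} with "
                    f"n_syn={self.n_syn}"
                )
            if np.any(h < 0):
                raise ValueError(f"H[{k!r}] must be non-negative")

    @property
    def n_muscles(self) -> int:
        return self.W.shape[0]

    @property
    def n_syn(self) -> int:
        return self.W.shape[1]

    @property
    def conditions(self) -> list[str]:
        return list(self.H)

    def excitations(self, condition: str) -> np.ndarray:
        """(m, P) excitation matrix W @ H for one condition."""
        return self.W @ self.H[condition]

    def normalized(self) -> "SynergyStructure":
        """Rescale so each weighting column has unit Euclidean norm.

        The combination is invariant under (W D, D^-1 H) for positive
        diagonal D, so this fixes the scale degeneracy without changing the
        excitations.
        """
        norms = np.linalg.norm(self.W, axis=0)
        norms = np.where(norms > 0, norms, 1.0)
        return SynergyStructure(
            self.W / norms, {k: h * norms[:, None] for k, h in self.H.items()}
        )

    # -- serialization ------------------------------------------------------
    def save(self, out_dir: str | Path, times: dict[str, np.ndarray] | None = None,
             muscle_names: list[str] | None = None) -> None:
        """Write one weightings CSV plus one controls CSV per condition."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        idx = muscle_names if muscle_names else [f"m{i}" for i in range(self.n_muscles)]
        cols = [f"syn{k}" for k in range(self.n_syn)]
        pd.DataFrame(self.W, index=idx, columns=cols).to_csv(
            out / "weightings.csv", index_label="muscle"
        )
        for cond, h in self.H.items():
            t = (times or {}).get(cond, np.arange(h.shape[1], dtype=float))
            df = pd.DataFrame(h.T, columns=cols)
            df.insert(0, "time", t)
            df.to_csv(out / f"controls_{cond}.csv", index=False)

    @classmethod
    def load(cls, in_dir: str | Path) -> "SynergyStructure":
        in_dir = Path(in_dir)
        W = pd.read_csv(in_dir / "weightings.csv", index_col=0).to_numpy()
        H = {}
        for f in sorted(in_dir.glob("controls_*.csv")):
            cond = f.stem[len("controls_"):]
            df = pd.read_csv(f)
            H[cond] = df.drop(columns=["time"]).to_numpy().T
        return cls(W, H)


def combine(W: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Excitations from the linear synergy combination u_i = sum_k W_ik h_k.

    ``h`` may be a length-``n_syn`` vector (one instant) or an
    ``(n_syn, P)`` matrix of control trajectories.
    """
    W = np.asarray(W, dtype=float)
    h = np.asarray(h, dtype=float)
    if W.ndim != 2 or h.shape[0] != W.shape[1]:
        raise ValueError(f"shape mismatch: W {W.shape} vs h {h.shape}")
    if np.any(W < 0) or np.any(h < 0):
        raise ValueError("W and h must be non-negative")
    return W @ h


def nnmf(U: np.ndarray, n_components: int, seed: int,
         max_iter: int = 2000, tol: float = 1e-8):
    """Non-negative matrix factorization U ~ W H (Frobenius loss).

    Multiplicative updates with seeded random non-negative initialization;
    deterministic given ``seed``. Returns ``(W, H, rel_err)`` with the
    relative Frobenius reconstruction error.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U < 0):
        raise ValueError("U must be non-negative")
    nU = np.linalg.norm(U)
    if nU == 0:
        raise ValueError("cannot factorize an all-zero matrix")
    if not 1 <= n_components <= min(U.shape):
        raise ValueError(f"n_components {n_components} outside [1, {min(U.shape)}]")
    model = NMF(n_components=n_components, init="random", solver="mu",
                max_iter=max_iter, tol=tol, random_state=int(seed) % (2**31))
    with warnings.catch_warnings():
        # the factorization seeds initial guesses; hitting max_iter is fine
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(U)
    H = model.components_
    rel_err = np.linalg.norm(U - W @ H) / nU
    return W, H, rel_err


# ---------------------------------------------------------------------------
# arbitrary excitation-pattern families for initial guesses
# ---------------------------------------------------------------------------

def constant_patterns(n_muscles: int, times: np.ndarray, rng: np.random.Generator,
                      level: float | None = None) -> np.ndarray:
    """Constant excitation per muscle, drawn from [0.05, 0.6] unless fixed."""
    if level is not None:
        c = np.full(n_muscles, float(level))
    else:
        c = rng.uniform(0.05, 0.6, size=n_muscles)
    return np.repeat(c[:, None], len(times), axis=1)


def sine_pulse_patterns(n_muscles: int, times: np.ndarray, cycle_period: float,
                        rng: np.random.Generator) -> np.ndarray:
    """1-3 half-sine pulses per gait cycle per muscle, seeded onset/width/amp.

    Amplitudes lie in [0.05, 0.6]; pulses repeat every cycle, with a small
    baseline so the pattern never reaches zero.
    """
    U = np.full((n_muscles, len(times)), 0.02)
    phase = (times % cycle_period) / cycle_period
    for i in range(n_muscles):
        for _ in range(rng.integers(1, 4)):
            onset = rng.uniform(0.0, 1.0)
            width = rng.uniform(0.15, 0.5)
            amp = rng.uniform(0.05, 0.6)
            x = (phase - onset) % 1.0
            mask = x < width
            U[i, mask] += amp * np.sin(np.pi * x[mask] / width)
    return np.clip(U, 0.0, 0.95)


def excitation_patterns(pattern: str, n_muscles: int, times: np.ndarray,
                        cycle_period: float, rng: np.random.Generator,
                        level: float | None = None) -> np.ndarray:
    """Dispatch on the pattern family name: 'constant' or 'sine-pulses'."""
    if pattern == "constant":
        return constant_patterns(n_muscles, times, rng, level=level)
    if pattern in ("sine-pulses", "sine"):
        return sine_pulse_patterns(n_muscles, times, cycle_period, rng)
    raise ValueError(f"unknown pattern family {pattern!r}")


def static_optimization_patterns(trial, times, muscles,
                                 ridge: float = 5.0,
                                 u_prior: float = 0.2) -> np.ndarray:
    """Excitations from per-node non-negative static optimization.

    At every node the muscle forces are approximated as proportional to
    excitation (force evaluated at mid activation with the fiber at its
    isometric equilibrium), and the excitation vector solving the
    moment-matching NNLS with a small ridge toward a tonic prior is taken.
    A model-informed start family: unlike the arbitrary constant/sine
    patterns it usually lies in the basin of the global minimum.
    """
    from scipy.optimize import nnls as _nnls
    from . import muscle as mm

    rs = trial.resample(times)
    m = rs.n_muscles
    P = len(times)
    U = np.empty((m, P))
    a_ref = 0.5
    for n in range(P):
        l_eq = mm.equilibrium_fiber_length(a_ref, rs.mt_lengths[n], muscles)
        F_hat = mm.fiber_equilibrium_force(l_eq, rs.mt_lengths[n], muscles) / a_ref
        A = (rs.moment_arms[n] * F_hat[:, None]).T        # (NJ, m)
        A_aug = np.vstack([A, ridge * np.eye(m)])
        b_aug = np.concatenate([rs.moments[n], ridge * np.full(m, u_prior)])
        U[:, n], _ = _nnls(A_aug, b_aug)
    # light temporal smoothing against node-to-node chatter
    if P >= 3:
        U[:, 1:-1] = (U[:, :-2] + 2 * U[:, 1:-1] + U[:, 2:]) / 4.0
    return np.clip(U, 0.02, 0.95)


def make_initial_guess(pattern: str, trials, n_syn: int, seed: int,
                       muscles, grid=None, scheme: str = "hermite-simpson",
                       level: float | None = None) -> dict:
    """Full decision-variable guess from an excitation pattern family.

    A seeded excitation pattern (constant levels, sine pulses, or
    static-optimization excitations) is built for every muscle over all
    conditions, factorized by NNMF into shared weightings and
    per-condition controls, and the muscle dynamics are integrated under
    the reconstructed excitations to supply admissible state trajectories
    at every collocation node.

    Returns ``{"W", "H", "a", "l", "_patterns"}``; the state entries are
    (P, m) arrays per condition.
    """
    from .collocation import CollocationGrid, _CondProblem
    from . import muscle as mm

    if not trials:
        raise ValueError("need at least one trial")
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if grid is None:
        grid = CollocationGrid.from_trials(trials)
    rng = np.random.default_rng(int(seed))
    m = trials[0].n_muscles
    patterns = {}
    for tr in trials:
        times = grid.times[tr.condition]
        if pattern == "static":
            patterns[tr.condition] = static_optimization_patterns(
                tr, times, muscles
            )
        else:
            patterns[tr.condition] = excitation_patterns(
                pattern, m, times, tr.cycle_period, rng, level=level
            )
    U = np.concatenate([patterns[tr.condition] for tr in trials], axis=1)
    W, Hcat, _ = nnmf(np.maximum(U, 1e-9), n_syn, seed)
    H = {}
    off = 0
    for tr in trials:
        P = grid.n_points(tr.condition)
        H[tr.condition] = Hcat[:, off:off + P]
        off += P
    guess = {"W": W, "H": H, "a": {}, "l": {}, "_patterns": patterns}
    for tr in trials:
        cond = tr.condition
        cp = _CondProblem(tr, grid.times[cond], muscles, scheme, 0.01, 1.0)
        u0 = np.clip(W @ H[cond][:, 0], 0.01, 1.0)
        a0 = u0
        l0 = mm.equilibrium_fiber_length(a0, cp.lmt[0], muscles)
        out = cp.propagate(W, H[cond], a0, l0, need_sens=False, nW=m * n_syn)
        guess["a"][cond] = out["a"]
        guess["l"][cond] = out["l"]
    return guess
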