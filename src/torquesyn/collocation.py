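"""Direct-collocation transcription and solution of the torque-decomposition OCP.

The decomposition seeks a shared non-negative weighting matrix ``W`` and
per-condition non-negative synergy controls ``h`` such that excitations
``u = W h``, driven through activation and contraction dynamics, produce
muscle forces whose moment-arm-weighted sum tracks the experimental joint
moments. The continuous problem is transcribed on a uniform grid per
condition: states (activation ``a``, fiber length ``l``) and controls live
at the grid nodes, the muscle ODEs become per-interval defect constraints
(Hermite-Simpson by default, trapezoidal selectable), and the objective is
the discretized sum of squared moment errors plus an optional
``K``-weighted sum of squared activations.

The solver condenses the transcription: for any candidate ``(W, H)`` and
initial states, the defect equations are solved interval by interval
(safeguarded Newton), which eliminates the state variables exactly. The
reduced nonlinear least-squares problem in ``(W, H, a0, l0)`` is then
solved by a trust-region Gauss-Newton method
(:func:`scipy.optimize.least_squares`) with analytic forward sensitivities.
The returned full decision vector therefore satisfies every defect
constraint of the transcription to Newton tolerance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from . import _kernels
from . import muscle as mm
from .muscle import MuscleSet
from .synergy import SynergyStructure
from .trial import TrialData

__all__ = [
    "CollocationGrid",
    "OcpSpec",
    "SolveResult",
    "joint_moments",
    "cost_function",
    "transcribe",
    "solve",
]

DEFAULT_OPTIONS: dict[str, Any] = {
    "max_nfev": 300,     # Gauss-Newton iteration budget per start
    "ftol": 1e-10,
    "xtol": 1e-10,
    "gtol": 1e-10,
    "penalty_u": 200.0,  # weight on the u <= u_max hinge residuals
    "verbose": 0,
}


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass
class CollocationGrid:
    """Uniform collocation grids, one per condition.

    ``times[cond]`` is an equispaced array of P_s node times spanning the
    condition's window; ``dt`` and the covered duration follow from it.
    """

    times: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = {k: np.asarray(v, dtype=float) for k, v in self.times.items()}
        for cond, t in self.times.items():
            if len(t) < 2:
                raise ValueError(f"grid for {cond!r} needs at least 2 points")
            d = np.diff(t)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-8):
                raise ValueError(f"grid for {cond!r} must be uniform and increasing")

    def n_points(self, cond: str) -> int:
        return len(self.times[cond])

    def dt(self, cond: str) -> float:
        t = self.times[cond]
        return float(t[1] - t[0])

    def duration(self, cond: str) -> float:
        t = self.times[cond]
        return float(t[-1] - t[0])

    @classmethod
    def from_trials(cls, trials: list[TrialData],
                    n_points: int | dict[str, int] | None = None,
                    target_dt: float | None = None) -> "CollocationGrid":
        """Build grids spanning each trial's window.

        Either a node count (shared or per condition) or a target spacing
        may be given; with neither, the trial's own sampling density is
        kept.
        """
        times = {}
        for tr in trials:
            if isinstance(n_points, dict):
                P = n_points[tr.condition]
            elif n_points is not None:
                P = int(n_points)
            elif target_dt is not None:
                P = max(int(round(tr.duration / target_dt)) + 1, 2)
            else:
                P = len(tr.time)
            times[tr.condition] = np.linspace(tr.time[0], tr.time[-1], P)
        return cls(times)


# ---------------------------------------------------------------------------
# problem specification and result containers
# ---------------------------------------------------------------------------

@dataclass
class OcpSpec:
    """Everything that defines one torque-decomposition solve.

    ``K`` is the effort weight (0 gives the pure-synergy problem);
    ``fixed_W`` freezes the weighting matrix so only controls and states
    are free (the held-out-condition validation protocol).
    """

    trials: list[TrialData]
    muscles: MuscleSet
    n_syn: int
    K: float = 0.0
    scheme: str = "hermite-simpson"
    n_substeps: int = 4
    u_min: float = 0.01
    u_max: float = 1.0
    fixed_W: np.ndarray | None = None
    options: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.n_syn < 1:
            raise ValueError("n_syn must be >= 1")
        if self.scheme not in ("hermite-simpson", "trapezoidal"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not self.trials:
            raise ValueError("need at least one trial")
        if self.fixed_W is not None:
            self.fixed_W = np.asarray(self.fixed_W, dtype=float)
            m = len(self.muscles)
            if self.fixed_W.shape != (m, self.n_syn):
                raise ValueError("fixed_W shape mismatch")


@dataclass
class SolveResult:
    """Optimized synergy structure plus trajectories and diagnostics."""

    structure: SynergyStructure
    states: dict[str, dict[str, np.ndarray]]      # cond -> {'a': (P,m), 'l': (P,m)}
    moments: dict[str, np.ndarray]                # cond -> (P, NJ) simulated
    exp_moments: dict[str, np.ndarray]            # cond -> (P, NJ) experimental
    times: dict[str, np.ndarray]
    nrmse: float
    moment_cost: float
    activation_cost: float
    objective: float
    K: float
    success: bool
    converged: bool
    status: int
    message: str
    n_iter: int
    max_defect: float
    guess_objective: float
    wall_time_s: float

    @property
    def excitations(self) -> dict[str, np.ndarray]:
        return {c: self.structure.excitations(c) for c in self.structure.conditions}

    def summary(self) -> dict[str, Any]:
        return {
            "nrmse_percent": self.nrmse,
            "moment_cost": self.moment_cost,
            "activation_cost": self.activation_cost,
            "objective": self.objective,
            "K": self.K,
            "success": bool(self.success),
            "converged": bool(self.converged),
            "status": int(self.status),
            "n_iter": int(self.n_iter),
            "max_defect": self.max_defect,
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def joint_moments(forces: np.ndarray, moment_arms: np.ndarray) -> np.ndarray:
    """Moments M_j = sum_i R_ij F_i from muscle forces and signed arms.

    ``forces`` is (m,) or (P, m); ``moment_arms`` is (m, NJ) or (P, m, NJ).
    """
    F = np.asarray(forces, dtype=float)
    R = np.asarray(moment_arms, dtype=float)
    if F.ndim == 1 and R.ndim == 2:
        if F.shape[0] != R.shape[0]:
            raise ValueError(f"shape mismatch: forces {F.shape}, arms {R.shape}")
        return F @ R
    if F.ndim == 2 and R.ndim == 3:
        if F.shape != R.shape[:2]:
            raise ValueError(f"shape mismatch: forces {F.shape}, arms {R.shape}")
        return np.einsum("pm,pmj->pj", F, R)
    raise ValueError("forces must be (m,) with arms (m,NJ), or (P,m) with (P,m,NJ)")


def cost_function(M, M_star, a, K: float, dt: float | None = None) -> float:
    """Discretized objective: sum of squared moment errors + K * sum a^2.

    ``M``/``M_star``/``a`` may be single-condition arrays or dicts over
    conditions. The discretized objective is a plain sum over nodes; if
    ``dt`` is given the node sums are scaled by it (the integral-form
    objective), which rescales but does not reshape the problem.
    """
    if not isinstance(M, dict):
        M, M_star, a = {"_": M}, {"_": M_star}, {"_": a}
        dts = {"_": dt}
    else:
        dts = dt if isinstance(dt, dict) else {c: dt for c in M}
    total = 0.0
    for c in M:
        err = np.asarray(M[c], dtype=float) - np.asarray(M_star[c], dtype=float)
        term = np.sum(err ** 2) + K * np.sum(np.asarray(a[c], dtype=float) ** 2)
        w = dts.get(c)
        total += term * (w if w is not None else 1.0)
    return float(total)


# ---------------------------------------------------------------------------
# smooth excitation clamp
# ---------------------------------------------------------------------------

_SCLAMP_DELTA = 1e-3


def _sclamp(x, lo, hi, delta=_SCLAMP_DELTA):
    """Smooth clamp of x into [lo, hi]; C^inf, within delta/2 of the hard clamp."""
    y = lo + 0.5 * ((x - lo) + np.sqrt((x - lo) ** 2 + delta ** 2))
    return y - 0.5 * ((y - hi) + np.sqrt((y - hi) ** 2 + delta ** 2))


def _sclamp_grad(x, lo, hi, delta=_SCLAMP_DELTA):
    g1 = 0.5 * (1.0 + (x - lo) / np.sqrt((x - lo) ** 2 + delta ** 2))
    y = lo + 0.5 * ((x - lo) + np.sqrt((x - lo) ** 2 + delta ** 2))
    g2 = 1.0 - 0.5 * (1.0 + (y - hi) / np.sqrt((y - hi) ** 2 + delta ** 2))
    return g1 * g2


# ---------------------------------------------------------------------------
# vectorized safeguarded root solver (per-muscle scalar equations)
# ---------------------------------------------------------------------------

def _safeguarded_newton(fun, x0, lo, hi, tol, itmax=60):
    """Solve fun(x) = 0 elementwise for x in [lo, hi].

    ``fun`` maps an array x to (residual, d(residual)/dx). Newton steps are
    taken when they stay inside the current sign-bracket; otherwise the
    method bisects. Brackets start at [lo, hi]; if the residual does not
    change sign there, the iteration still runs damped Newton clipped into
    the box (the equation may have its root at a bound).
    """
    x = np.clip(np.asarray(x0, dtype=float).copy(), lo, hi)
    bl = np.full_like(x, lo, dtype=float)
    bh = np.full_like(x, hi, dtype=float)
    f_bl, _ = fun(bl)
    f_bh, _ = fun(bh)
    bracketed = np.sign(f_bl) * np.sign(f_bh) < 0
    # orient so f(bl) < 0 < f(bh) where bracketed
    flip = bracketed & (f_bl > 0)
    bl_f, bh_f = bl.copy(), bh.copy()
    bl = np.where(flip, bh_f, bl)
    bh = np.where(flip, bl_f, bh)
    for _ in range(itmax):
        f, df = fun(x)
        # update brackets with the sign at x
        neg = f < 0
        bl = np.where(bracketed & neg, x, bl)
        bh = np.where(bracketed & ~neg, x, bh)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = f / df
        step = np.where(np.isfinite(step), step, 0.0)
        xn = x - step
        inside = bracketed & ((xn - bl) * (xn - bh) < 0)
        xn = np.where(bracketed & ~inside, 0.5 * (bl + bh), xn)
        xn = np.clip(xn, lo, hi)
        done = np.abs(xn - x) < tol
        x = xn
        if np.all(done):
            break
    return x


# ---------------------------------------------------------------------------
# per-condition condensed propagation with forward sensitivities
# ---------------------------------------------------------------------------

class _CondProblem:
    """Resampled data and propagation machinery for one condition.

    States and controls live at the P coarse collocation nodes; between
    adjacent nodes the dynamics are integrated with ``n_substeps`` refined
    steps of the chosen scheme (controls linearly interpolated), so the
    per-interval defect map is accurate well beyond the node spacing.
    """

    def __init__(self, trial: TrialData, grid_times: np.ndarray, mset: MuscleSet,
                 scheme: str, u_min: float, u_max: float, n_substeps: int = 4):
        self.condition = trial.condition
        self.mset = mset
        self.scheme = scheme
        self.u_min = u_min
        self.u_max = u_max
        self.S = int(n_substeps)
        if self.S < 1:
            raise ValueError("n_substeps must be >= 1")
        rs = trial.resample(grid_times)
        self.times = grid_times
        self.dt = float(grid_times[1] - grid_times[0])
        self.P = len(grid_times)
        self.M_star = rs.moments                      # (P, NJ)
        self.R = rs.moment_arms                       # (P, m, NJ)
        self.lmt = rs.mt_lengths                      # (P, m)
        self.n_dofs = self.M_star.shape[1]
        self.cycle_times = trial.cycle_times

        # fine stepping grid: S substeps per collocation interval
        P, S = self.P, self.S
        F = (P - 1) * S + 1
        self.F = F
        self.dt_fine = self.dt / S
        t_fine = grid_times[0] + self.dt_fine * np.arange(F)
        t_fine[-1] = grid_times[-1]
        self.t_fine = t_fine
        m = trial.n_muscles

        # the transcribed problem is fully defined by the node data: between
        # nodes, muscle-tendon lengths follow the same piecewise-linear
        # interpolant the forward-consistency check sees
        def interp_lmt(ts):
            return np.stack([np.interp(ts, grid_times, self.lmt[:, i])
                             for i in range(m)], axis=1)

        self.lmt_fine = interp_lmt(t_fine)
        self.lmt_fine_mid = interp_lmt(0.5 * (t_fine[:-1] + t_fine[1:])) \
            if scheme == "hermite-simpson" else np.zeros((F - 1, m))
        # linear-interpolation weights mapping coarse nodes to fine nodes
        j = np.arange(F)
        self.f_lo = np.minimum(j // S, P - 2)         # coarse interval index
        self.f_alpha = (j - self.f_lo * S) / S        # position inside it
        jm = np.arange(F - 1) + 0.5
        self.fm_lo = np.minimum((np.arange(F - 1)) // S, P - 2)
        self.fm_alpha = (jm - self.fm_lo * S) / S

    # -- excitations --------------------------------------------------------
    def excitations(self, W, H):
        """Clamped node/midpoint excitations (P, m) from controls (n_syn, P)."""
        u_raw = (W @ H).T
        u = _sclamp(u_raw, self.u_min, self.u_max)
        if self.scheme == "hermite-simpson":
            h_mid = 0.5 * (H[:, :-1] + H[:, 1:])
            um_raw = (W @ h_mid).T
            um = _sclamp(um_raw, self.u_min, self.u_max)
        else:
            um_raw = um = None
        return u_raw, u, um_raw, um

    def _du_blocks(self, W, H, u_raw, um_raw, nW, D):
        """d(u)/d(theta) at nodes and midpoints.

        Returns ``(du_raw, du, dum)``: the raw (pre-clamp) node derivatives,
        the clamped node derivatives (P, m, D) and the clamped midpoint
        derivatives (P-1, m, D) (None for trapezoidal).
        """
        m, n_syn = W.shape
        P = self.P
        rows = np.arange(P)[:, None]          # node index
        cols_m = np.arange(m)[None, :]        # muscle index
        du_raw = np.zeros((P, m, D))
        idx_i = np.repeat(np.arange(m), n_syn)
        idx_k = np.tile(np.arange(n_syn), m)
        if nW:
            du_raw[:, idx_i, idx_i * n_syn + idx_k] = H[idx_k, :].T
        for k in range(n_syn):
            du_raw[rows, cols_m, nW + k * P + rows] = W[:, k][None, :]
        du = du_raw * _sclamp_grad(u_raw, self.u_min, self.u_max)[:, :, None]
        dum = None
        if self.scheme == "hermite-simpson":
            h_mid = 0.5 * (H[:, :-1] + H[:, 1:])
            dum = np.zeros((P - 1, m, D))
            if nW:
                dum[:, idx_i, idx_i * n_syn + idx_k] = h_mid[idx_k, :].T
            rows_c = np.arange(P - 1)[:, None]
            for k in range(n_syn):
                dum[rows_c, cols_m, nW + k * P + rows_c] += 0.5 * W[:, k][None, :]
                dum[rows_c, cols_m, nW + k * P + rows_c + 1] += 0.5 * W[:, k][None, :]
            dum *= _sclamp_grad(um_raw, self.u_min, self.u_max)[:, :, None]
        return du_raw, du, dum

    # -- dynamics helpers ---------------------------------------------------
    def _fa(self, a, u):
        return mm.activation_rate(a, u, self.mset)

    def _fa_p(self, a, u):
        return mm.activation_rate_partials(a, u, self.mset)

    def _fv(self, a, l, lmt):
        return mm.fiber_velocity(a, l, lmt, self.mset)

    def _fv_p(self, a, l, lmt):
        return mm.fiber_velocity_partials(a, l, lmt, self.mset)

    # -- condensed propagation ---------------------------------------------
    def _kernel_consts(self):
        if not hasattr(self, "_kc"):
            ms = self.mset
            eps_toe = 0.609 * ms.eps_t_max
            k_lin = (1.0 - ms.f_toe) / (ms.eps_t_max - eps_toe)
            self._kc = tuple(np.ascontiguousarray(x, dtype=float) for x in (
                ms.l_opt, ms.l_opt * np.sin(ms.alpha_opt), ms.l_slack,
                ms.f_toe, ms.k_toe, eps_toe, k_lin,
                ms.gamma_fl, ms.k_pe, ms.eps_m0,
                ms.a_f, ms.f_len, ms.v_max,
                ms.tau_act, ms.tau_deact, ms.act_blend,
            ))
        return self._kc

    def _fine_inputs(self, W, H, need_sens: bool, nW: int):
        """Excitations (and their parameter derivatives) on the fine grid."""
        m = len(self.mset)
        P, n_syn = self.P, W.shape[1]
        u_raw = (W @ H).T                                         # (P, m)
        al = self.f_alpha[:, None]
        ur_f = (1 - al) * u_raw[self.f_lo] + al * u_raw[self.f_lo + 1]
        u_f = _sclamp(ur_f, self.u_min, self.u_max)
        hs = self.scheme == "hermite-simpson"
        if hs:
            alm = self.fm_alpha[:, None]
            urm_f = (1 - alm) * u_raw[self.fm_lo] + alm * u_raw[self.fm_lo + 1]
            um_f = _sclamp(urm_f, self.u_min, self.u_max)
        else:
            um_f = np.zeros((self.F - 1, m))
        du_raw = du_f = dum_f = None
        if need_sens:
            D = nW + n_syn * P + 2 * m
            # raw coarse-node derivatives (no clamp chain)
            du_raw = np.zeros((P, m, D))
            idx_i = np.repeat(np.arange(m), n_syn)
            idx_k = np.tile(np.arange(n_syn), m)
            rows = np.arange(P)[:, None]
            cols_m = np.arange(m)[None, :]
            if nW:
                du_raw[:, idx_i, idx_i * n_syn + idx_k] = H[idx_k, :].T
            for k in range(n_syn):
                du_raw[rows, cols_m, nW + k * P + rows] = W[:, k][None, :]
            alf = self.f_alpha[:, None, None]
            du_f = (1 - alf) * du_raw[self.f_lo] + alf * du_raw[self.f_lo + 1]
            du_f *= _sclamp_grad(ur_f, self.u_min, self.u_max)[:, :, None]
            if hs:
                almf = self.fm_alpha[:, None, None]
                dum_f = (1 - almf) * du_raw[self.fm_lo] \
                    + almf * du_raw[self.fm_lo + 1]
                dum_f *= _sclamp_grad(urm_f, self.u_min, self.u_max)[:, :, None]
            else:
                dum_f = np.zeros((self.F - 1, m, D))
        return u_raw, ur_f, u_f, um_f, du_raw, du_f, dum_f

    def propagate(self, W, H, a0, l0, need_sens: bool, nW: int):
        """Condensed march of the defect equations (compiled fast path)."""
        m = len(self.mset)
        S = self.S
        u_raw, ur_f, u_f, um_f, du_raw, du_f, dum_f = \
            self._fine_inputs(W, H, need_sens, nW)
        if not need_sens:
            du_f = np.zeros((self.F, m, 0))
            dum_f = np.zeros((self.F - 1, m, 0))
        hs = self.scheme == "hermite-simpson"
        a_f, l_f, Sa_f, Sl_f = _kernels.propagate_kernel(
            hs, need_sens, self.dt_fine,
            np.ascontiguousarray(u_f), np.ascontiguousarray(um_f),
            np.ascontiguousarray(du_f), np.ascontiguousarray(dum_f),
            np.ascontiguousarray(self.lmt_fine),
            np.ascontiguousarray(self.lmt_fine_mid),
            np.ascontiguousarray(a0, dtype=float),
            np.ascontiguousarray(l0, dtype=float),
            *self._kernel_consts(),
        )
        out = {"a": a_f[::S], "l": l_f[::S],
               "u": _sclamp(u_raw, self.u_min, self.u_max), "u_raw": u_raw}
        if need_sens:
            out.update({"Sa": Sa_f[::S], "Sl": Sl_f[::S], "du_raw": du_raw})
        return out

    def step_interval(self, n: int, a_n, l_n, W, H):
        """Propagate states across one collocation interval (S substeps)."""
        m = len(self.mset)
        S = self.S
        _, _, u_f, um_f, _, _, _ = self._fine_inputs(W, H, False, 0)
        sl = slice(n * S, (n + 1) * S + 1)
        slm = slice(n * S, (n + 1) * S)
        a_s, l_s, _, _ = _kernels.propagate_kernel(
            self.scheme == "hermite-simpson", False, self.dt_fine,
            np.ascontiguousarray(u_f[sl]), np.ascontiguousarray(um_f[slm]),
            np.zeros((S + 1, m, 0)), np.zeros((S, m, 0)),
            np.ascontiguousarray(self.lmt_fine[sl]),
            np.ascontiguousarray(self.lmt_fine_mid[slm]),
            np.ascontiguousarray(a_n, dtype=float),
            np.ascontiguousarray(l_n, dtype=float),
            *self._kernel_consts(),
        )
        return a_s[-1], l_s[-1]

    @property
    def lmt_mid(self):
        # coarse midpoints coincide with fine midpoints when S == 1
        if self.S != 1:
            raise AttributeError("coarse midpoints undefined for S > 1")
        return self.lmt_fine_mid

    def propagate_py(self, W, H, a0, l0, need_sens: bool, nW: int):
        """Reference numpy march of the defect equations (single-substep).

        theta is the condition-local parameter vector
        [vec(W) (if free) | vec(H) | a0 | l0]; the returned sensitivity
        arrays have shape (P, m, D). Used for parity checks against the
        compiled kernel and as a fallback when numba is unavailable.
        """
        if self.S != 1:
            raise NotImplementedError(
                "the reference propagator supports n_substeps=1 only"
            )
        mset = self.mset
        m = len(mset)
        P, dt = self.P, self.dt
        n_syn = W.shape[1]
        u_raw, u, um_raw, um = self.excitations(W, H)
        lo_l = 0.25 * mset.l_opt
        hi_l = 1.78 * mset.l_opt

        a = np.empty((P, m))
        l = np.empty((P, m))
        a[0] = np.clip(a0, 0.005, 1.0)
        l[0] = np.clip(l0, lo_l, hi_l)

        D = 0
        Sa = Sl = du_raw_d = du = dum = None
        if need_sens:
            D = nW + n_syn * P + 2 * m
            du_raw_d, du, dum = self._du_blocks(W, H, u_raw, um_raw, nW, D)
            Sa = np.zeros((P, m, D))
            Sl = np.zeros((P, m, D))
            ia0 = nW + n_syn * P
            Sa[0, np.arange(m), ia0 + np.arange(m)] = 1.0
            Sl[0, np.arange(m), ia0 + m + np.arange(m)] = 1.0

        hs = self.scheme == "hermite-simpson"
        tol_a, tol_l = 1e-12, 1e-13

        for n in range(P - 1):
            u0, u1 = u[n], u[n + 1]
            an = a[n]
            f0 = self._fa(an, u0)
            f0_a, f0_u = self._fa_p(an, u0)
            if hs:
                uc = um[n]

                def res_a(x):
                    f1 = self._fa(x, u1)
                    f1_a, _ = self._fa_p(x, u1)
                    ac = 0.5 * (an + x) + dt / 8 * (f0 - f1)
                    fc = self._fa(ac, uc)
                    fc_a, _ = self._fa_p(ac, uc)
                    r = x - an - dt / 6 * (f0 + 4 * fc + f1)
                    dr = 1 - dt / 6 * (4 * fc_a * (0.5 - dt / 8 * f1_a) + f1_a)
                    return r, dr
            else:

                def res_a(x):
                    f1 = self._fa(x, u1)
                    f1_a, _ = self._fa_p(x, u1)
                    return x - an - dt / 2 * (f0 + f1), 1 - dt / 2 * f1_a

            a1 = _safeguarded_newton(res_a, an + dt * f0, 0.005, 1.0, tol_a)
            a[n + 1] = a1

            f1 = self._fa(a1, u1)
            f1_a, f1_u = self._fa_p(a1, u1)
            if hs:
                ac = 0.5 * (an + a1) + dt / 8 * (f0 - f1)
                fc = self._fa(ac, um[n])
                fc_a, fc_u = self._fa_p(ac, um[n])

            # fiber-length step; activation values now known at n, (mid,) n+1
            ln_ = l[n]
            lmt0, lmt1 = self.lmt[n], self.lmt[n + 1]
            g0 = self._fv(an, ln_, lmt0)
            if hs:
                lmtc = self.lmt_mid[n]

                def res_l(x):
                    g1 = self._fv(a1, x, lmt1)
                    _, g1_l = self._fv_p(a1, x, lmt1)
                    lc = 0.5 * (ln_ + x) + dt / 8 * (g0 - g1)
                    gc = self._fv(ac, lc, lmtc)
                    _, gc_l = self._fv_p(ac, lc, lmtc)
                    r = x - ln_ - dt / 6 * (g0 + 4 * gc + g1)
                    dr = 1 - dt / 6 * (4 * gc_l * (0.5 - dt / 8 * g1_l) + g1_l)
                    return r, dr
            else:

                def res_l(x):
                    g1 = self._fv(a1, x, lmt1)
                    _, g1_l = self._fv_p(a1, x, lmt1)
                    return x - ln_ - dt / 2 * (g0 + g1), 1 - dt / 2 * g1_l

            l1 = _safeguarded_newton(res_l, ln_ + dt * g0, lo_l, hi_l, tol_l)
            l[n + 1] = l1

            if not need_sens:
                continue

            # --- sensitivity updates (implicit function theorem) ---
            du0, du1 = du[n], du[n + 1]
            San = Sa[n]
            if hs:
                duc = dum[n]
                dR_da1 = 1 - dt / 6 * (4 * fc_a * (0.5 - dt / 8 * f1_a) + f1_a)
                rhs = (
                    (-1 - dt / 6 * (f0_a + 4 * fc_a * (0.5 + dt / 8 * f0_a)))[:, None] * San
                    + (-dt / 6 * f0_u * (1 + dt / 2 * fc_a))[:, None] * du0
                    + (-dt / 6 * 4 * fc_u)[:, None] * duc
                    + (-dt / 6 * f1_u * (1 - dt / 2 * fc_a))[:, None] * du1
                )
                Sa1 = -rhs / dR_da1[:, None]
                Sac = (0.5 * (San + Sa1)
                       + dt / 8 * (f0_a[:, None] * San + f0_u[:, None] * du0
                                   - f1_a[:, None] * Sa1 - f1_u[:, None] * du1))
            else:
                dR_da1 = 1 - dt / 2 * f1_a
                rhs = ((-1 - dt / 2 * f0_a)[:, None] * San
                       + (-dt / 2 * f0_u)[:, None] * du0
                       + (-dt / 2 * f1_u)[:, None] * du1)
                Sa1 = -rhs / dR_da1[:, None]
            Sa[n + 1] = Sa1

            g0_a, g0_l = self._fv_p(an, ln_, lmt0)
            g1v = self._fv(a1, l1, lmt1)
            g1_a, g1_l = self._fv_p(a1, l1, lmt1)
            Sln = Sl[n]
            if hs:
                lc = 0.5 * (ln_ + l1) + dt / 8 * (g0 - g1v)
                gc_a, gc_l = self._fv_p(ac, lc, lmtc)
                dR_dl1 = 1 - dt / 6 * (4 * gc_l * (0.5 - dt / 8 * g1_l) + g1_l)
                rhs = (
                    (-1 - dt / 6 * (g0_l + 4 * gc_l * (0.5 + dt / 8 * g0_l)))[:, None] * Sln
                    + (-dt / 6 * g0_a * (1 + dt / 2 * gc_l))[:, None] * San
                    + (-dt / 6 * g1_a * (1 - dt / 2 * gc_l))[:, None] * Sa1
                    + (-dt / 6 * 4 * gc_a)[:, None] * Sac
                )
                Sl1 = -rhs / dR_dl1[:, None]
            else:
                dR_dl1 = 1 - dt / 2 * g1_l
                rhs = ((-1 - dt / 2 * g0_l)[:, None] * Sln
                       + (-dt / 2 * g0_a)[:, None] * San
                       + (-dt / 2 * g1_a)[:, None] * Sa1)
                Sl1 = -rhs / dR_dl1[:, None]
            Sl[n + 1] = Sl1

        out = {"a": a, "l": l, "u": u, "u_raw": u_raw}
        if need_sens:
            out.update({"Sa": Sa, "Sl": Sl, "du_raw": du_raw_d})
        return out

    def forces_and_moments(self, l):
        F = mm.fiber_equilibrium_force(l, self.lmt, self.mset)     # (P, m)
        M = joint_moments(F, self.R)                                # (P, NJ)
        return F, M

    def defects(self, a, l, W, H):
        """Per-interval defect residuals: node state minus the integrated
        image of the previous node state, (P-1, 2m)."""
        da = np.empty((self.P - 1, len(self.mset)))
        dl = np.empty_like(da)
        for n in range(self.P - 1):
            a_pred, l_pred = self.step_interval(n, a[n], l[n], W, H)
            da[n] = a[n + 1] - a_pred
            dl[n] = l[n + 1] - l_pred
        return np.concatenate([da, dl], axis=1)


# ---------------------------------------------------------------------------
# the transcribed NLP
# ---------------------------------------------------------------------------

class CollocationNLP:
    """The transcribed nonlinear program.

    Full decision vector (the transcription contract): ``W`` (unless
    frozen), then per condition the controls ``h`` (n_syn * P), activations
    ``a`` (m * P) and fiber lengths ``l`` (m * P). Constraints are the
    2 * m * (P-1) defect equations per condition plus box bounds; the
    objective is :func:`cost_function`. Conditions share only ``W``.
    """

    def __init__(self, spec: OcpSpec, grid: CollocationGrid):
        self.spec = spec
        self.grid = grid
        self.mset = spec.muscles
        self.m = len(spec.muscles)
        self.n_syn = spec.n_syn
        self.conditions = [t.condition for t in spec.trials]
        if set(self.conditions) != set(grid.times):
            raise ValueError("grid conditions do not match trials")
        self.cond = {
            t.condition: _CondProblem(t, grid.times[t.condition], spec.muscles,
                                      spec.scheme, spec.u_min, spec.u_max,
                                      n_substeps=spec.n_substeps)
            for t in spec.trials
        }
        self.free_W = spec.fixed_W is None
        self.nW = self.m * self.n_syn if self.free_W else 0
        self.options = {**DEFAULT_OPTIONS, **spec.options}

        # full decision-vector layout
        self._layout = {}
        off = 0
        if self.free_W:
            self._layout["W"] = (0, self.nW)
            off = self.nW
        for c in self.conditions:
            P = self.cond[c].P
            self._layout[("h", c)] = (off, off + self.n_syn * P); off += self.n_syn * P
            self._layout[("a", c)] = (off, off + self.m * P); off += self.m * P
            self._layout[("l", c)] = (off, off + self.m * P); off += self.m * P
        self.n_vars = off
        self.n_defects = sum(2 * self.m * (self.cond[c].P - 1) for c in self.conditions)

    # -- full-vector interface ---------------------------------------------
    def pack(self, W, H, A, L) -> np.ndarray:
        z = np.empty(self.n_vars)
        if self.free_W:
            z[0:self.nW] = np.asarray(W, dtype=float).ravel()
        for c in self.conditions:
            P = self.cond[c].P
            i0, i1 = self._layout[("h", c)]
            z[i0:i1] = np.asarray(H[c], dtype=float).ravel()
            i0, i1 = self._layout[("a", c)]
            z[i0:i1] = np.asarray(A[c], dtype=float).T.ravel()
            i0, i1 = self._layout[("l", c)]
            z[i0:i1] = np.asarray(L[c], dtype=float).T.ravel()
        return z

    def unpack(self, z):
        z = np.asarray(z, dtype=float)
        W = (z[0:self.nW].reshape(self.m, self.n_syn)
             if self.free_W else self.spec.fixed_W)
        H, A, L = {}, {}, {}
        for c in self.conditions:
            P = self.cond[c].P
            i0, i1 = self._layout[("h", c)]
            H[c] = z[i0:i1].reshape(self.n_syn, P)
            i0, i1 = self._layout[("a", c)]
            A[c] = z[i0:i1].reshape(self.m, P).T
            i0, i1 = self._layout[("l", c)]
            L[c] = z[i0:i1].reshape(self.m, P).T
        return W, H, A, L

    def bounds(self):
        lo = np.full(self.n_vars, -np.inf)
        hi = np.full(self.n_vars, np.inf)
        if self.free_W:
            lo[0:self.nW] = 0.0
        for c in self.conditions:
            i0, i1 = self._layout[("h", c)]
            lo[i0:i1] = 0.0
            i0, i1 = self._layout[("a", c)]
            lo[i0:i1], hi[i0:i1] = self.spec.u_min, 1.0
            i0, i1 = self._layout[("l", c)]
            lo[i0:i1] = 0.25 * np.tile(self.mset.l_opt, self.cond[c].P)
            hi[i0:i1] = 1.78 * np.tile(self.mset.l_opt, self.cond[c].P)
        return lo, hi

    def defects(self, z) -> np.ndarray:
        W, H, A, L = self.unpack(z)
        out = []
        for c in self.conditions:
            cp = self.cond[c]
            out.append(cp.defects(A[c], L[c], W, H[c]).ravel())
        return np.concatenate(out)

    def objective(self, z) -> float:
        W, H, A, L = self.unpack(z)
        M = {}
        for c in self.conditions:
            _, M[c] = self.cond[c].forces_and_moments(L[c])
        return cost_function(M, {c: self.cond[c].M_star for c in self.conditions},
                             {c: A[c] for c in self.conditions}, self.spec.K)

    # -- condensed (reduced) interface --------------------------------------
    @property
    def n_reduced(self) -> int:
        return self.nW + sum(self.n_syn * self.cond[c].P + 2 * self.m
                             for c in self.conditions)

    def reduced_bounds(self):
        lo, hi = [], []
        if self.free_W:
            lo += [0.0] * self.nW
            hi += [np.inf] * self.nW
        for c in self.conditions:
            P = self.cond[c].P
            lo += [0.0] * (self.n_syn * P)
            hi += [np.inf] * (self.n_syn * P)
            lo += [0.01] * self.m + list(0.4 * self.mset.l_opt)
            hi += [1.0] * self.m + list(1.7 * self.mset.l_opt)
        return np.array(lo), np.array(hi)

    def reduced_from_guess(self, guess: dict) -> np.ndarray:
        parts = []
        if self.free_W:
            parts.append(np.asarray(guess["W"], dtype=float).ravel())
        for c in self.conditions:
            parts.append(np.asarray(guess["H"][c], dtype=float).ravel())
            a = np.asarray(guess["a"][c], dtype=float)
            l = np.asarray(guess["l"][c], dtype=float)
            parts.append(np.clip(a[0], 0.01, 1.0))
            parts.append(np.clip(l[0], 0.4 * self.mset.l_opt, 1.7 * self.mset.l_opt))
        return np.concatenate(parts)

    def split_reduced(self, x):
        x = np.asarray(x, dtype=float)
        W = (x[0:self.nW].reshape(self.m, self.n_syn)
             if self.free_W else self.spec.fixed_W)
        off = self.nW
        H, a0, l0 = {}, {}, {}
        for c in self.conditions:
            P = self.cond[c].P
            H[c] = x[off:off + self.n_syn * P].reshape(self.n_syn, P)
            off += self.n_syn * P
            a0[c] = x[off:off + self.m]; off += self.m
            l0[c] = x[off:off + self.m]; off += self.m
        return W, H, a0, l0

    def _eval(self, x, need_jac: bool):
        """Residual vector (and Jacobian) of the condensed least-squares problem."""
        W, H, a0, l0 = self.split_reduced(x)
        K = self.spec.K
        w_u = self.options["penalty_u"]
        res_blocks, jac_blocks = [], []
        traj = {}
        for ci, c in enumerate(self.conditions):
            cp = self.cond[c]
            P, m = cp.P, self.m
            out = cp.propagate(W, H[c], a0[c], l0[c], need_jac, self.nW)
            F, M = cp.forces_and_moments(out["l"])
            traj[c] = {"a": out["a"], "l": out["l"], "u": out["u"], "F": F, "M": M}
            r_m = (M - cp.M_star).ravel()
            hinge = np.maximum(out["u_raw"] - self.spec.u_max, 0.0)
            r_u = w_u * hinge.ravel()
            block = [r_m]
            if K > 0:
                block.append(np.sqrt(K) * out["a"].ravel())
            block.append(r_u)
            res_blocks.append(np.concatenate(block))
            if need_jac:
                D = self.nW + self.n_syn * P + 2 * m
                dF = mm._dF_dl(out["l"], cp.lmt, self.mset)           # (P, m)
                dFdth = dF[:, :, None] * out["Sl"]                    # (P, m, D)
                dM = np.einsum("pmj,pmd->pjd", cp.R, dFdth)           # (P, NJ, D)
                Jm = dM.reshape(P * cp.n_dofs, D)
                rows = [Jm]
                if K > 0:
                    rows.append(np.sqrt(K) * out["Sa"].reshape(P * m, D))
                Ju = w_u * (hinge > 0)[:, :, None] * out["du_raw"]
                rows.append(Ju.reshape(P * m, D))
                Jloc = np.vstack(rows)
                # scatter local columns into the global reduced vector
                Jglob = np.zeros((Jloc.shape[0], self.n_reduced))
                if self.nW:
                    Jglob[:, 0:self.nW] = Jloc[:, 0:self.nW]
                off = self.nW
                for cj in self.conditions:
                    Pj = self.cond[cj].P
                    if cj == c:
                        Jglob[:, off:off + self.n_syn * Pj + 2 * m] = \
                            Jloc[:, self.nW:]
                    off += self.n_syn * Pj + 2 * m
                jac_blocks.append(Jglob)
        r = np.concatenate(res_blocks)
        if need_jac:
            return r, np.vstack(jac_blocks), traj
        return r, None, traj


def transcribe(spec: OcpSpec, grid: CollocationGrid | None = None) -> CollocationNLP:
    """Transcribe the OCP onto the collocation grid (built from the trials
    if not supplied)."""
    if grid is None:
        grid = CollocationGrid.from_trials(spec.trials)
    return CollocationNLP(spec, grid)


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def solve(nlp: CollocationNLP, guess: dict, options: dict | None = None) -> SolveResult:
    """Solve the transcribed problem from an initial guess.

    ``guess`` is a dict with keys ``W`` (m, n_syn), ``H`` (condition ->
    (n_syn, P)), ``a`` and ``l`` (condition -> (P, m) state trajectories;
    only the initial rows seed the condensed vector). Returns the best
    iterate with diagnostics; failure statuses are reported, never raised.
    """
    t_start = time.perf_counter()
    opts = {**nlp.options, **(options or {})}
    x0 = nlp.reduced_from_guess(guess)
    lo, hi = nlp.reduced_bounds()
    x0 = np.clip(x0, lo, hi)

    def fun(x):
        r, _, _ = nlp._eval(x, need_jac=False)
        return r

    def jac(x):
        _, J, _ = nlp._eval(x, need_jac=True)
        return J

    r0 = fun(x0)
    guess_obj = float(r0 @ r0)
    try:
        sol = least_squares(
            fun, x0, jac=jac, bounds=(lo, hi), method="trf",
            max_nfev=opts["max_nfev"], ftol=opts["ftol"], xtol=opts["xtol"],
            gtol=opts["gtol"], x_scale="jac", verbose=opts.get("verbose", 0),
        )
        x_best, status, message, nfev = sol.x, sol.status, sol.message, sol.nfev
        success = sol.status >= 0      # a usable iterate was produced
        converged = sol.status > 0     # a convergence test fired
    except Exception as exc:  # solver failure: report the guess as last iterate
        x_best, status, message, nfev = x0, -10, f"solver error: {exc}", 0
        success = converged = False

    r, _, traj = nlp._eval(x_best, need_jac=False)
    W, H, a0, l0 = nlp.split_reduced(x_best)
    structure = SynergyStructure(W.copy(), {c: H[c].copy() for c in nlp.conditions})
    states = {c: {"a": traj[c]["a"], "l": traj[c]["l"]} for c in nlp.conditions}
    moments = {c: traj[c]["M"] for c in nlp.conditions}
    exp_moments = {c: nlp.cond[c].M_star for c in nlp.conditions}
    m_cost = cost_function(moments, exp_moments,
                           {c: states[c]["a"] for c in nlp.conditions}, 0.0)
    a_cost = float(sum(np.sum(states[c]["a"] ** 2) for c in nlp.conditions))
    objective = m_cost + nlp.spec.K * a_cost

    from .workflows import nrmse  # local import to avoid a cycle
    err = nrmse(moments, exp_moments)

    z = nlp.pack(W, {c: H[c] for c in nlp.conditions},
                 {c: states[c]["a"] for c in nlp.conditions},
                 {c: states[c]["l"] for c in nlp.conditions})
    max_defect = float(np.max(np.abs(nlp.defects(z)))) if nlp.n_defects else 0.0

    return SolveResult(
        structure=structure,
        states=states,
        moments=moments,
        exp_moments=exp_moments,
        times={c: nlp.cond[c].times for c in nlp.conditions},
        nrmse=err,
        moment_cost=m_cost,
        activation_cost=a_cost,
        objective=objective,
        K=nlp.spec.K,
        success=success,
        converged=converged,
        status=status,
        message=message,
        n_iter=nfev,
        max_defect=max_defect,
        guess_objective=guess_obj,
        wall_time_s=time.perf_counter() - t_start,
    )
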