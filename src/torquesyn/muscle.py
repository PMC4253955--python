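"""Hill-type muscle-tendon model: force curves, contraction and activation dynamics.

The model follows the curve family standard in musculoskeletal
simulators: a Gaussian active
force-length curve, an exponential passive force-length curve, an
exponential-toe/linear tendon curve, a hyperbolic force-velocity relation
(inverted in closed form so fiber velocity is an explicit function of the
force state), constant-thickness pennation, and a two-regime first-order
activation law smoothed with a tanh blend so that every function exposed here
is continuously differentiable — a requirement of the gradient-based
collocation solver built on top.

All curve constants are recorded on :class:`MuscleParams` so the model is
fully specified by this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MuscleParams",
    "MuscleState",
    "MuscleSet",
    "activation_derivative",
    "activation_rate",
    "activation_rate_partials",
    "tendon_force",
    "tendon_force_norm",
    "tendon_stiffness_norm",
    "active_force_length",
    "passive_force_length",
    "cos_pennation",
    "fiber_equilibrium_force",
    "fiber_velocity",
    "fiber_velocity_partials",
    "equilibrium_fiber_length",
    "clamp_counter",
    "load_muscle_params",
]

# Operational bounds on activation and excitation; values below 0.01 create
# singularities in the force-velocity inversion (a multiplies the isometric
# capacity in its denominator).
A_MIN = 0.01
A_MAX = 1.0

# Normalized fiber length is clamped to this interval inside curve
# evaluations; excursions are tallied on ``clamp_counter``.
LN_LO = 0.05
LN_HI = 1.8


class _ClampCounter:
    """Tallies normalized-fiber-length clamps during curve evaluation."""

    def __init__(self) -> None:
        self.count = 0

    def add(self, n: int) -> None:
        self.count += int(n)

    def reset(self) -> None:
        self.count = 0


clamp_counter = _ClampCounter()


@dataclass(frozen=True)
class MuscleParams:
    """Constants of one muscle-tendon actuator.

    Parameters
    ----------
    f_max : maximum isometric force, N.
    l_opt : optimal fiber length, m.
    alpha_opt : pennation angle at optimal fiber length, rad.
    l_slack : tendon slack length, m.
    eps_t_max : tendon strain at which tendon force equals ``f_max``.
    v_max : maximum shortening velocity, optimal fiber lengths / s.
    tau_act, tau_deact : activation / deactivation time constants, s.

    The remaining fields are shape constants of the force curves:
    ``gamma_fl`` (width of the Gaussian active force-length curve), ``k_pe``
    and ``eps_m0`` (passive exponential shape and strain at ``f_max``),
    ``f_toe``/``k_toe`` (tendon toe-region force fraction and exponent),
    ``a_f`` (force-velocity curvature) and ``f_len`` (maximum normalized
    force under lengthening).
    """

    name: str = "muscle"
    f_max: float = 1000.0
    l_opt: float = 0.10
    alpha_opt: float = 0.0
    l_slack: float = 0.20
    eps_t_max: float = 0.04
    v_max: float = 10.0
    tau_act: float = 0.020
    tau_deact: float = 0.050
    gamma_fl: float = 0.45
    k_pe: float = 4.0
    eps_m0: float = 0.6
    f_toe: float = 0.33
    k_toe: float = 3.0
    a_f: float = 0.25
    f_len: float = 1.4
    act_blend: float = 40.0

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError(f"f_max must be positive, got {self.f_max}")
        if not self.l_opt > 0:
            raise ValueError(f"l_opt must be positive, got {self.l_opt}")
        if self.l_slack < 0:
            raise ValueError(f"l_slack must be non-negative, got {self.l_slack}")
        if not 0 < self.eps_t_max < 1:
            raise ValueError(f"eps_t_max must lie in (0, 1), got {self.eps_t_max}")
        if not 0 <= self.alpha_opt < np.pi / 2:
            raise ValueError(f"alpha_opt must lie in [0, pi/2), got {self.alpha_opt}")
        if not (self.tau_act > 0 and self.tau_deact > 0):
            raise ValueError("activation time constants must be positive")
        if not self.v_max > 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")


@dataclass
class MuscleState:
    """Dynamic state of one muscle: activation and fiber length."""

    a: float
    l: float

    def __post_init__(self) -> None:
        if not A_MIN <= self.a <= A_MAX:
            raise ValueError(f"activation {self.a} outside [{A_MIN}, {A_MAX}]")
        if not self.l > 0:
            raise ValueError(f"fiber length {self.l} must be positive")


class MuscleSet:
    """A stack of muscles with parameter fields exposed as numpy arrays.

    Every scalar field of :class:`MuscleParams` becomes a length-``m`` array
    attribute, so the curve functions below vectorize across the whole set.
    """

    def __init__(self, muscles: list[MuscleParams]):
        if not muscles:
            raise ValueError("empty muscle list")
        self.muscles = list(muscles)
        self.names = [p.name for p in muscles]
        for f in fields(MuscleParams):
            if f.name == "name":
                continue
            setattr(self, f.name, np.array([getattr(p, f.name) for p in muscles]))

    def __len__(self) -> int:
        return len(self.muscles)

    def __getitem__(self, i: int) -> MuscleParams:
        return self.muscles[i]


# ---------------------------------------------------------------------------
# activation dynamics (f3)
# ---------------------------------------------------------------------------

def activation_rate(a, u, params):
    """da/dt of the smoothed two-regime first-order activation law.

    The rate is ``(u - a) * r`` where ``r`` blends smoothly between
    ``1/tau_act`` (excitation above activation) and ``1/tau_deact``
    (below), with blend ``0.5 + 0.5*tanh(act_blend*(u - a))``.
    """
    x = np.asarray(u, dtype=float) - np.asarray(a, dtype=float)
    w = 0.5 + 0.5 * np.tanh(params.act_blend * x)
    r = w / params.tau_act + (1.0 - w) / params.tau_deact
    return x * r


def activation_rate_partials(a, u, params):
    """(d/da, d/du) of :func:`activation_rate` — exact."""
    x = np.asarray(u, dtype=float) - np.asarray(a, dtype=float)
    b = params.act_blend
    t = np.tanh(b * x)
    w = 0.5 + 0.5 * t
    r = w / params.tau_act + (1.0 - w) / params.tau_deact
    dr_dx = 0.5 * b * (1.0 - t * t) * (1.0 / params.tau_act - 1.0 / params.tau_deact)
    dfdx = r + x * dr_dx
    return -dfdx, dfdx


def activation_derivative(a: float, u: float, params: MuscleParams) -> float:
    """Validated activation dynamics; raises on out-of-bounds state or drive."""
    if not np.all((np.asarray(a) >= A_MIN) & (np.asarray(a) <= A_MAX)):
        raise ValueError(f"activation a={a} outside [{A_MIN}, {A_MAX}]")
    if not np.all((np.asarray(u) >= A_MIN) & (np.asarray(u) <= A_MAX)):
        raise ValueError(f"excitation u={u} outside [{A_MIN}, {A_MAX}]")
    return activation_rate(a, u, params)


# ---------------------------------------------------------------------------
# tendon (series elastic element)
# ---------------------------------------------------------------------------

def _tendon_consts(params):
    eps0 = params.eps_t_max
    eps_toe = 0.609 * eps0
    # linear-region slope chosen so the curve passes exactly through
    # (eps_t_max, f_max) — the definition of the FmaxTendonStrain parameter.
    k_lin = (1.0 - params.f_toe) / (eps0 - eps_toe)
    return eps_toe, k_lin


def tendon_force_norm(eps_t, params):
    """Tendon force / f_max as a function of tendon strain."""
    eps_t = np.asarray(eps_t, dtype=float)
    if not np.all(np.isfinite(eps_t)):
        raise ValueError("non-finite tendon strain")
    eps_toe, k_lin = _tendon_consts(params)
    c = params.f_toe / (np.exp(params.k_toe) - 1.0)
    toe = c * (np.expm1(params.k_toe * np.minimum(eps_t, eps_toe) / eps_toe))
    lin = params.f_toe + k_lin * (eps_t - eps_toe)
    out = np.where(eps_t <= eps_toe, toe, lin)
    return np.where(eps_t <= 0.0, 0.0, out)


def tendon_stiffness_norm(eps_t, params):
    """d(tendon_force_norm)/d(strain)."""
    eps_t = np.asarray(eps_t, dtype=float)
    eps_toe, k_lin = _tendon_consts(params)
    c = params.f_toe / (np.exp(params.k_toe) - 1.0)
    toe = c * params.k_toe / eps_toe * np.exp(
        params.k_toe * np.minimum(eps_t, eps_toe) / eps_toe
    )
    out = np.where(eps_t <= eps_toe, toe, k_lin)
    return np.where(eps_t <= 0.0, 0.0, out)


def tendon_force(eps_t, params):
    """Tendon force in N at strain ``eps_t``; zero when slack."""
    return params.f_max * tendon_force_norm(eps_t, params)


# ---------------------------------------------------------------------------
# fiber force-length curves (f1)
# ---------------------------------------------------------------------------

def _clamp_ln(ln):
    ln = np.asarray(ln, dtype=float)
    n_out = int(np.count_nonzero((ln < LN_LO) | (ln > LN_HI)))
    if n_out:
        clamp_counter.add(n_out)
    return np.clip(ln, LN_LO, LN_HI)


def active_force_length(ln, params):
    """Normalized active force-length curve (Gaussian, peak 1 at ln = 1)."""
    ln = _clamp_ln(ln)
    return np.exp(-((ln - 1.0) ** 2) / params.gamma_fl)


def passive_force_length(ln, params):
    """Normalized passive force-length curve (exponential, zero below slack)."""
    ln = _clamp_ln(ln)
    num = np.expm1(params.k_pe * (ln - 1.0) / params.eps_m0)
    return np.maximum(num, 0.0) / np.expm1(params.k_pe)


def cos_pennation(l, params):
    """cos of pennation at fiber length ``l`` (constant-thickness model)."""
    h = params.l_opt * np.sin(params.alpha_opt)
    l = np.asarray(l, dtype=float)
    s = np.clip(h / np.maximum(l, 1e-9), 0.0, 0.99)
    return np.sqrt(1.0 - s * s)


def _d_lcos_dl(l, params):
    """d(l*cos(pennation))/dl = l / (l*cos(pennation))."""
    h = params.l_opt * np.sin(params.alpha_opt)
    l = np.asarray(l, dtype=float)
    proj = np.sqrt(np.maximum(l * l - h * h, 1e-12))
    return l / proj


def fiber_equilibrium_force(l, L_mt, params):
    """Tendon force (N) implied by the muscle-tendon geometry.

    Tendon length is ``L_mt - l*cos(pennation(l))``; its strain drives the
    tendon curve. Raises when the configuration leaves no room for the
    tendon.
    """
    l = np.asarray(l, dtype=float)
    L_mt = np.asarray(L_mt, dtype=float)
    if np.any(l <= 0) or np.any(L_mt <= 0):
        raise ValueError("fiber and muscle-tendon lengths must be positive")
    lt = L_mt - l * cos_pennation(l, params)
    if np.any(lt <= 0):
        raise ValueError(
            f"infeasible geometry: tendon length {np.min(lt):.4g} m <= 0 "
            f"(muscle {getattr(params, 'name', '?')})"
        )
    eps = (lt - params.l_slack) / params.l_slack
    return tendon_force(eps, params)


def _dF_dl(l, L_mt, params):
    """d(fiber_equilibrium_force)/d(fiber length), N/m — exact."""
    lt = L_mt - np.asarray(l) * cos_pennation(l, params)
    eps = (lt - params.l_slack) / params.l_slack
    return (
        -params.f_max
        * tendon_stiffness_norm(eps, params)
        * _d_lcos_dl(l, params)
        / params.l_slack
    )


# ---------------------------------------------------------------------------
# force-velocity inversion (f2)
# ---------------------------------------------------------------------------

def _velocity_from_active_force(a, fl, fm_act, params):
    """Normalized fiber velocity (l_opt/s) from the normalized active force.

    Closed-form inversion of the hyperbolic force-velocity relation:
    concentric branch for ``fm_act`` below the isometric capacity
    ``a*fl``, eccentric branch above it, with linear extrapolation beyond
    95% of the eccentric asymptote ``a*fl*f_len`` (and below zero force) to
    keep the map monotone and finite everywhere.
    """
    a = np.asarray(a, dtype=float)
    fl = np.asarray(fl, dtype=float)
    fm = np.asarray(fm_act, dtype=float)
    fa = np.maximum(a * fl, 1e-6)
    vs = (0.25 + 0.75 * a) * params.v_max  # velocity scale, l_opt/s

    def core(f):
        b_con = fa + f / params.a_f
        b_ecc = (2.0 + 2.0 / params.a_f) * (fa * params.f_len - f) / (
            params.f_len - 1.0
        )
        b = np.where(f <= fa, b_con, b_ecc)
        return vs * (f - fa) / b

    f_hi = 0.95 * fa * params.f_len
    f_eval = np.clip(fm, 0.0, f_hi)
    v = core(f_eval)
    # analytic slope dv/df on each branch for the linear extensions
    b_con0 = fa  # at f = 0
    slope_lo = vs * (b_con0 - (0.0 - fa) / params.a_f) / (b_con0 * b_con0)
    b_hi = (2.0 + 2.0 / params.a_f) * (fa * params.f_len - f_hi) / (params.f_len - 1.0)
    db_hi = -(2.0 + 2.0 / params.a_f) / (params.f_len - 1.0)
    slope_hi = vs * (b_hi - (f_hi - fa) * db_hi) / (b_hi * b_hi)
    v = np.where(fm < 0.0, core(np.zeros_like(fm)) + slope_lo * fm, v)
    v = np.where(fm > f_hi, core(f_hi * np.ones_like(fm)) + slope_hi * (fm - f_hi), v)
    return _saturate_velocity(v, params)


def _saturate_velocity(v, params):
    """Smooth, C1 saturation of normalized fiber velocity.

    Exactly linear for |v| <= v_max; beyond that rolls off with a tanh to a
    hard cap of 1.6 * v_max, so the linear extrapolations of the
    force-velocity inversion can never produce runaway velocities at very
    low activation.
    """
    v1 = params.v_max
    span = 0.6 * params.v_max
    av = np.abs(v)
    excess = np.maximum(av - v1, 0.0)
    sat = v1 + span * np.tanh(excess / span)
    return np.where(av <= v1, v, np.sign(v) * sat)


def fiber_velocity(a, l, L_mt, params):
    """dl/dt (m/s) from the fiber/tendon force balance.

    The tendon force implied by the geometry, projected along the fiber and
    stripped of the passive component, yields the active normalized force;
    the force-velocity relation is then inverted in closed form.
    """
    a = np.asarray(a, dtype=float)
    l = np.asarray(l, dtype=float)
    ft = fiber_equilibrium_force(l, L_mt, params) / params.f_max
    cosa = cos_pennation(l, params)
    ln = l / params.l_opt
    fl = active_force_length(ln, params)
    fpe = passive_force_length(ln, params)
    fm_act = ft / cosa - fpe
    return _velocity_from_active_force(a, fl, fm_act, params) * params.l_opt


def fiber_velocity_partials(a, l, L_mt, params, h_rel=1e-6):
    """(dv/da, dv/dl) by central differences of :func:`fiber_velocity`.

    The closed-form inversion is piecewise-analytic; central differences at
    step ``h_rel * l_opt`` give derivatives accurate to ~1e-8 relative,
    sufficient for Newton steps and Gauss-Newton sensitivities.
    """
    ha = 1e-6
    hl = h_rel * params.l_opt
    dva = (fiber_velocity(a + ha, l, L_mt, params)
           - fiber_velocity(a - ha, l, L_mt, params)) / (2 * ha)
    dvl = (fiber_velocity(a, l + hl, L_mt, params)
           - fiber_velocity(a, l - hl, L_mt, params)) / (2 * hl)
    return dva, dvl


def equilibrium_fiber_length(a, L_mt, params):
    """Fiber length at the isometric equilibrium for activation ``a``.

    Solves tendon force = (active + passive) fiber force along the tendon at
    zero fiber velocity, by bracketed root finding on the fiber length.
    """

    def resid(l, lmt, ai):
        cosa = cos_pennation(l, params)
        ln = l / params.l_opt
        fib = (ai * active_force_length(ln, params)
               + passive_force_length(ln, params)) * cosa
        lt = lmt - l * cosa
        eps = (lt - params.l_slack) / params.l_slack
        return tendon_force_norm(eps, params) - fib

    if isinstance(params, MuscleSet):
        a_arr = np.broadcast_to(np.asarray(a, dtype=float), (len(params),))
        L_arr = np.broadcast_to(np.asarray(L_mt, dtype=float), (len(params),))
        return np.array([
            equilibrium_fiber_length(float(a_arr[i]), float(L_arr[i]), params[i])
            for i in range(len(params))
        ])
    scalar = np.isscalar(a) and np.isscalar(L_mt)
    a = np.atleast_1d(np.asarray(a, dtype=float))
    L_mt = np.atleast_1d(np.asarray(L_mt, dtype=float))
    a, L_mt = np.broadcast_arrays(a, L_mt)
    out = np.empty(a.shape)
    lo, hi = 0.3 * params.l_opt, 1.75 * params.l_opt
    for i in np.ndindex(a.shape):
        rl, rh = resid(lo, L_mt[i], a[i]), resid(hi, L_mt[i], a[i])
        if rl * rh > 0:
            # no sign change: pick the bound with the smaller imbalance
            out[i] = lo if abs(rl) < abs(rh) else hi
        else:
            out[i] = brentq(resid, lo, hi, args=(L_mt[i], a[i]), xtol=1e-12)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# parameter I/O
# ---------------------------------------------------------------------------

def load_muscle_params(path: str | Path) -> MuscleSet:
    """Read a muscle parameter table (CSV, one row per muscle).

    Columns must be named exactly as :class:`MuscleParams` fields; the curve
    shape constants are optional and default to the documented values.
    """
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError("muscle parameter table needs a 'name' column")
    known = {f.name for f in fields(MuscleParams)}
    unknown = set(df.columns) - known
    if unknown:
        raise ValueError(f"unknown muscle parameter columns: {sorted(unknown)}")
    return MuscleSet(
        [MuscleParams(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]
    )


def save_muscle_params(mset: MuscleSet, path: str | Path) -> None:
    """Write a muscle parameter table as CSV (inverse of load_muscle_params)."""
    rows = []
    for p in mset.muscles:
        rows.append({f.name: getattr(p, f.name) for f in fields(MuscleParams)})
    pd.DataFrame(rows).to_csv(path, index=False)
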