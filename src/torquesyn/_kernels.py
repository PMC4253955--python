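"""Compiled inner loops for the condensed collocation propagation.

The muscle-curve formulas here mirror :mod:`torquesyn.muscle` exactly (the
test suite asserts parity); they are restated in scalar form because the
defect recursion is sequential in time and its per-interval Newton solves
dominate the solver's runtime. Everything else (residual assembly,
Jacobian scatter, the trust-region iteration) stays in numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speedup, soft dep
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

LN_LO = 0.05
LN_HI = 1.8


@njit(cache=True)
def _fa_scalar(a, u, tau_act, tau_deact, blend):
    x = u - a
    w = 0.5 + 0.5 * math.tanh(blend * x)
    return x * (w / tau_act + (1.0 - w) / tau_deact)


@njit(cache=True)
def _fa_partials(a, u, tau_act, tau_deact, blend):
    x = u - a
    t = math.tanh(blend * x)
    w = 0.5 + 0.5 * t
    r = w / tau_act + (1.0 - w) / tau_deact
    dr = 0.5 * blend * (1.0 - t * t) * (1.0 / tau_act - 1.0 / tau_deact)
    dfdx = r + x * dr
    return -dfdx, dfdx


@njit(cache=True)
def _ft_norm(eps, f_toe, k_toe, eps_toe, k_lin):
    if eps <= 0.0:
        return 0.0
    if eps <= eps_toe:
        c = f_toe / (math.exp(k_toe) - 1.0)
        return c * (math.expm1(k_toe * eps / eps_toe))
    return f_toe + k_lin * (eps - eps_toe)


@njit(cache=True)
def _fv_scalar(a, l, lmt, l_opt, hpen, l_slack, f_toe, k_toe, eps_toe, k_lin,
               gamma_fl, k_pe, eps_m0, a_f, f_len, v_max):
    # pennation (constant thickness)
    s = hpen / l if l > 1e-9 else 0.99
    if s > 0.99:
        s = 0.99
    if s < 0.0:
        s = 0.0
    cosa = math.sqrt(1.0 - s * s)
    # tendon force from geometry
    lt = lmt - l * cosa
    eps = (lt - l_slack) / l_slack
    ft = _ft_norm(eps, f_toe, k_toe, eps_toe, k_lin)
    # fiber curves at clamped normalized length
    ln = l / l_opt
    if ln < LN_LO:
        ln = LN_LO
    elif ln > LN_HI:
        ln = LN_HI
    d = ln - 1.0
    fl = math.exp(-d * d / gamma_fl)
    num = math.expm1(k_pe * d / eps_m0)
    if num < 0.0:
        num = 0.0
    fpe = num / math.expm1(k_pe)
    fm = ft / cosa - fpe
    fa_cap = a * fl
    if fa_cap < 1e-6:
        fa_cap = 1e-6
    vs = (0.25 + 0.75 * a) * v_max

    f_hi = 0.95 * fa_cap * f_len
    if fm < 0.0:
        b0 = fa_cap
        v0 = vs * (0.0 - fa_cap) / b0
        slope_lo = vs * (b0 + fa_cap / a_f) / (b0 * b0)
        v = v0 + slope_lo * fm
    elif fm > f_hi:
        b_hi = (2.0 + 2.0 / a_f) * (fa_cap * f_len - f_hi) / (f_len - 1.0)
        v_hi = vs * (f_hi - fa_cap) / b_hi
        db_hi = -(2.0 + 2.0 / a_f) / (f_len - 1.0)
        slope_hi = vs * (b_hi - (f_hi - fa_cap) * db_hi) / (b_hi * b_hi)
        v = v_hi + slope_hi * (fm - f_hi)
    elif fm <= fa_cap:
        b = fa_cap + fm / a_f
        v = vs * (fm - fa_cap) / b
    else:
        b = (2.0 + 2.0 / a_f) * (fa_cap * f_len - fm) / (f_len - 1.0)
        v = vs * (fm - fa_cap) / b
    # smooth C1 saturation: linear to v_max, tanh roll-off to 1.6 v_max
    av = v if v >= 0.0 else -v
    if av > v_max:
        span = 0.6 * v_max
        sat = v_max + span * math.tanh((av - v_max) / span)
        v = sat if v > 0.0 else -sat
    return v * l_opt


@njit(cache=True)
def _fv_dl(a, l, lmt, hstep, l_opt, hpen, l_slack, f_toe, k_toe, eps_toe,
           k_lin, gamma_fl, k_pe, eps_m0, a_f, f_len, v_max):
    vp = _fv_scalar(a, l + hstep, lmt, l_opt, hpen, l_slack, f_toe, k_toe,
                    eps_toe, k_lin, gamma_fl, k_pe, eps_m0, a_f, f_len, v_max)
    vm = _fv_scalar(a, l - hstep, lmt, l_opt, hpen, l_slack, f_toe, k_toe,
                    eps_toe, k_lin, gamma_fl, k_pe, eps_m0, a_f, f_len, v_max)
    return (vp - vm) / (2.0 * hstep)


@njit(cache=True)
def _fv_da(a, l, lmt, l_opt, hpen, l_slack, f_toe, k_toe, eps_toe, k_lin,
           gamma_fl, k_pe, eps_m0, a_f, f_len, v_max):
    ha = 1e-6
    vp = _fv_scalar(a + ha, l, lmt, l_opt, hpen, l_slack, f_toe, k_toe,
                    eps_toe, k_lin, gamma_fl, k_pe, eps_m0, a_f, f_len, v_max)
    vm = _fv_scalar(a - ha, l, lmt, l_opt, hpen, l_slack, f_toe, k_toe,
                    eps_toe, k_lin, gamma_fl, k_pe, eps_m0, a_f, f_len, v_max)
    return (vp - vm) / (2.0 * ha)


@njit(cache=True)
def propagate_kernel(hs, need_sens, dt, u, um, du, dum, lmt, lmt_mid,
                     a0, l0,
                     l_opt, hpen, l_slack, f_toe, k_toe, eps_toe, k_lin,
                     gamma_fl, k_pe, eps_m0, a_f, f_len, v_max,
                     tau_act, tau_deact, blend):
    """Condensed defect-equation march with forward sensitivities.

    Shapes: u (P, m); um (P-1, m) (ignored unless ``hs``); du (P, m, D);
    dum (P-1, m, D); lmt (P, m); lmt_mid (P-1, m). Returns a, l (P, m) and
    Sa, Sl (P, m, D) (zero-size D when ``need_sens`` is false).
    """
    P, m = u.shape
    D = du.shape[2] if need_sens else 0
    a = np.empty((P, m))
    l = np.empty((P, m))
    Sa = np.zeros((P, m, D))
    Sl = np.zeros((P, m, D))
    for i in range(m):
        ai = a0[i]
        if ai < 0.005:
            ai = 0.005
        elif ai > 1.0:
            ai = 1.0
        a[0, i] = ai
        li = l0[i]
        lo_l = 0.25 * l_opt[i]
        hi_l = 1.78 * l_opt[i]
        if li < lo_l:
            li = lo_l
        elif li > hi_l:
            li = hi_l
        l[0, i] = li
    if need_sens:
        # initial-state sensitivity columns: a0 block then l0 block at the
        # tail of theta = [W | H | a0 | l0]
        ia0 = D - 2 * m
        for i in range(m):
            Sa[0, i, ia0 + i] = 1.0
            Sl[0, i, ia0 + m + i] = 1.0

    tol_a = 1e-12
    for n in range(P - 1):
        for i in range(m):
            ta, td, bl_ = tau_act[i], tau_deact[i], blend[i]
            an = a[n, i]
            u0 = u[n, i]
            u1 = u[n + 1, i]
            f0 = _fa_scalar(an, u0, ta, td, bl_)
            f0_a, f0_u = _fa_partials(an, u0, ta, td, bl_)
            uc = um[n, i] if hs else 0.0

            # ---- activation step: safeguarded Newton on [0.005, 1] ----
            blo, bhi = 0.005, 1.0
            # residual at brackets
            if hs:
                fb = _fa_scalar(blo, u1, ta, td, bl_)
                acb = 0.5 * (an + blo) + dt / 8.0 * (f0 - fb)
                fcb = _fa_scalar(acb, uc, ta, td, bl_)
                rlo = blo - an - dt / 6.0 * (f0 + 4.0 * fcb + fb)
                fb = _fa_scalar(bhi, u1, ta, td, bl_)
                acb = 0.5 * (an + bhi) + dt / 8.0 * (f0 - fb)
                fcb = _fa_scalar(acb, uc, ta, td, bl_)
                rhi = bhi - an - dt / 6.0 * (f0 + 4.0 * fcb + fb)
            else:
                rlo = blo - an - dt / 2.0 * (f0 + _fa_scalar(blo, u1, ta, td, bl_))
                rhi = bhi - an - dt / 2.0 * (f0 + _fa_scalar(bhi, u1, ta, td, bl_))
            bracketed = rlo * rhi < 0.0
            if bracketed and rlo > 0.0:
                blo, bhi = bhi, blo
            x = an + dt * f0
            if x < 0.005:
                x = 0.005
            elif x > 1.0:
                x = 1.0
            for _ in range(60):
                f1 = _fa_scalar(x, u1, ta, td, bl_)
                f1_a, f1_u = _fa_partials(x, u1, ta, td, bl_)
                if hs:
                    ac = 0.5 * (an + x) + dt / 8.0 * (f0 - f1)
                    fc = _fa_scalar(ac, uc, ta, td, bl_)
                    fc_a, fc_u = _fa_partials(ac, uc, ta, td, bl_)
                    r = x - an - dt / 6.0 * (f0 + 4.0 * fc + f1)
                    dr = 1.0 - dt / 6.0 * (4.0 * fc_a * (0.5 - dt / 8.0 * f1_a) + f1_a)
                else:
                    r = x - an - dt / 2.0 * (f0 + f1)
                    dr = 1.0 - dt / 2.0 * f1_a
                if bracketed:
                    if r < 0.0:
                        blo = x
                    else:
                        bhi = x
                step = r / dr if dr != 0.0 else 0.0
                xn = x - step
                if bracketed and (xn - blo) * (xn - bhi) >= 0.0:
                    xn = 0.5 * (blo + bhi)
                if xn < 0.005:
                    xn = 0.005
                elif xn > 1.0:
                    xn = 1.0
                conv = abs(xn - x) < tol_a
                x = xn
                if conv:
                    break
            a1 = x
            a[n + 1, i] = a1
            f1 = _fa_scalar(a1, u1, ta, td, bl_)
            f1_a, f1_u = _fa_partials(a1, u1, ta, td, bl_)
            if hs:
                ac = 0.5 * (an + a1) + dt / 8.0 * (f0 - f1)
                fc = _fa_scalar(ac, uc, ta, td, bl_)
                fc_a, fc_u = _fa_partials(ac, uc, ta, td, bl_)

            # ---- fiber-length step ----
            lop, hp, ls = l_opt[i], hpen[i], l_slack[i]
            fo, kt, et, kl = f_toe[i], k_toe[i], eps_toe[i], k_lin[i]
            gf, kp, em = gamma_fl[i], k_pe[i], eps_m0[i]
            af_, fln, vm_ = a_f[i], f_len[i], v_max[i]
            ln_ = l[n, i]
            lmt0 = lmt[n, i]
            lmt1 = lmt[n + 1, i]
            lmtc = lmt_mid[n, i] if hs else 0.0
            g0 = _fv_scalar(an, ln_, lmt0, lop, hp, ls, fo, kt, et, kl,
                            gf, kp, em, af_, fln, vm_)
            lo_l = 0.25 * lop
            hi_l = 1.78 * lop
            hstep = 1e-7 * lop
            tol_l = 1e-12 * lop

            # bracket residuals
            def_rlo = 0.0
            def_rhi = 0.0
            for which in range(2):
                xb = lo_l if which == 0 else hi_l
                g1b = _fv_scalar(a1, xb, lmt1, lop, hp, ls, fo, kt, et, kl,
                                 gf, kp, em, af_, fln, vm_)
                if hs:
                    lcb = 0.5 * (ln_ + xb) + dt / 8.0 * (g0 - g1b)
                    gcb = _fv_scalar(ac, lcb, lmtc, lop, hp, ls, fo, kt, et,
                                     kl, gf, kp, em, af_, fln, vm_)
                    rb = xb - ln_ - dt / 6.0 * (g0 + 4.0 * gcb + g1b)
                else:
                    rb = xb - ln_ - dt / 2.0 * (g0 + g1b)
                if which == 0:
                    def_rlo = rb
                else:
                    def_rhi = rb
            blo, bhi = lo_l, hi_l
            bracketed = def_rlo * def_rhi < 0.0
            if bracketed and def_rlo > 0.0:
                blo, bhi = bhi, blo
            x = ln_ + dt * g0
            if x < lo_l:
                x = lo_l
            elif x > hi_l:
                x = hi_l
            for _ in range(60):
                g1 = _fv_scalar(a1, x, lmt1, lop, hp, ls, fo, kt, et, kl,
                                gf, kp, em, af_, fln, vm_)
                g1_l = _fv_dl(a1, x, lmt1, hstep, lop, hp, ls, fo, kt, et,
                              kl, gf, kp, em, af_, fln, vm_)
                if hs:
                    lc = 0.5 * (ln_ + x) + dt / 8.0 * (g0 - g1)
                    gc = _fv_scalar(ac, lc, lmtc, lop, hp, ls, fo, kt, et,
                                    kl, gf, kp, em, af_, fln, vm_)
                    gc_l = _fv_dl(ac, lc, lmtc, hstep, lop, hp, ls, fo, kt,
                                  et, kl, gf, kp, em, af_, fln, vm_)
                    r = x - ln_ - dt / 6.0 * (g0 + 4.0 * gc + g1)
                    dr = 1.0 - dt / 6.0 * (4.0 * gc_l * (0.5 - dt / 8.0 * g1_l) + g1_l)
                else:
                    r = x - ln_ - dt / 2.0 * (g0 + g1)
                    dr = 1.0 - dt / 2.0 * g1_l
                if bracketed:
                    if r < 0.0:
                        blo = x
                    else:
                        bhi = x
                step = r / dr if dr != 0.0 else 0.0
                xn = x - step
                if bracketed and (xn - blo) * (xn - bhi) >= 0.0:
                    xn = 0.5 * (blo + bhi)
                if xn < lo_l:
                    xn = lo_l
                elif xn > hi_l:
                    xn = hi_l
                conv = abs(xn - x) < tol_l
                x = xn
                if conv:
                    break
            l1 = x
            l[n + 1, i] = l1

            if not need_sens:
                continue

            # ---- sensitivity updates (implicit function theorem) ----
            if hs:
                dR_da1 = 1.0 - dt / 6.0 * (4.0 * fc_a * (0.5 - dt / 8.0 * f1_a) + f1_a)
                cA = -1.0 - dt / 6.0 * (f0_a + 4.0 * fc_a * (0.5 + dt / 8.0 * f0_a))
                cu0 = -dt / 6.0 * f0_u * (1.0 + dt / 2.0 * fc_a)
                cuc = -dt / 6.0 * 4.0 * fc_u
                cu1 = -dt / 6.0 * f1_u * (1.0 - dt / 2.0 * fc_a)
                for dcol in range(D):
                    rhs_ = (cA * Sa[n, i, dcol] + cu0 * du[n, i, dcol]
                            + cuc * dum[n, i, dcol] + cu1 * du[n + 1, i, dcol])
                    Sa[n + 1, i, dcol] = -rhs_ / dR_da1
            else:
                dR_da1 = 1.0 - dt / 2.0 * f1_a
                for dcol in range(D):
                    rhs_ = (-(1.0 + dt / 2.0 * f0_a) * Sa[n, i, dcol]
                            - dt / 2.0 * f0_u * du[n, i, dcol]
                            - dt / 2.0 * f1_u * du[n + 1, i, dcol])
                    Sa[n + 1, i, dcol] = -rhs_ / dR_da1

            g0_a = _fv_da(an, ln_, lmt0, lop, hp, ls, fo, kt, et, kl,
                          gf, kp, em, af_, fln, vm_)
            g0_l = _fv_dl(an, ln_, lmt0, hstep, lop, hp, ls, fo, kt, et, kl,
                          gf, kp, em, af_, fln, vm_)
            g1v = _fv_scalar(a1, l1, lmt1, lop, hp, ls, fo, kt, et, kl,
                             gf, kp, em, af_, fln, vm_)
            g1_a = _fv_da(a1, l1, lmt1, lop, hp, ls, fo, kt, et, kl,
                          gf, kp, em, af_, fln, vm_)
            g1_l = _fv_dl(a1, l1, lmt1, hstep, lop, hp, ls, fo, kt, et, kl,
                          gf, kp, em, af_, fln, vm_)
            if hs:
                lc = 0.5 * (ln_ + l1) + dt / 8.0 * (g0 - g1v)
                gc_a = _fv_da(ac, lc, lmtc, lop, hp, ls, fo, kt, et, kl,
                              gf, kp, em, af_, fln, vm_)
                gc_l = _fv_dl(ac, lc, lmtc, hstep, lop, hp, ls, fo, kt, et,
                              kl, gf, kp, em, af_, fln, vm_)
                dR_dl1 = 1.0 - dt / 6.0 * (4.0 * gc_l * (0.5 - dt / 8.0 * g1_l) + g1_l)
                cL = -1.0 - dt / 6.0 * (g0_l + 4.0 * gc_l * (0.5 + dt / 8.0 * g0_l))
                ca0 = -dt / 6.0 * g0_a * (1.0 + dt / 2.0 * gc_l)
                ca1 = -dt / 6.0 * g1_a * (1.0 - dt / 2.0 * gc_l)
                cac = -dt / 6.0 * 4.0 * gc_a
                for dcol in range(D):
                    # state-midpoint activation sensitivity
                    sac = (0.5 * (Sa[n, i, dcol] + Sa[n + 1, i, dcol])
                           + dt / 8.0 * (f0_a * Sa[n, i, dcol]
                                         + f0_u * du[n, i, dcol]
                                         - f1_a * Sa[n + 1, i, dcol]
                                         - f1_u * du[n + 1, i, dcol]))
                    rhs_ = (cL * Sl[n, i, dcol] + ca0 * Sa[n, i, dcol]
                            + ca1 * Sa[n + 1, i, dcol] + cac * sac)
                    Sl[n + 1, i, dcol] = -rhs_ / dR_dl1
            else:
                dR_dl1 = 1.0 - dt / 2.0 * g1_l
                for dcol in range(D):
                    rhs_ = (-(1.0 + dt / 2.0 * g0_l) * Sl[n, i, dcol]
                            - dt / 2.0 * g0_a * Sa[n, i, dcol]
                            - dt / 2.0 * g1_a * Sa[n + 1, i, dcol])
                    Sl[n + 1, i, dcol] = -rhs_ / dR_dl1
    return a, l, Sa, Sl
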