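"""JIT-compiled numerical core.

Scalar kernels for the TriSeg wall mechanics (spherical-cap kinematics,
myofiber stress, tension balance at the shared junction) and the nine-state
closed-loop circulation right-hand side.  Everything here operates on plain
floats / flat float64 arrays so numba can compile it; the public modules
(`geometry`, `sarcomere`, `core`, `circulation`) wrap these kernels with
validation, dataclasses and documentation.

Unit system: cm / mL / mmHg / s for hemodynamics, kPa for stress, um for
sarcomere lengths.
"""

import math

import numpy as np
from numba import njit

KPA_PER_MMHG = 0.133322
PI = math.pi

# Sub-slack passive regularization: tiny linear compressive stress below the
# slack length keeps the junction Newton solve nonsingular when a wall goes
# fully slack.  Contributes < 0.05 mmHg anywhere in a physiological state.
SUBSLACK_K = 1.0e-4

# --------------------------------------------------------------------------
# Parameter-vector layout (single flat float64 array shared with the JIT code)
# --------------------------------------------------------------------------
VW_LW, VW_SW, VW_RW = 0, 1, 2
AMREF_LW, AMREF_SW, AMREF_RW = 3, 4, 5
LREF, LC0, LSE_ISO, VMAX, GAMMA, NU_L = 6, 7, 8, 9, 10, 11
KPAS_LW, KPAS_SW, KPAS_RW = 12, 13, 14
KACT_LW, KACT_SW, KACT_RW = 15, 16, 17
PERIOD, T_S, T_R = 18, 19, 20
PERI_S, PERI_VH0, PERI_ON = 21, 22, 23
C_SA, C_SV, C_PA, C_PV = 24, 25, 26, 27
VU_SA, VU_SV, VU_PA, VU_PV = 28, 29, 30, 31
R_SYS, R_PUL, RT_SA, RT_PA, R_MITRAL, R_TRICUSPID = 32, 33, 34, 35, 36, 37
NPAR = 38

# State-vector layout
IV_LV, IV_SA, IV_SV, IV_RV, IV_PA, IV_PV = 0, 1, 2, 3, 4, 5
ILC_LW, ILC_SW, ILC_RW = 6, 7, 8
NSTATE = 9

# Observation-vector layout (filled by `observe`)
OP_LV, OP_RV, OP_SA, OP_SV, OP_PA, OP_PV = 0, 1, 2, 3, 4, 5
OQ_MIT, OQ_AO, OQ_SYS, OQ_TRI, OQ_PV, OQ_PUL = 6, 7, 8, 9, 10, 11
OCM_SW, OP_PERI, OY = 12, 13, 14
OLS_LW, OLS_SW, OLS_RW = 15, 16, 17
OXM_LW, OXM_SW, OXM_RW, OYM = 18, 19, 20, 21
OP_SA_EL, OP_PA_EL = 22, 23
NOBS = 24


@njit(cache=True)
def activation(t, ts, tr):
    """Half-cosine activation waveform on one beat, in [0, 1]."""
    if t < 0.0:
        return 0.0
    if t <= ts:
        return 0.5 * (1.0 - math.cos(PI * t / ts))
    if t <= ts + tr:
        return 0.5 * (1.0 + math.cos(PI * (t - ts) / tr))
    return 0.0


@njit(cache=True)
def passive_stress(ls, lc0, gamma, nu_l):
    """Klotz-form passive myofiber stress (kPa before k_pas scaling)."""
    x = nu_l * (ls - lc0)
    if x > 0.0:
        return x ** gamma
    return SUBSLACK_K * x


@njit(cache=True)
def active_stress(ls, lc, y_act, lc0, lse_iso, nu_l):
    """Active myofiber stress of the series-elastic arrangement (kPa)."""
    e = nu_l * (lc - lc0)
    if e < 0.0:
        e = 0.0
    return e * ((ls - lc) / lse_iso) * y_act


@njit(cache=True)
def contractile_rate(ls, lc, lse_iso, vmax):
    """dLc/dt of the contractile element (um/s)."""
    return ((ls - lc) / lse_iso - 1.0) * vmax


@njit(cache=True)
def cap_geometry(xm, ym):
    """Spherical-cap midwall area, curvature and enclosed volume."""
    d = xm * xm + ym * ym
    am = PI * d
    cm = 2.0 * xm / d
    vm = PI / 6.0 * xm * (xm * xm + 3.0 * ym * ym)
    return am, cm, vm


@njit(cache=True)
def wall_strain(am, cm, vw, am_ref, lref):
    """Curvature ratio z, natural fiber strain and sarcomere length."""
    z = 1.5 * cm * vw / am
    z2 = z * z
    eps = 0.5 * math.log(am / am_ref) - z2 / 12.0 - 0.019 * z2 * z2
    return z, eps, lref * math.exp(eps)


@njit(cache=True)
def wall_tension(sigma, vw, am, z, xm, ym):
    """Representative midwall tension and its junction components."""
    z2 = z * z
    tm = sigma * vw * (1.0 + z2 / 3.0 + z2 * z2 / 5.0) / (2.0 * am)
    d = xm * xm + ym * ym
    tx = tm * 2.0 * xm * ym / d
    ty = tm * (ym * ym - xm * xm) / d
    return tm, tx, ty


@njit(cache=True)
def _wall_eval(xm, ym, vw, am_ref, kpas, kact, lc, y_act, par):
    """Full per-wall chain xm,ym -> (Vm, Am, Cm, z, Ls, sigma, Tm, Tx, Ty)."""
    am, cm, vm = cap_geometry(xm, ym)
    z, _eps, ls = wall_strain(am, cm, vw, am_ref, par[LREF])
    spas = passive_stress(ls, par[LC0], par[GAMMA], par[NU_L])
    sact = active_stress(ls, lc, y_act, par[LC0], par[LSE_ISO], par[NU_L])
    sigma = kpas * spas + kact * sact
    tm, tx, ty = wall_tension(sigma, vw, am, z, xm, ym)
    return vm, am, cm, z, ls, sigma, tm, tx, ty


@njit(cache=True)
def junction_residual(u, v_lv, v_rv, lc, y_act, par, out):
    """Four TriSeg equilibrium residuals (volumes in mL, tensions kPa cm).

    out[0]: LV midwall-cap volume consistency
    out[1]: RV midwall-cap volume consistency
    out[2]: sum of axial tension components Tx
    out[3]: sum of radial tension components Ty
    """
    ym = u[3]
    vm_l, _, _, _, _, _, _, tx_l, ty_l = _wall_eval(
        u[0], ym, par[VW_LW], par[AMREF_LW], par[KPAS_LW], par[KACT_LW],
        lc[0], y_act, par)
    vm_s, _, _, _, _, _, _, tx_s, ty_s = _wall_eval(
        u[1], ym, par[VW_SW], par[AMREF_SW], par[KPAS_SW], par[KACT_SW],
        lc[1], y_act, par)
    vm_r, _, _, _, _, _, _, tx_r, ty_r = _wall_eval(
        u[2], ym, par[VW_RW], par[AMREF_RW], par[KPAS_RW], par[KACT_RW],
        lc[2], y_act, par)
    out[0] = (vm_s - vm_l) - (v_lv + 0.5 * par[VW_LW] + 0.5 * par[VW_SW])
    out[1] = (vm_r - vm_s) - (v_rv + 0.5 * par[VW_SW] + 0.5 * par[VW_RW])
    out[2] = tx_l + tx_s + tx_r
    out[3] = ty_l + ty_s + ty_r


@njit(cache=True)
def _solve4(a, b):
    """In-place 4x4 Gaussian elimination with partial pivoting.

    Returns False when the pivot underflows (singular system).
    """
    for k in range(4):
        p = k
        amax = abs(a[k, k])
        for i in range(k + 1, 4):
            if abs(a[i, k]) > amax:
                amax = abs(a[i, k])
                p = i
        if amax < 1.0e-300:
            return False
        if p != k:
            for j in range(4):
                tmp = a[k, j]
                a[k, j] = a[p, j]
                a[p, j] = tmp
            tmp = b[k]
            b[k] = b[p]
            b[p] = tmp
        for i in range(k + 1, 4):
            f = a[i, k] / a[k, k]
            for j in range(k, 4):
                a[i, j] -= f * a[k, j]
            b[i] -= f * b[k]
    for i in range(3, -1, -1):
        s = b[i]
        for j in range(i + 1, 4):
            s -= a[i, j] * b[j]
        b[i] = s / a[i, i]
    return True


@njit(cache=True)
def solve_junction(u, v_lv, v_rv, lc, y_act, par, tol, maxit):
    """Newton solve of the quasi-static TriSeg configuration.

    `u` = (xm_LW, xm_SW, xm_RW, ym) is updated in place (warm start in,
    solution out).  Residuals are scaled by the chamber volume and by the
    total tension magnitude so `tol` is a relative tolerance.  Returns the
    iteration count, or -1 on failure.
    """
    r = np.empty(4)
    r2 = np.empty(4)
    jac = np.empty((4, 4))
    step = np.empty(4)
    v_scale_l = v_lv + 0.5 * par[VW_LW] + 0.5 * par[VW_SW]
    v_scale_r = v_rv + 0.5 * par[VW_SW] + 0.5 * par[VW_RW]
    for it in range(maxit):
        junction_residual(u, v_lv, v_rv, lc, y_act, par, r)
        t_scale = (abs(r[2]) + abs(r[3]))
        # typical tension magnitude for scaling: rebuild from Tm sum
        tm_sum = 0.0
        for w in range(3):
            idx_vw = VW_LW + w
            am, cm, _ = cap_geometry(u[w], u[3])
            z, _, ls = wall_strain(am, cm, par[idx_vw], par[AMREF_LW + w],
                                   par[LREF])
            spas = passive_stress(ls, par[LC0], par[GAMMA], par[NU_L])
            sact = active_stress(ls, lc[w], y_act, par[LC0], par[LSE_ISO],
                                 par[NU_L])
            sigma = par[KPAS_LW + w] * spas + par[KACT_LW + w] * sact
            tm, _, _ = wall_tension(sigma, par[idx_vw], am, z, u[w], u[3])
            tm_sum += abs(tm)
        t_scale = tm_sum if tm_sum > 1.0e-9 else 1.0e-9
        e0 = abs(r[0]) / v_scale_l
        e1 = abs(r[1]) / v_scale_r
        e2 = abs(r[2]) / t_scale
        e3 = abs(r[3]) / t_scale
        err = max(max(e0, e1), max(e2, e3))
        if err < tol:
            return it
        # forward-difference Jacobian
        for j in range(4):
            h = 1.0e-6 * (abs(u[j]) if abs(u[j]) > 0.01 else 0.01)
            uj = u[j]
            u[j] = uj + h
            junction_residual(u, v_lv, v_rv, lc, y_act, par, r2)
            u[j] = uj
            for i in range(4):
                jac[i, j] = (r2[i] - r[i]) / h
        for i in range(4):
            step[i] = -r[i]
        if not _solve4(jac, step):
            return -1
        # damp so ym stays positive and steps stay bounded
        lam = 1.0
        if u[3] + step[3] <= 0.05 * u[3]:
            lam = min(lam, -0.95 * u[3] / step[3])
        smax = 0.0
        for i in range(4):
            if abs(step[i]) > smax:
                smax = abs(step[i])
        if smax > 2.0:
            lam = min(lam, 2.0 / smax)
        for i in range(4):
            u[i] += lam * step[i]
    return -1


@njit(cache=True)
def pericardial_pressure(v_lv, v_rv, s, vh0, on):
    """Exponential pericardial constraint (mmHg); zero at Vh = Vh0."""
    if on == 0.0:
        return 0.0
    return math.exp(s * ((v_lv + v_rv) / vh0 - 1.0)) - 1.0


@njit(cache=True)
def observe(t, y, par, u, out):
    """Solve the wall configuration at state `y` and fill observation vector.

    Returns the Newton iteration count (-1 on failure).  `u` is the
    warm-started junction unknown vector, updated in place.
    """
    tb = t % par[PERIOD]
    y_act = activation(tb, par[T_S], par[T_R])
    lc = y[ILC_LW:ILC_RW + 1]
    v_lv = y[IV_LV]
    v_rv = y[IV_RV]
    it = solve_junction(u, v_lv, v_rv, lc, y_act, par, 1.0e-9, 50)
    if it < 0:
        # cold restart from the nominal displacements; the warm start can
        # stray near the all-slack degenerate configuration
        u[0] = -5.0
        u[1] = 2.0
        u[2] = 6.0
        u[3] = 3.0
        it = solve_junction(u, v_lv, v_rv, lc, y_act, par, 1.0e-9, 200)
        if it < 0:
            return -1
    ym = u[3]
    _, _, _, _, ls_l, _, _, tx_l, _ = _wall_eval(
        u[0], ym, par[VW_LW], par[AMREF_LW], par[KPAS_LW], par[KACT_LW],
        lc[0], y_act, par)
    _, _, cm_s, _, ls_s, _, _, _, _ = _wall_eval(
        u[1], ym, par[VW_SW], par[AMREF_SW], par[KPAS_SW], par[KACT_SW],
        lc[1], y_act, par)
    _, _, _, _, ls_r, _, _, tx_r, _ = _wall_eval(
        u[2], ym, par[VW_RW], par[AMREF_RW], par[KPAS_RW], par[KACT_RW],
        lc[2], y_act, par)
    p_peri = pericardial_pressure(v_lv, v_rv, par[PERI_S], par[PERI_VH0],
                                  par[PERI_ON])
    p_lv = (-2.0 * tx_l / ym) / KPA_PER_MMHG + p_peri
    p_rv = (2.0 * tx_r / ym) / KPA_PER_MMHG + p_peri
    p_sa_el = (y[IV_SA] - par[VU_SA]) / par[C_SA]
    p_sv = (y[IV_SV] - par[VU_SV]) / par[C_SV]
    p_pa_el = (y[IV_PA] - par[VU_PA]) / par[C_PA]
    p_pv = (y[IV_PV] - par[VU_PV]) / par[C_PV]

    q_ao = max(p_lv - p_sa_el, 0.0) / par[RT_SA]
    q_sys = (p_sa_el - p_sv) / par[R_SYS]
    q_tri = max(p_sv - p_rv, 0.0) / par[R_TRICUSPID]
    q_pvalve = max(p_rv - p_pa_el, 0.0) / par[RT_PA]
    q_pul = (p_pa_el - p_pv) / par[R_PUL]
    q_mit = max(p_pv - p_lv, 0.0) / par[R_MITRAL]

    out[OP_LV] = p_lv
    out[OP_RV] = p_rv
    # arterial compartments carry a viscoelastic (Rt * dV/dt) pressure term
    out[OP_SA] = p_sa_el + par[RT_SA] * (q_ao - q_sys)
    out[OP_SV] = p_sv
    out[OP_PA] = p_pa_el + par[RT_PA] * (q_pvalve - q_pul)
    out[OP_PV] = p_pv
    out[OQ_MIT] = q_mit
    out[OQ_AO] = q_ao
    out[OQ_SYS] = q_sys
    out[OQ_TRI] = q_tri
    out[OQ_PV] = q_pvalve
    out[OQ_PUL] = q_pul
    out[OCM_SW] = cm_s
    out[OP_PERI] = p_peri
    out[OY] = y_act
    out[OLS_LW] = ls_l
    out[OLS_SW] = ls_s
    out[OLS_RW] = ls_r
    out[OXM_LW] = u[0]
    out[OXM_SW] = u[1]
    out[OXM_RW] = u[2]
    out[OYM] = ym
    out[OP_SA_EL] = p_sa_el
    out[OP_PA_EL] = p_pa_el
    return it


@njit(cache=True)
def rhs(t, y, par, u, dy, obs):
    """Closed-loop ODE right-hand side; returns -1 if the wall solve fails.

    State: six compartment volumes (mL) + three contractile lengths (um).
    Flow topology: PV -> LV -> SA -> SV -> RV -> PA -> PV with diode valves
    at PV->LV (Rm), LV->SA (Rt_SA), SV->RV (Rt) and RV->PA (Rt_PA).
    """
    it = observe(t, y, par, u, obs)
    if it < 0:
        return -1
    q_mit = obs[OQ_MIT]
    q_ao = obs[OQ_AO]
    q_sys = obs[OQ_SYS]
    q_tri = obs[OQ_TRI]
    q_pvalve = obs[OQ_PV]
    q_pul = obs[OQ_PUL]
    dy[IV_LV] = q_mit - q_ao
    dy[IV_SA] = q_ao - q_sys
    dy[IV_SV] = q_sys - q_tri
    dy[IV_RV] = q_tri - q_pvalve
    dy[IV_PA] = q_pvalve - q_pul
    dy[IV_PV] = q_pul - q_mit
    dy[ILC_LW] = contractile_rate(obs[OLS_LW], y[ILC_LW], par[LSE_ISO],
                                  par[VMAX])
    dy[ILC_SW] = contractile_rate(obs[OLS_SW], y[ILC_SW], par[LSE_ISO],
                                  par[VMAX])
    dy[ILC_RW] = contractile_rate(obs[OLS_RW], y[ILC_RW], par[LSE_ISO],
                                  par[VMAX])
    return it
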