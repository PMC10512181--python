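"""Subject-specific calibration.

Three stages:

1. **Klotz single-beat EDPVR** — from one measured (EDP, EDV) pair the
   empirical landmark volumes V0 (pressure ~0) and V30 (30 mmHg) define a
   power-law end-diastolic pressure-volume relationship P = alpha V^beta
   through the measured point.  The same template is applied to the RV
   (assumed to share LV material properties).
2. **gamma optimization** — the passive length-tension steepness gamma is
   fit by nonlinear least squares so that the model's *ex vivo* EDPVRs
   (isolated, passive, no pericardium) match the Klotz curves of both
   ventricles over a volume grid.
3. **k_pas / k_act scaling** — per-wall stress scaling factors map the
   unit-scale sarcomere stresses to the measured end-diastolic and
   end-systolic pressures through the dimensionless geometric factor
   Gamma = P_chamber / sigma_wall of the spherical end-diastolic /
   end-systolic configuration (computed numerically from the wall-tension
   machinery, not from a closed form).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._core import KPA_PER_MMHG
from .circulation import derive_circulation_parameters
from .config import Config
from .core import (DEFAULT_DISPLACEMENTS, PericardiumParams,
                   solve_wall_configuration, wall_tension)
from .geometry import (ReferenceGeometry, WallGeometry, WALLS,
                       build_reference_geometry, end_systolic_geometry)
from .model import CardioModel
from .sarcomere import (ActivationParams, SarcomereParams, WallProperties,
                        active_stress, passive_stress)

#: Klotz normalized-template constants (An in mmHg).
KLOTZ_AN = 27.78
KLOTZ_BN = 2.76

#: Activation fraction assumed at end-systole for the k_act calibration.
ES_ACTIVATION = 0.6

#: Sarcomere length (um) assumed at rest for the k_pas calibration.
ED_SARCOMERE_LENGTH = 2.0


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class KlotzCurve:
    """Single-beat EDPVR estimate through one (EDV, EDP) point."""

    V0: float      # volume at ~0 mmHg, mL
    V30: float     # volume at 30 mmHg, mL
    An: float      # normalized-template amplitude, mmHg
    Bn: float      # normalized-template exponent
    alpha: float   # subject curve coefficient (mmHg / mL^beta)
    beta: float    # subject curve exponent

    def pressure(self, V) -> np.ndarray:
        """EDPVR pressure (mmHg) at volume(s) V."""
        return self.alpha * np.asarray(V, dtype=float) ** self.beta

    def normalized_volume(self, V) -> np.ndarray:
        """Map volumes to the Klotz normalized axis (V - V0)/(V30 - V0)."""
        return (np.asarray(V, dtype=float) - self.V0) / (self.V30 - self.V0)


def klotz_curve(EDP: float, EDV: float) -> KlotzCurve:
    """Build the single-beat Klotz EDPVR from one measured point."""
    if not (EDP > 0 and EDV > 0):
        raise ValueError("EDP and EDV must be positive")
    if EDP >= 30.0:
        warnings.warn("EDP >= 30 mmHg: Klotz single-beat curve is an "
                      "extrapolation", RuntimeWarning, stacklevel=2)
    v0 = EDV * (0.6 - 0.006 * EDP)
    v30 = v0 + (EDV - v0) / (EDP / KLOTZ_AN) ** (1.0 / KLOTZ_BN)
    beta = math.log(EDP / 30.0) / math.log(EDV / v30)
    alpha = 30.0 / v30 ** beta
    return KlotzCurve(V0=v0, V30=v30, An=KLOTZ_AN, Bn=KLOTZ_BN,
                      alpha=alpha, beta=beta)


@dataclass(frozen=True)
class EDPVRCurve:
    """Sampled pressure-volume relation with a provenance tag."""

    volume: np.ndarray
    pressure: np.ndarray
    provenance: str   # "model ex vivo" | "Klotz" | "model in vivo"


def ex_vivo_edpvr(geom: ReferenceGeometry, props: dict[str, WallProperties],
                  sarc: SarcomereParams, volumes) -> tuple[EDPVRCurve,
                                                           EDPVRCurve]:
    """Passive inflation of the isolated heart (both chambers together).

    Zero activation, no pericardium, V_LV = V_RV = each grid volume; the
    static TriSeg configuration is solved at every point (warm-started in
    ascending volume order).  Returns (LV curve, RV curve).
    """
    vols = np.sort(np.asarray(volumes, dtype=float))
    p_lv = np.empty_like(vols)
    p_rv = np.empty_like(vols)
    u = np.array(DEFAULT_DISPLACEMENTS)
    from .core import chamber_pressures
    for i, v in enumerate(vols):
        state, walls = solve_wall_configuration(
            v, v, [sarc.L_ref] * 3, 0.0, geom, props, sarc, u0=u)
        u = state.displacements
        p = chamber_pressures(state, walls, peri=None)
        p_lv[i] = p["P_LV"]
        p_rv[i] = p["P_RV"]
    return (EDPVRCurve(vols, p_lv, "model ex vivo"),
            EDPVRCurve(vols, p_rv, "model ex vivo"))


def normalize_edpvr(curve: EDPVRCurve, klotz: KlotzCurve) -> EDPVRCurve:
    """Map the volume axis to the Klotz normalized axis."""
    return EDPVRCurve(klotz.normalized_volume(curve.volume),
                      curve.pressure, curve.provenance)


def _sphere_gamma_factor(wall: WallGeometry) -> float:
    """Dimensionless chamber-pressure-per-unit-fiber-stress of a sphere.

    Computed through the wall-tension machinery: unit fiber stress gives a
    midwall tension Tm; the spherical force balance then yields
    P = 2 Tm Cm.  Depends only on the sphere's Vw/Am ratio and curvature,
    so the 2/3 : 1/3 LW/SW split shares the whole-LV-sphere factor (the
    wall volume is rebuilt from the radii, not the per-wall split).
    """
    vw = 4.0 / 3.0 * math.pi * (wall.r_o ** 3 - wall.r_i ** 3)
    am = 4.0 * math.pi * wall.r_m ** 2
    cm = 1.0 / wall.r_m
    z = 1.5 * cm * vw / am
    t = wall_tension(1.0, vw, am, z, xm=wall.r_m, ym=wall.r_m)
    return 2.0 * t["Tm"] * cm


def _sphere_sarcomere_length(wall: WallGeometry, ref: WallGeometry,
                             sarc: SarcomereParams) -> float:
    """Sarcomere length of a spherical configuration relative to reference."""
    am = 4.0 * math.pi * wall.r_m ** 2
    am_ref = 4.0 * math.pi * ref.r_m ** 2
    cm = 1.0 / wall.r_m
    z = 1.5 * cm * wall.Vw / am
    z2 = z * z
    eps = 0.5 * math.log(am / am_ref) - z2 / 12.0 - 0.019 * z2 * z2
    return sarc.L_ref * math.exp(eps)


def _chamber_edp(subject, wall: str) -> float:
    return subject.EDP_LV if wall in ("LW", "SW") else subject.EDP_RV


def _sphere_kpas(subject, geom: ReferenceGeometry,
                 sarc: SarcomereParams) -> dict[str, float]:
    """Closed-form initial guess using the spherical Gamma factor and the
    uniform resting sarcomere length."""
    spas = passive_stress(ED_SARCOMERE_LENGTH, sarc)
    if spas <= 0:
        raise CalibrationError("resting sarcomere length is at or below "
                               "slack; passive calibration impossible")
    out = {}
    for w in WALLS:
        gamma_d = _sphere_gamma_factor(geom.wall(w))
        edp = _chamber_edp(subject, w) * KPA_PER_MMHG
        out[w] = edp / (gamma_d * spas)
    return out


def compute_kpas(subject, geom: ReferenceGeometry, sarc: SarcomereParams,
                 rtol: float = 1.0e-10, maxit: int = 60) -> dict[str, float]:
    """Passive scaling factors k_pas,i = EDP_i / (Gamma_i,d sigma_pas,i,d).

    Gamma (pressure per unit wall stress) is evaluated numerically at the
    frozen end-diastolic TriSeg configuration (both chambers at their EDV,
    zero activation, no pericardium): starting from the spherical
    closed-form guess, the configuration is solved and the LV-side (LW and
    SW jointly, the septum sharing the LV material) and RW factors are
    rescaled until the chamber pressures reproduce the measured EDPs.
    """
    from .core import chamber_pressures

    kpas = _sphere_kpas(subject, geom, sarc)
    u = None
    for _ in range(maxit):
        props = {w: WallProperties(k_pas=kpas[w], k_act=0.0) for w in WALLS}
        state, walls = solve_wall_configuration(
            subject.EDV_LV, subject.EDV_RV, [sarc.L_ref] * 3, 0.0,
            geom, props, sarc, u0=u)
        u = state.displacements
        p = chamber_pressures(state, walls, peri=None)
        r_lv = subject.EDP_LV / p["P_LV"]
        r_rv = subject.EDP_RV / p["P_RV"]
        kpas["LW"] *= r_lv
        kpas["SW"] *= r_lv
        kpas["RW"] *= r_rv
        if abs(r_lv - 1.0) < rtol and abs(r_rv - 1.0) < rtol:
            return kpas
    raise CalibrationError("end-diastolic pressure matching did not converge")


def compute_kact(subject, geom: ReferenceGeometry, sarc: SarcomereParams,
                 kpas: dict[str, float] | None = None,
                 rtol: float = 1.0e-10, maxit: int = 80) -> dict[str, float]:
    """Active scaling factors k_act,i = ESP_i / (Gamma_i,s sigma_act,i,s).

    Same numerical-Gamma scheme at the frozen end-systolic configuration:
    chambers at their ESV, 60% activation, contractile elements at the
    isometric equilibrium Lc = Ls - L_se_iso, no pericardium.  The
    spherical construction (wall volume conserved from end-diastole) seeds
    both the factors and the sarcomere lengths.
    """
    from .core import chamber_pressures

    if kpas is None:
        kpas = compute_kpas(subject, geom, sarc)
    kact = {}
    ls_guess = {}
    for w in WALLS:
        ref = geom.wall(w)
        if w in ("LW", "SW"):
            esv, esp = subject.ESV_LV, subject.ESP_LV
            ref_sphere = dataclasses.replace(
                ref, Vw=geom.LW.Vw + geom.SW.Vw)
        else:
            esv, esp = subject.ESV_RV, subject.ESP_RV
            ref_sphere = ref
        es = end_systolic_geometry(esv, ref_sphere.Vw, ref_sphere.h)
        ls = _sphere_sarcomere_length(es, ref_sphere, sarc)
        lc = ls - sarc.L_se_iso
        sact = active_stress(ls, lc, ES_ACTIVATION, sarc)
        if sact <= 0:
            raise CalibrationError(
                f"end-systolic active stress non-positive for wall {w} "
                f"(Ls={ls:.3f} um); check ESV/EDV inputs")
        kact[w] = esp * KPA_PER_MMHG / (_sphere_gamma_factor(es) * sact)
        ls_guess[w] = ls
    lc = np.array([ls_guess[w] - sarc.L_se_iso for w in WALLS])
    u = None
    for _ in range(maxit):
        props = {w: WallProperties(k_pas=kpas[w], k_act=kact[w])
                 for w in WALLS}
        state, walls = solve_wall_configuration(
            subject.ESV_LV, subject.ESV_RV, lc, ES_ACTIVATION,
            geom, props, sarc, u0=u)
        u = state.displacements
        lc = np.array([walls[w].Ls - sarc.L_se_iso for w in WALLS])
        p = chamber_pressures(state, walls, peri=None)
        if p["P_LV"] <= 0 or p["P_RV"] <= 0:
            raise CalibrationError("non-positive end-systolic pressure "
                                   "during k_act matching")
        r_lv = subject.ESP_LV / p["P_LV"]
        r_rv = subject.ESP_RV / p["P_RV"]
        kact["LW"] *= r_lv
        kact["SW"] *= r_lv
        kact["RW"] *= r_rv
        if abs(r_lv - 1.0) < rtol and abs(r_rv - 1.0) < rtol:
            return kact
    raise CalibrationError("end-systolic pressure matching did not converge")


def _passive_props(kpas: dict[str, float]) -> dict[str, WallProperties]:
    return {w: WallProperties(k_pas=kpas[w], k_act=0.0) for w in WALLS}


def fit_gamma(subject, geom: ReferenceGeometry, sarc: SarcomereParams,
              n_grid: int = 40, span: tuple[float, float] = (0.5, 1.3),
              x0: float = 5.0, target_lv=None,
              target_rv=None) -> tuple[float, dict]:
    """Least-squares fit of gamma against both ventricles' reference EDPVRs.

    For each trial gamma the passive scalings are re-derived (so the model
    curve keeps passing near the measured (EDV, EDP) point) and the
    *ex vivo* inflation is compared with the reference pressures on an
    ``n_grid``-point volume grid spanning ``span`` x EDV.  The references
    default to the Klotz single-beat curves; pass ``target_lv`` /
    ``target_rv`` callables (volume -> pressure) to fit against other
    curves, e.g. for parameter-recovery checks.  Returns the fitted gamma
    and a diagnostics dict.
    """
    if target_lv is None:
        target_lv = klotz_curve(subject.EDP_LV, subject.EDV_LV).pressure
    if target_rv is None:
        target_rv = klotz_curve(subject.EDP_RV, subject.EDV_RV).pressure
    # chambers are inflated together; use one grid on the common span
    vols = np.linspace(span[0] * subject.EDV_LV, span[1] * subject.EDV_LV,
                       n_grid)

    def residuals(x):
        g = float(x[0])
        s = dataclasses.replace(sarc, gamma=g)
        props = _passive_props(compute_kpas(subject, geom, s))
        lv, rv = ex_vivo_edpvr(geom, props, s, vols)
        return np.concatenate([lv.pressure - np.asarray(target_lv(vols)),
                               rv.pressure - np.asarray(target_rv(vols))])

    fit = least_squares(residuals, x0=[x0], bounds=([1.5], [30.0]),
                        diff_step=1.0e-3)
    if not fit.success:
        raise CalibrationError(f"gamma optimization failed: {fit.message}; "
                               f"residual norm {np.linalg.norm(fit.fun):.3g}")
    gamma = float(fit.x[0])
    return gamma, {"residual_norm": float(np.linalg.norm(fit.fun)),
                   "n_grid": n_grid, "volumes": vols}


def calibrate(config: Config, fit_passive: bool = True) -> tuple[CardioModel,
                                                                 dict]:
    """Full subject-specific calibration; returns (model, report).

    With ``fit_passive=False`` the configured gamma is used as-is (skipping
    the Klotz optimization, e.g. for fast tests).
    """
    subj = config.subject
    cons = config.constants
    geom = build_reference_geometry(subj.EDV_LV, subj.EDV_RV,
                                    h_LV=cons.h_LV, h_RW=cons.h_RW)
    sarc = SarcomereParams(nu_L=cons.nu_L, L_c0=cons.L_c0,
                           L_se_iso=cons.L_se_iso, v_max=cons.v_max,
                           gamma=cons.gamma, L_ref=cons.L_ref)
    report: dict = {}
    if fit_passive:
        gamma, diag = fit_gamma(subj, geom, sarc)
        report["gamma_fit"] = {"gamma": gamma,
                               "residual_norm": diag["residual_norm"]}
    else:
        gamma = cons.gamma
    sarc = dataclasses.replace(sarc, gamma=gamma)
    kpas = compute_kpas(subj, geom, sarc)
    kact = compute_kact(subj, geom, sarc)
    walls = {w: WallProperties(k_pas=kpas[w], k_act=kact[w]) for w in WALLS}
    act = ActivationParams(T=60.0 / subj.HR, k_TS=cons.k_TS, k_TR=cons.k_TR)
    peri = PericardiumParams.from_edv(subj.EDV_LV, subj.EDV_RV, s=cons.peri_s)
    circ = derive_circulation_parameters(subj, config.compartments, cons,
                                         disease=False)
    model = CardioModel(subject=subj, geometry=geom, sarcomere=sarc,
                        activation=act, walls=walls, pericardium=peri,
                        circulation=circ, gamma=gamma)
    report["gamma"] = gamma
    report["k_pas"] = kpas
    report["k_act"] = kact
    return model, report
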