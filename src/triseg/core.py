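"""TriSeg wall mechanics: cap kinematics, tension balance, chamber pressures.

The three walls (LW, SW, RW) are spherical caps sharing a circular junction
of radius ``ym``; each cap's axial extent is ``xm`` (x axis pointing from
the LV free wall toward the RV free wall, so xm_LW < 0 < xm_RW and a
positive septal curvature means bowing into the RV).  At every instant the
four unknowns (xm_LW, xm_SW, xm_RW, ym) satisfy two midwall-cap volume
constraints and the axial/radial tension balance at the junction; the solve
is quasi-static (Newton, warm-started) as in the original TriSeg
formulation, keeping the ODE state to compartment volumes plus contractile
lengths.

Tension here is the energy-conjugate of midwall area (Tm = dW/dAm per unit
area change), with the natural fiber strain equal to half the logarithmic
area strain; the transmural pressure of a chamber follows from the axial
force balance as 2 Tx / ym.  For a thin sphere this machinery reproduces
Laplace's law P = 2 sigma_t h / r with the per-direction tangential stress
sigma_t = sigma_fiber / 2 (the isotropically distributed fibers carry the
biaxial load half per direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from ._core import KPA_PER_MMHG
from .geometry import ReferenceGeometry, WALLS
from .sarcomere import SarcomereParams, WallProperties

#: Default Newton initial guess (xm_LW, xm_SW, xm_RW, ym) in cm.
DEFAULT_DISPLACEMENTS = (-5.0, 2.0, 6.0, 3.0)


class DegenerateGeometryError(ValueError):
    """Raised when the junction radius is not positive."""


class JunctionSolveError(RuntimeError):
    """Newton iteration on the wall configuration failed to converge."""

    def __init__(self, residuals):
        self.residuals = np.asarray(residuals)
        super().__init__(
            f"TriSeg junction solve did not converge; residuals "
            f"{self.residuals}")


@dataclass(frozen=True)
class PericardiumParams:
    """Exponential pericardial constraint parameters."""

    s: float = 10.0
    Vh_0: float = 312.5   # mL; 1.25 x (EDV_LV + EDV_RV) for the default subject
    enabled: bool = True

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.Vh_0 > 0):
            raise ValueError("pericardium parameters must be positive")

    @classmethod
    def from_edv(cls, EDV_LV: float, EDV_RV: float, s: float = 10.0,
                 enabled: bool = True) -> "PericardiumParams":
        """Reference heart volume 25% above the summed end-diastolic volumes."""
        return cls(s=s, Vh_0=1.25 * (EDV_LV + EDV_RV), enabled=enabled)


@dataclass
class TriSegState:
    """Instantaneous displacements, chamber volumes and contractile lengths."""

    xm_LW: float
    xm_SW: float
    xm_RW: float
    ym: float
    V_LV: float
    V_RV: float
    Lc_LW: float
    Lc_SW: float
    Lc_RW: float

    @property
    def displacements(self) -> np.ndarray:
        return np.array([self.xm_LW, self.xm_SW, self.xm_RW, self.ym])


@dataclass(frozen=True)
class WallConfiguration:
    """Derived kinematics and tensions of one wall at one instant."""

    Am: float      # midwall area, cm^2
    Cm: float      # midwall curvature, 1/cm
    Vm: float      # signed spherical-cap midwall volume, mL
    z: float       # curvature-thickness ratio
    Ls: float      # sarcomere length, um
    sigma: float   # total fiber stress, kPa
    Tm: float      # representative midwall tension, kPa cm
    Tx: float      # axial junction component
    Ty: float      # radial junction component


def cap_geometry(xm: float, ym: float) -> dict[str, float]:
    """Midwall area, curvature and signed cap volume of one wall."""
    if not ym > 0:
        raise DegenerateGeometryError(f"junction radius must be > 0, got {ym}")
    am, cm, vm = _core.cap_geometry(xm, ym)
    return {"Am": am, "Cm": cm, "Vm": vm}


def wall_strain_and_length(Am: float, Cm: float, Vw: float, Am_ref: float,
                           L_ref: float = 2.0) -> dict[str, float]:
    """Curvature ratio z, natural fiber strain and sarcomere length."""
    if not Am_ref > 0:
        raise ValueError("reference area must be positive")
    z, eps, ls = _core.wall_strain(Am, Cm, Vw, Am_ref, L_ref)
    return {"z": z, "eps_f": eps, "Ls": ls}


def wall_tension(sigma: float, Vw: float, Am: float, z: float,
                 xm: float, ym: float) -> dict[str, float]:
    """Representative tension Tm and its axial/radial components."""
    if not Am > 0:
        raise ValueError("midwall area must be positive")
    tm, tx, ty = _core.wall_tension(sigma, Vw, Am, z, xm, ym)
    return {"Tm": tm, "Tx": tx, "Ty": ty}


def pericardial_pressure(V_LV: float, V_RV: float,
                         params: PericardiumParams) -> float:
    """Pericardial pressure exp(s (Vh/Vh0 - 1)) - 1 in mmHg (Vh = VLV+VRV)."""
    if not (V_LV > 0 and V_RV > 0):
        raise ValueError("chamber volumes must be positive")
    return _core.pericardial_pressure(V_LV, V_RV, params.s, params.Vh_0,
                                      1.0 if params.enabled else 0.0)


def _heart_par(geom: ReferenceGeometry, props: dict[str, WallProperties],
               sarc: SarcomereParams) -> np.ndarray:
    par = np.zeros(_core.NPAR)
    for k, w in enumerate(WALLS):
        par[_core.VW_LW + k] = geom.wall(w).Vw
        par[_core.AMREF_LW + k] = geom.wall(w).Am_ref
        par[_core.KPAS_LW + k] = props[w].k_pas
        par[_core.KACT_LW + k] = props[w].k_act
    par[_core.LREF] = sarc.L_ref
    par[_core.LC0] = sarc.L_c0
    par[_core.LSE_ISO] = sarc.L_se_iso
    par[_core.VMAX] = sarc.v_max
    par[_core.GAMMA] = sarc.gamma
    par[_core.NU_L] = sarc.nu_L
    return par


def junction_residual(u, V_LV: float, V_RV: float, Lc, Y: float,
                      geom: ReferenceGeometry,
                      props: dict[str, WallProperties],
                      sarc: SarcomereParams) -> np.ndarray:
    """Four equilibrium residuals at displacements ``u``.

    Order: LV cap-volume consistency, RV cap-volume consistency, sum of
    axial tensions, sum of radial tensions; all zero at equilibrium.
    """
    par = _heart_par(geom, props, sarc)
    out = np.empty(4)
    _core.junction_residual(np.asarray(u, dtype=float), V_LV, V_RV,
                            np.asarray(Lc, dtype=float), Y, par, out)
    return out


def solve_wall_configuration(V_LV: float, V_RV: float, Lc, Y: float,
                             geom: ReferenceGeometry,
                             props: dict[str, WallProperties],
                             sarc: SarcomereParams,
                             u0=None, tol: float = 1.0e-9,
                             maxit: int = 50):
    """Newton-solve the quasi-static wall configuration.

    Returns ``(state, walls)`` where ``walls`` maps wall name to its
    :class:`WallConfiguration`.  ``u0`` warm-starts the iteration (the
    previous time step's solution; defaults to the nominal initial
    displacements).
    """
    par = _heart_par(geom, props, sarc)
    lc = np.asarray(Lc, dtype=float)
    u = np.array(DEFAULT_DISPLACEMENTS if u0 is None else u0, dtype=float)
    it = _core.solve_junction(u, V_LV, V_RV, lc, Y, par, tol, maxit)
    if it < 0:
        res = np.empty(4)
        _core.junction_residual(u, V_LV, V_RV, lc, Y, par, res)
        raise JunctionSolveError(res)
    walls = {}
    for k, w in enumerate(WALLS):
        vm, am, cm, z, ls, sigma, tm, tx, ty = _core._wall_eval(
            u[k], u[3], par[_core.VW_LW + k], par[_core.AMREF_LW + k],
            par[_core.KPAS_LW + k], par[_core.KACT_LW + k], lc[k], Y, par)
        walls[w] = WallConfiguration(Am=am, Cm=cm, Vm=vm, z=z, Ls=ls,
                                     sigma=sigma, Tm=tm, Tx=tx, Ty=ty)
    state = TriSegState(xm_LW=u[0], xm_SW=u[1], xm_RW=u[2], ym=u[3],
                        V_LV=V_LV, V_RV=V_RV,
                        Lc_LW=lc[0], Lc_SW=lc[1], Lc_RW=lc[2])
    return state, walls


def chamber_pressures(state: TriSegState, walls: dict[str, WallConfiguration],
                      peri: PericardiumParams | None = None
                      ) -> dict[str, float]:
    """Chamber pressures (mmHg) from the axial tension balance.

    Transmural pressure is 2 Tx / ym for each free wall (sign follows the
    bulge direction); the pericardial pressure, when enabled, adds to both
    chambers.
    """
    p_peri = 0.0
    if peri is not None:
        p_peri = pericardial_pressure(state.V_LV, state.V_RV, peri)
    p_lv = (-2.0 * walls["LW"].Tx / state.ym) / KPA_PER_MMHG + p_peri
    p_rv = (2.0 * walls["RW"].Tx / state.ym) / KPA_PER_MMHG + p_peri
    return {"P_LV": p_lv, "P_RV": p_rv, "P_peri": p_peri}
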