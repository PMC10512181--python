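"""Six-compartment closed-loop hemodynamics.

Compartments LV -> SA -> SV -> RV -> PA -> PV in series (systemic arteries /
veins, pulmonary arteries / veins), diode valves at the four heart-valve
positions, viscoelastic pressure terms on both arterial compartments.
Compliances, unstressed volumes and vascular resistances are derived from a
subject's total blood volume, compartment volume fractions and pressure
landmarks.  The ventricular "compartments" have no compliance of their own:
their pressures come from the TriSeg mechanics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _core
from .config import CompartmentRow, ModelConstants, SimulationSettings, \
    SubjectData
from .core import DEFAULT_DISPLACEMENTS, JunctionSolveError

COMPARTMENTS = ("LV", "SA", "SV", "RV", "PA", "PV")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CirculationParams:
    """Derived vascular parameters (mmHg, mL, s units)."""

    C_SA: float
    C_SV: float
    C_PA: float
    C_PV: float
    R_sys: float
    R_pul: float
    Rt_SA: float
    Rt_PA: float
    Rm: float
    Rt: float
    Vu_SA: float
    Vu_SV: float
    Vu_PA: float
    Vu_PV: float
    TBV: float
    init_fractions: tuple[float, ...] = (0.03, 0.2, 0.54, 0.03, 0.05, 0.15)

    def __post_init__(self) -> None:
        for name in ("C_SA", "C_SV", "C_PA", "C_PV", "R_sys", "R_pul",
                     "Rt_SA", "Rt_PA", "Rm", "Rt", "Vu_SA", "Vu_SV",
                     "Vu_PA", "Vu_PV", "TBV"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.Vu_SA + self.Vu_SV + self.Vu_PA + self.Vu_PV >= self.TBV:
            raise ConfigError("unstressed volumes must total below TBV")


def derive_circulation_parameters(
        subject: SubjectData,
        compartments: dict[str, CompartmentRow],
        constants: ModelConstants | None = None,
        disease: bool = False) -> CirculationParams:
    """Parameterize the vasculature from the subject and fraction table.

    Compartment total volume = fraction x TBV; unstressed volume =
    unstressed fraction x compartment volume (the disease column lowers the
    unstressed fractions, raising stressed volume); compliance = maximal
    stressed volume / maximal pressure; R_sys and R_pul from the mean
    pressure drops over nominal cardiac output SV x HR.
    """
    constants = constants or ModelConstants()
    total = sum(row.fraction for row in compartments.values())
    if abs(total - 1.0) > 1.0e-9:
        raise ConfigError(f"compartment fractions sum to {total}, not 1")

    def _vu_c(name: str) -> tuple[float, float]:
        row = compartments[name]
        vol = row.fraction * subject.TBV
        fu = row.unstressed_disease if disease else row.unstressed_healthy
        vu = fu * vol
        comp = (vol - vu) / row.P_max
        return vu, comp

    vu_sa, c_sa = _vu_c("SA")
    vu_sv, c_sv = _vu_c("SV")
    vu_pa, c_pa = _vu_c("PA")
    vu_pv, c_pv = _vu_c("PV")
    co = subject.cardiac_output  # mL/s
    r_sys = (compartments["SA"].P_mean - compartments["SV"].P_mean) / co
    r_pul = (compartments["PA"].P_mean - compartments["PV"].P_mean) / co
    return CirculationParams(
        C_SA=c_sa, C_SV=c_sv, C_PA=c_pa, C_PV=c_pv,
        R_sys=r_sys, R_pul=r_pul,
        Rt_SA=constants.Rt_SA, Rt_PA=constants.Rt_PA,
        Rm=constants.Rm, Rt=constants.Rt,
        Vu_SA=vu_sa, Vu_SV=vu_sv, Vu_PA=vu_pa, Vu_PV=vu_pv,
        TBV=subject.TBV,
        init_fractions=tuple(compartments[c].fraction for c in COMPARTMENTS),
    )


def valve_flow(P_upstream: float, P_downstream: float, R: float) -> float:
    """Ideal-diode valve: forward flow only, max(dP, 0)/R (mL/s)."""
    if not R > 0:
        raise ValueError("valve resistance must be positive")
    return max(P_upstream - P_downstream, 0.0) / R


def compartment_pressure(V: float, Vu: float, C: float,
                         q_net: float = 0.0, Rt: float = 0.0) -> float:
    """Elastic (V - Vu)/C plus viscoelastic Rt q_net pressure (mmHg)."""
    if not C > 0:
        raise ValueError("compliance must be positive")
    return (V - Vu) / C + Rt * q_net


def system_rhs(t: float, y: np.ndarray, model) -> np.ndarray:
    """State derivative of the nine-component closed-loop system.

    Thin wrapper over the JIT core for inspection and testing; `simulate`
    drives the core directly.
    """
    par = model.par_vector()
    u = np.array(DEFAULT_DISPLACEMENTS)
    dy = np.empty(_core.NSTATE)
    obs = np.empty(_core.NOBS)
    if _core.rhs(t, np.asarray(y, dtype=float), par, u, dy, obs) < 0:
        raise JunctionSolveError(np.full(4, np.nan))
    return dy


@dataclass
class SimulationResult:
    """Dense time series of the recorded beats plus beat bookkeeping."""

    t: np.ndarray          # s, recorded beats only
    y: np.ndarray          # (N, 9) volumes + contractile lengths
    obs: np.ndarray        # (N, NOBS) pressures, flows, curvature, ...
    T: float               # beat period, s
    HR: float
    tbv: float
    n_transient: int
    n_record: int
    beat_ends: np.ndarray  # (n_transient + n_record, 9) state at beat ends
    periodic: bool

    def _col(self, idx: int) -> np.ndarray:
        return self.obs[:, idx]

    @property
    def V_LV(self):
        return self.y[:, _core.IV_LV]

    @property
    def V_RV(self):
        return self.y[:, _core.IV_RV]

    @property
    def P_LV(self):
        return self._col(_core.OP_LV)

    @property
    def P_RV(self):
        return self._col(_core.OP_RV)

    @property
    def P_SA(self):
        return self._col(_core.OP_SA)

    @property
    def Cm_SW(self):
        return self._col(_core.OCM_SW)

    @property
    def total_volume(self) -> np.ndarray:
        return self.y[:, :6].sum(axis=1)

    def beat_slice(self, k: int) -> slice:
        """Samples of recorded beat ``k`` (0-based within the recording)."""
        n = len(self.t) // self.n_record
        return slice(k * n, (k + 1) * n)

    def last_beat(self) -> "SimulationResult":
        sl = self.beat_slice(self.n_record - 1)
        return replace(self, t=self.t[sl], y=self.y[sl], obs=self.obs[sl],
                       n_record=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "t": self.t,
            "V_LV": self.V_LV, "V_RV": self.V_RV,
            "V_SA": self.y[:, _core.IV_SA], "V_SV": self.y[:, _core.IV_SV],
            "V_PA": self.y[:, _core.IV_PA], "V_PV": self.y[:, _core.IV_PV],
            "P_LV": self.P_LV, "P_RV": self.P_RV,
            "P_SA": self.P_SA, "P_SV": self._col(_core.OP_SV),
            "P_PA": self._col(_core.OP_PA), "P_PV": self._col(_core.OP_PV),
            "q_mitral": self._col(_core.OQ_MIT),
            "q_aortic": self._col(_core.OQ_AO),
            "q_systemic": self._col(_core.OQ_SYS),
            "q_tricuspid": self._col(_core.OQ_TRI),
            "q_pulmonary_valve": self._col(_core.OQ_PV),
            "q_pulmonary": self._col(_core.OQ_PUL),
            "Cm_SW": self.Cm_SW,
            "P_peri": self._col(_core.OP_PERI),
            "activation": self._col(_core.OY),
            "Lc_LW": self.y[:, _core.ILC_LW],
            "Lc_SW": self.y[:, _core.ILC_SW],
            "Lc_RW": self.y[:, _core.ILC_RW],
            "xm_LW": self._col(_core.OXM_LW),
            "xm_SW": self._col(_core.OXM_SW),
            "xm_RW": self._col(_core.OXM_RW),
            "ym": self._col(_core.OYM),
        })
        return df


class IntegrationError(RuntimeError):
    pass


def initial_state(model, tbv: float | None = None) -> np.ndarray:
    """Distribute the circulating volume over compartments and relax Lc.

    Volumes follow the configured compartment fractions of the actual
    circulating volume; contractile lengths start at their passive
    equilibrium Ls - L_se_iso for the initial wall configuration.
    """
    from .core import solve_wall_configuration

    tbv = model.circulation.TBV if tbv is None else tbv
    frac = np.asarray(model.circulation.init_fractions)
    y0 = np.empty(_core.NSTATE)
    y0[:6] = frac * tbv
    lse = model.sarcomere.L_se_iso
    _, walls = solve_wall_configuration(
        y0[_core.IV_LV], y0[_core.IV_RV],
        [model.sarcomere.L_ref] * 3, 0.0,
        model.geometry, model.walls, model.sarcomere)
    for k, w in enumerate(("LW", "SW", "RW")):
        y0[_core.ILC_LW + k] = walls[w].Ls - lse
    return y0


def simulate(model, tbv: float | None = None,
             n_transient: int = 20, n_record: int = 2,
             settings: SimulationSettings | None = None,
             y0: np.ndarray | None = None) -> SimulationResult:
    """Integrate the closed loop to periodicity and record dense beats.

    Runs ``n_transient`` beats to wash out initial conditions, then
    ``n_record`` beats sampled densely for metric extraction.  Warns when
    the last two beats disagree by more than 0.1% (non-periodic).
    """
    settings = settings or SimulationSettings()
    par = model.par_vector()
    T = model.activation.T
    tbv = model.circulation.TBV if tbv is None else tbv
    if y0 is None:
        y0 = initial_state(model, tbv)
    y = np.array(y0, dtype=float)

    warm = np.array(DEFAULT_DISPLACEMENTS)
    dy_buf = np.empty(_core.NSTATE)
    obs_buf = np.empty(_core.NOBS)

    def f(t, yy):
        if _core.rhs(t, yy, par, warm, dy_buf, obs_buf) < 0:
            raise IntegrationError(
                f"TriSeg junction solve failed at t={t:.4f}s")
        return dy_buf.copy()

    n_total = n_transient + n_record
    beat_ends = np.empty((n_total, _core.NSTATE))
    ts, ys = [], []
    for k in range(n_total):
        t0, t1 = k * T, (k + 1) * T
        record = k >= n_transient
        t_eval = (np.linspace(t0, t1, settings.samples_per_beat + 1)
                  if record else None)
        sol = solve_ivp(f, (t0, t1), y, method=settings.method,
                        rtol=settings.rtol, atol=settings.atol,
                        t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise IntegrationError(f"integration failed in beat {k + 1}: "
                                   f"{sol.message}")
        if record:
            # keep the half-open sample grid; the beat-end state seeds the
            # next beat (and the next beat's first sample repeats it)
            ts.append(sol.t[:-1])
            ys.append(sol.y.T[:-1])
        y = sol.y[:, -1].copy()
        beat_ends[k] = y

    t = np.concatenate(ts)
    ymat = np.vstack(ys)
    # re-solve the wall configuration along the recorded samples
    obs = np.empty((len(t), _core.NOBS))
    warm2 = np.array(DEFAULT_DISPLACEMENTS)
    for i in range(len(t)):
        if _core.observe(t[i], ymat[i], par, warm2, obs[i]) < 0:
            raise IntegrationError(
                f"wall solve failed while recording at t={t[i]:.4f}s")

    scale = np.maximum(np.abs(beat_ends[-1]), 1.0e-9)
    drift = np.max(np.abs(beat_ends[-1] - beat_ends[-2]) / scale)
    periodic = bool(drift < 1.0e-3)
    if not periodic:
        warnings.warn(f"simulation not periodic after {n_transient} beats "
                      f"(relative beat-to-beat drift {drift:.2e})",
                      RuntimeWarning, stacklevel=2)
    vol_err = np.max(np.abs(ymat[:, :6].sum(axis=1) - tbv)) / tbv
    if vol_err > 1.0e-6:
        warnings.warn(f"closed-loop volume drift {vol_err:.2e} exceeds 1e-6",
                      RuntimeWarning, stacklevel=2)
    return SimulationResult(t=t, y=ymat, obs=obs, T=T, HR=model.subject.HR,
                            tbv=tbv, n_transient=n_transient,
                            n_record=n_record, beat_ends=beat_ends,
                            periodic=periodic)
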