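"""Assembled heart + circulation model.

:class:`CardioModel` bundles the calibrated reference geometry, sarcomere
constants, per-wall stress scalings, pericardium and circulation parameters,
and knows how to lay them out as the flat parameter vector the JIT core
consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _core
from .circulation import CirculationParams
from .config import SubjectData
from .core import PericardiumParams
from .geometry import ReferenceGeometry, WALLS
from .sarcomere import ActivationParams, SarcomereParams, WallProperties


@dataclass
class CardioModel:
    subject: SubjectData
    geometry: ReferenceGeometry
    sarcomere: SarcomereParams
    activation: ActivationParams
    walls: dict[str, WallProperties]
    pericardium: PericardiumParams
    circulation: CirculationParams
    gamma: float

    def par_vector(self) -> np.ndarray:
        par = np.zeros(_core.NPAR)
        for k, w in enumerate(WALLS):
            par[_core.VW_LW + k] = self.geometry.wall(w).Vw
            par[_core.AMREF_LW + k] = self.geometry.wall(w).Am_ref
            par[_core.KPAS_LW + k] = self.walls[w].k_pas
            par[_core.KACT_LW + k] = self.walls[w].k_act
        s = self.sarcomere
        par[_core.LREF] = s.L_ref
        par[_core.LC0] = s.L_c0
        par[_core.LSE_ISO] = s.L_se_iso
        par[_core.VMAX] = s.v_max
        par[_core.GAMMA] = s.gamma
        par[_core.NU_L] = s.nu_L
        par[_core.PERIOD] = self.activation.T
        par[_core.T_S] = self.activation.T_S
        par[_core.T_R] = self.activation.T_R
        par[_core.PERI_S] = self.pericardium.s
        par[_core.PERI_VH0] = self.pericardium.Vh_0
        par[_core.PERI_ON] = 1.0 if self.pericardium.enabled else 0.0
        c = self.circulation
        par[_core.C_SA] = c.C_SA
        par[_core.C_SV] = c.C_SV
        par[_core.C_PA] = c.C_PA
        par[_core.C_PV] = c.C_PV
        par[_core.VU_SA] = c.Vu_SA
        par[_core.VU_SV] = c.Vu_SV
        par[_core.VU_PA] = c.Vu_PA
        par[_core.VU_PV] = c.Vu_PV
        par[_core.R_SYS] = c.R_sys
        par[_core.R_PUL] = c.R_pul
        par[_core.RT_SA] = c.Rt_SA
        par[_core.RT_PA] = c.Rt_PA
        par[_core.R_MITRAL] = c.Rm
        par[_core.R_TRICUSPID] = c.Rt
        return par

    def with_walls(self, walls: dict[str, WallProperties]) -> "CardioModel":
        return dataclasses.replace(self, walls=walls)

    def with_circulation(self, circ: CirculationParams) -> "CardioModel":
        return dataclasses.replace(self, circulation=circ)

    def with_heart_rate(self, hr: float) -> "CardioModel":
        act = ActivationParams(T=60.0 / hr, k_TS=self.activation.k_TS,
                               k_TR=self.activation.k_TR)
        subj = dataclasses.replace(self.subject, HR=hr)
        return dataclasses.replace(self, activation=act, subject=subj)

    def without_pericardium(self) -> "CardioModel":
        peri = dataclasses.replace(self.pericardium, enabled=False)
        return dataclasses.replace(self, pericardium=peri)
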