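"""Configuration: subject data, fixed model constants and compartment tables.

The defaults describe a normative healthy 70 kg adult.  Every block can be
overridden from a YAML file whose keys mirror the dataclass fields, e.g. ::

    subject:
      EDV_LV: 140.0
      HR: 80.0
    constants:
      h_RW: 0.5

Units follow the package convention: mmHg, mL, cm, s, um.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class SubjectData:
    """Normative scalar hemodynamic measurements for one subject.

    ``ESP_LV`` defaults to 1.05 x mean systolic pressure (the lumped
    circulation carries no pulse-wave amplification) and ``EDP_RV`` to a
    quarter of the LV end-diastolic pressure; pass explicit values to
    override either derivation.
    """

    SBP_bar: float = 120.0   # mean systolic arterial pressure, mmHg
    DBP_bar: float = 80.0    # mean diastolic arterial pressure, mmHg
    EDP_LV: float = 5.0      # mmHg
    ESP_RV: float = 25.0     # mmHg
    ESV_LV: float = 50.0     # mL
    EDV_LV: float = 125.0    # mL
    EDV_RV: float = 125.0    # mL
    TBV: float = 5000.0      # total blood volume, mL
    HR: float = 60.0         # beats per minute
    ESP_LV: float | None = None
    EDP_RV: float | None = None
    ESV_RV: float | None = None

    def __post_init__(self) -> None:
        if self.ESP_LV is None:
            self.ESP_LV = 1.05 * self.SBP_bar
        if self.EDP_RV is None:
            self.EDP_RV = self.EDP_LV / 4.0
        if self.ESV_RV is None:
            self.ESV_RV = self.ESV_LV
        self.validate()

    def validate(self) -> None:
        for name in ("SBP_bar", "DBP_bar", "ESP_LV", "EDP_LV", "ESP_RV",
                     "EDP_RV", "ESV_LV", "EDV_LV", "ESV_RV", "EDV_RV",
                     "TBV", "HR"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")
        if self.EDV_LV <= self.ESV_LV or self.EDV_RV <= self.ESV_RV:
            raise ValueError("EDV must exceed ESV for both ventricles")
        if self.SBP_bar <= self.DBP_bar:
            raise ValueError("systolic pressure must exceed diastolic")

    @property
    def stroke_volume(self) -> float:
        return self.EDV_LV - self.ESV_LV

    @property
    def cardiac_output(self) -> float:
        """Nominal cardiac output in mL/s (SV x HR)."""
        return self.stroke_volume * self.HR / 60.0


@dataclass
class ModelConstants:
    """Fixed cardiac, activation and pericardial constants."""

    # circulation
    Rt_SA: float = 0.08      # systemic arterial viscoelastic R, mmHg s/mL
    Rt_PA: float = 0.02      # pulmonary arterial viscoelastic R, mmHg s/mL
    Rm: float = 5.0e-4       # mitral valve resistance, mmHg s/mL
    Rt: float = 5.0e-4       # tricuspid valve resistance, mmHg s/mL
    # wall thicknesses (cm); LW and SW share the LV thickness
    h_LV: float = 0.8
    h_RW: float = 0.4
    # sarcomere
    L_ref: float = 2.0       # reference sarcomere length, um
    L_c0: float = 1.51       # slack contractile length, um
    L_se_iso: float = 0.04   # isometric series-elastic length, um
    v_max: float = 3.5       # shortening velocity, um/s
    nu_L: float = 1.0        # unit conversion, 1/um
    gamma: float = 7.5       # passive length-tension steepness (calibrated)
    # activation
    k_TS: float = 0.2
    k_TR: float = 0.2
    # pericardium
    peri_s: float = 10.0


#: Table of compartment volume fractions and pressure landmarks
#: (fraction of TBV, unstressed fraction healthy / disease, P max/mean/min).
@dataclass
class CompartmentRow:
    fraction: float
    unstressed_healthy: float | None
    unstressed_disease: float | None
    P_max: float | None
    P_mean: float | None
    P_min: float | None


def default_compartments() -> dict[str, CompartmentRow]:
    return {
        "LV": CompartmentRow(0.03, None, None, 121.0, None, 4.0),
        "SA": CompartmentRow(0.20, 0.70, 0.60, 120.0, 95.0, 80.0),
        "SV": CompartmentRow(0.54, 0.90, 0.80, 6.0, 4.0, 4.0),
        "RV": CompartmentRow(0.03, None, None, 26.0, None, 4.0),
        "PA": CompartmentRow(0.05, 0.40, 0.35, 25.0, 15.0, 10.0),
        "PV": CompartmentRow(0.15, 0.90, 0.75, 8.0, 5.0, 2.0),
    }


@dataclass
class SimulationSettings:
    """Numerical protocol: 20 transient beats + 2 recorded, stiff integrator."""

    n_transient: int = 20
    n_record: int = 2
    samples_per_beat: int = 1000
    rtol: float = 1.0e-6
    atol: float = 1.0e-8
    method: str = "BDF"


@dataclass
class Config:
    subject: SubjectData = field(default_factory=SubjectData)
    constants: ModelConstants = field(default_factory=ModelConstants)
    compartments: dict[str, CompartmentRow] = field(
        default_factory=default_compartments)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)


def default_config() -> Config:
    return Config()


def load_config(path: str) -> Config:
    """Load a YAML configuration, overriding defaults block by block."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = Config()
    if "subject" in raw:
        base = {f.name: getattr(cfg.subject, f.name)
                for f in dataclasses.fields(SubjectData)}
        base.update(raw["subject"])
        cfg.subject = SubjectData(**base)
    if "constants" in raw:
        cfg.constants = dataclasses.replace(cfg.constants, **raw["constants"])
    if "simulation" in raw:
        cfg.simulation = dataclasses.replace(cfg.simulation,
                                             **raw["simulation"])
    for name, row in (raw.get("compartments") or {}).items():
        if name not in cfg.compartments:
            raise ValueError(f"unknown compartment {name!r}")
        cfg.compartments[name] = dataclasses.replace(
            cfg.compartments[name], **row)
    return cfg


def dump_config(cfg: Config, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
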