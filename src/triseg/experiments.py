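"""Dysfunction and volume-loading experiments, metric extraction.

Acute ventricular dysfunction scales the calibrated wall properties
(k_act down for systolic, k_pas up for diastolic; the septum counts as part
of the LV) and activates the disease unstressed-volume fractions.  The
volume-loading protocol raises circulating blood volume and the
compensation search finds the volume at which cycle-mean systemic arterial
pressure reaches the target (~95 mmHg), the common baseline for comparing
cases.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core
from .calibration import calibrate
from .circulation import (IntegrationError, SimulationResult,
                          derive_circulation_parameters, simulate)
from .config import Config, SimulationSettings
from .model import CardioModel
from .sarcomere import WallProperties

#: Work unit conversion: 1 mmHg mL in joules.
JOULE_PER_MMHG_ML = 1.33322e-4

SYSTOLIC_SCALE = {"healthy": 1.0, "moderate": 0.6, "severe": 0.4}
DIASTOLIC_SCALE = {"healthy": 1.0, "moderate": 7.0, "severe": 15.0}


@dataclass(frozen=True)
class DysfunctionSpec:
    """Which ventricle is impaired, how, and how badly."""

    target: str     # "LV" | "RV"
    mode: str       # "systolic" | "diastolic"
    severity: str   # "healthy" | "moderate" | "severe"

    def __post_init__(self) -> None:
        if self.target not in ("LV", "RV"):
            raise ValueError("target must be LV or RV")
        if self.mode not in ("systolic", "diastolic"):
            raise ValueError("mode must be systolic or diastolic")
        if self.severity not in ("healthy", "moderate", "severe"):
            raise ValueError("severity must be healthy, moderate or severe")

    @property
    def walls(self) -> tuple[str, ...]:
        # the septum is considered part of the LV
        return ("LW", "SW") if self.target == "LV" else ("RW",)

    @property
    def label(self) -> str:
        code = {"systolic": "SD", "diastolic": "DD"}[self.mode]
        sev = {"healthy": "H", "moderate": "M", "severe": "S"}[self.severity]
        return f"{self.target}{code}-{sev}"


def apply_dysfunction(props: dict[str, WallProperties],
                      spec: DysfunctionSpec) -> dict[str, WallProperties]:
    """Scale the targeted walls' k_act (systolic) or k_pas (diastolic)."""
    out = dict(props)
    if spec.severity == "healthy":
        return out
    for w in spec.walls:
        p = props[w]
        if spec.mode == "systolic":
            out[w] = WallProperties(p.k_pas,
                                    p.k_act * SYSTOLIC_SCALE[spec.severity])
        else:
            out[w] = WallProperties(p.k_pas * DIASTOLIC_SCALE[spec.severity],
                                    p.k_act)
    return out


def dysfunction_model(model: CardioModel, spec: DysfunctionSpec,
                      config: Config) -> CardioModel:
    """Dysfunction-scaled model with the disease unstressed-volume column."""
    out = model.with_walls(apply_dysfunction(model.walls, spec))
    if spec.severity != "healthy":
        circ = derive_circulation_parameters(model.subject,
                                             config.compartments,
                                             config.constants, disease=True)
        out = out.with_circulation(circ)
    return out


@dataclass(frozen=True)
class BeatMetrics:
    """Per-ventricle per-beat functional metrics."""

    SV: float    # mL
    EF: float    # %
    CO: float    # L/min
    CPO: float   # W, pressure-volume loop area x heart rate
    CPO_map: float  # W, secondary diagnostic: mean ejection P x CO
    ESP: float   # mmHg
    EDP: float   # mmHg
    ESV: float   # mL
    EDV: float   # mL


def _loop_area(p: np.ndarray, v: np.ndarray) -> float:
    """Signed pressure-volume loop area (mmHg mL), positive for a pump."""
    dv = np.roll(v, -1) - np.roll(v, 1)
    return float(-0.5 * np.sum(p * dv))


def _ventricle_metrics(p: np.ndarray, v: np.ndarray, hr: float) -> BeatMetrics:
    # The volume trace is flat through the isovolumic phases, so the raw
    # argmax/argmin can land anywhere on a plateau where pressure swings by
    # tens of mmHg.  Take the PV-loop corners instead: among samples within
    # a small tolerance of the volume extremum, end-diastole is the
    # lowest-pressure sample and end-systole the highest-pressure one.
    edv = float(v.max())
    esv = float(v.min())
    tol = max(1.0e-3 * (edv - esv), 1.0e-9)
    ed_candidates = np.nonzero(v >= edv - tol)[0]
    es_candidates = np.nonzero(v <= esv + tol)[0]
    i_ed = int(ed_candidates[np.argmin(p[ed_candidates])])
    i_es = int(es_candidates[np.argmax(p[es_candidates])])
    sv = edv - esv
    ef = 100.0 * sv / edv
    co = sv * hr / 1000.0
    area = _loop_area(p, v)
    cpo = area * JOULE_PER_MMHG_ML * hr / 60.0
    map_proxy = float(np.mean(p)) * co * 1000.0 / 60.0 * JOULE_PER_MMHG_ML
    return BeatMetrics(SV=sv, EF=ef, CO=co, CPO=cpo, CPO_map=map_proxy,
                       ESP=float(p[i_es]), EDP=float(p[i_ed]),
                       ESV=esv, EDV=edv)


def cardiac_metrics(result: SimulationResult,
                    HR: float | None = None) -> dict[str, BeatMetrics]:
    """Metrics of the final recorded beat for both ventricles.

    EDV/ESV are the beat's volume extrema; EDP/ESP the pressures at those
    instants; CPO is the loop area times beat frequency (the clinical
    MAP x CO product is attached as a secondary diagnostic).
    """
    hr = HR if HR is not None else result.HR
    beat = result.last_beat()
    if not result.periodic:
        warnings.warn("metrics extracted from a non-periodic beat",
                      RuntimeWarning, stacklevel=2)
    return {"LV": _ventricle_metrics(beat.P_LV, beat.V_LV, hr),
            "RV": _ventricle_metrics(beat.P_RV, beat.V_RV, hr)}


def mean_systemic_pressure(result: SimulationResult) -> float:
    """Cycle-averaged systemic arterial pressure of the final beat (mmHg)."""
    beat = result.last_beat()
    return float(np.trapezoid(beat.P_SA, beat.t) / (beat.t[-1] - beat.t[0]))


@dataclass
class SeptalCurvature:
    """Septal curvature time course with cardiac-phase annotations."""

    t: np.ndarray
    Cm_SW: np.ndarray
    ejection: np.ndarray           # boolean mask, aortic valve open
    isovolumic_relaxation: np.ndarray
    filling: np.ndarray            # mitral valve open
    plateau: float                 # mean curvature over isovolumic relaxation
    diastolic_min: float           # minimum curvature during filling
    minimum: float                 # global minimum over the beat


def septal_curvature_timecourse(result: SimulationResult) -> SeptalCurvature:
    """Extract the septal midwall curvature of the final beat.

    Phases come from the valve flows: ejection while the aortic valve
    carries flow, isovolumic relaxation between aortic closure and mitral
    opening, filling while the mitral valve carries flow.
    """
    beat = result.last_beat()
    q_ao = beat.obs[:, _core.OQ_AO]
    q_mit = beat.obs[:, _core.OQ_MIT]
    tol_ao = 1.0e-6 * max(q_ao.max(), 1.0)
    tol_mit = 1.0e-6 * max(q_mit.max(), 1.0)
    ejecting = q_ao > tol_ao
    filling = q_mit > tol_mit
    if not ejecting.any():
        raise ValueError("no ejection detected on the recorded beat")
    i_close = int(np.max(np.nonzero(ejecting)))
    after = np.arange(len(beat.t)) > i_close
    open_after = after & filling
    i_open = int(np.min(np.nonzero(open_after))) if open_after.any() \
        else len(beat.t)
    ivr = after & (np.arange(len(beat.t)) < i_open)
    cm = beat.Cm_SW
    dia_min = float(cm[filling].min()) if filling.any() else float(cm.min())
    return SeptalCurvature(
        t=beat.t, Cm_SW=cm, ejection=ejecting,
        isovolumic_relaxation=ivr, filling=filling,
        plateau=float(cm[ivr].mean()) if ivr.any() else float("nan"),
        diastolic_min=dia_min, minimum=float(cm.min()))


@dataclass
class LoadingPoint:
    fraction: float
    tbv: float
    mean_Psa: float
    metrics: dict[str, BeatMetrics]
    failed: bool = False


@dataclass
class LoadingSweepResult:
    points: list[LoadingPoint]

    def frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            row = {"fraction": p.fraction, "TBV": p.tbv,
                   "mean_Psa": p.mean_Psa, "failed": p.failed}
            if not p.failed:
                for side in ("LV", "RV"):
                    m = p.metrics[side]
                    for f in dataclasses.fields(m):
                        row[f"{side}_{f.name}"] = getattr(m, f.name)
            rows.append(row)
        return pd.DataFrame(rows)

    def locus(self, side: str, which: str) -> np.ndarray:
        """ES or ED (volume, pressure) locus across the sweep."""
        pts = [p for p in self.points if not p.failed]
        if which == "ES":
            return np.array([(p.metrics[side].ESV, p.metrics[side].ESP)
                             for p in pts])
        if which == "ED":
            return np.array([(p.metrics[side].EDV, p.metrics[side].EDP)
                             for p in pts])
        raise ValueError("which must be 'ES' or 'ED'")

    def frank_starling(self, side: str) -> np.ndarray:
        """(EDP, SV) pairs across the sweep."""
        pts = [p for p in self.points if not p.failed]
        return np.array([(p.metrics[side].EDP, p.metrics[side].SV)
                         for p in pts])


def volume_loading_sweep(model: CardioModel, fractions=None,
                         n_transient: int = 20, n_record: int = 2,
                         settings: SimulationSettings | None = None
                         ) -> LoadingSweepResult:
    """Run the model across a grid of circulating-volume fractions.

    Each point runs to periodicity and records beat metrics; integration
    failures at extreme loading are kept as flagged partial results.
    """
    if fractions is None:
        fractions = np.arange(1.0, 3.5 + 1.0e-9, 0.1)
    pts = []
    for f in np.asarray(fractions, dtype=float):
        tbv = f * model.circulation.TBV
        try:
            res = simulate(model, tbv=tbv, n_transient=n_transient,
                           n_record=n_record, settings=settings)
            pts.append(LoadingPoint(f, tbv, mean_systemic_pressure(res),
                                    cardiac_metrics(res)))
        except IntegrationError:
            pts.append(LoadingPoint(f, tbv, float("nan"), {}, failed=True))
    return LoadingSweepResult(pts)


@dataclass
class CompensationResult:
    tbv: float
    mean_Psa: float
    compensated: bool
    n_evaluations: int
    result: SimulationResult   # simulation at the returned TBV


def find_compensated_tbv(model: CardioModel, target_mean_Psa: float = 95.0,
                         bracket: tuple[float, float] = (0.7, 3.5),
                         tol: float = 0.5, n_transient: int = 20,
                         n_record: int = 2,
                         settings: SimulationSettings | None = None
                         ) -> CompensationResult:
    """Volume-load until cycle-mean systemic pressure hits the target.

    Safeguarded secant iteration on the (monotone) mean-pressure-vs-volume
    relation, bracketed by ``bracket`` x nominal TBV.  If the target is not
    reachable within the bracket the boundary result is returned with
    ``compensated=False`` (never an exception).
    """
    nominal = model.circulation.TBV
    lo, hi = bracket[0] * nominal, bracket[1] * nominal
    cache: dict[float, tuple[float, SimulationResult]] = {}

    def eval_at(tbv: float) -> float | None:
        """Cycle-mean Psa minus target; None when integration fails."""
        if tbv not in cache:
            try:
                res = simulate(model, tbv=tbv, n_transient=n_transient,
                               n_record=n_record, settings=settings)
            except IntegrationError:
                return None
            cache[tbv] = (mean_systemic_pressure(res), res)
        return cache[tbv][0] - target_mean_Psa

    def finish(tbv: float, compensated: bool) -> CompensationResult:
        psa, res = cache[tbv]
        return CompensationResult(tbv=tbv, mean_Psa=psa,
                                  compensated=compensated,
                                  n_evaluations=len(cache), result=res)

    def best_available() -> CompensationResult:
        tbv = min(cache, key=lambda x: abs(cache[x][0] - target_mean_Psa))
        return finish(tbv, abs(cache[tbv][0] - target_mean_Psa) <= tol)

    # walk from the nominal volume toward a sign change (f monotone in TBV)
    x = min(max(nominal, lo), hi)
    f = eval_at(x)
    if f is None:
        raise IntegrationError("simulation failed at the nominal volume")
    if abs(f) <= tol:
        return finish(x, True)
    xa = xb = x
    fa = fb = f
    factor = 0.9 if f > 0 else 1.25
    at_edge = False
    while fa * fb > 0:
        xn = x * factor
        if not lo < xn < hi:
            xn = lo if f > 0 else hi
            at_edge = True
        fn = eval_at(xn)
        if fn is None:
            # infeasible volume: treat the last feasible point as the edge
            return best_available()
        if abs(fn) <= tol:
            return finish(xn, True)
        if fn < 0:
            xa, fa = xn, fn
        else:
            xb, fb = xn, fn
        if at_edge and fa * fb > 0:
            return best_available()   # target outside the bracket
        x = xn
    # secant with bisection safeguard inside the sign-changing bracket
    for _ in range(30):
        xn = xb - fb * (xb - xa) / (fb - fa) if fb != fa else 0.5 * (xa + xb)
        if not min(xa, xb) < xn < max(xa, xb):
            xn = 0.5 * (xa + xb)
        fn = eval_at(xn)
        if fn is None:
            return best_available()
        if abs(fn) <= tol:
            return finish(xn, True)
        if fn < 0:
            xa, fa = xn, fn
        else:
            xb, fb = xn, fn
    return best_available()


ALL_CASES = [DysfunctionSpec("LV", "systolic", "moderate"),
             DysfunctionSpec("LV", "systolic", "severe"),
             DysfunctionSpec("LV", "diastolic", "moderate"),
             DysfunctionSpec("LV", "diastolic", "severe"),
             DysfunctionSpec("RV", "systolic", "moderate"),
             DysfunctionSpec("RV", "systolic", "severe"),
             DysfunctionSpec("RV", "diastolic", "moderate"),
             DysfunctionSpec("RV", "diastolic", "severe")]


@dataclass
class StudyCase:
    label: str
    spec: DysfunctionSpec | None
    compensation: CompensationResult | None
    metrics: dict[str, BeatMetrics] | None
    curvature: SeptalCurvature | None
    error: str | None = None


@dataclass
class StudyReport:
    model: CardioModel
    calibration: dict
    cases: list[StudyCase] = field(default_factory=list)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for case in self.cases:
            if case.metrics is None:
                continue
            for side in ("LV", "RV"):
                m = case.metrics[side]
                rows.append({
                    "case": case.label, "ventricle": side,
                    "SV_mL": m.SV, "EF_pct": m.EF, "CO_L_min": m.CO,
                    "CPO_W": m.CPO, "ESP_mmHg": m.ESP, "EDP_mmHg": m.EDP,
                    "ESV_mL": m.ESV, "EDV_mL": m.EDV,
                    "TBV_mL": case.compensation.tbv,
                    "compensated": case.compensation.compensated,
                })
        return pd.DataFrame(rows)


def run_study(config: Config, cases: list[DysfunctionSpec] | None = None,
              out_dir: str | None = None,
              settings: SimulationSettings | None = None,
              n_transient: int = 20, n_record: int = 2) -> StudyReport:
    """Calibrate, then run healthy + dysfunction cases at full compensation.

    Per-case failures are isolated (recorded with an error message) and the
    study continues.  With ``out_dir`` the metrics table, per-case time
    series and a JSON manifest are written.
    """
    model, cal = calibrate(config)
    report = StudyReport(model=model, calibration=cal)
    all_specs: list[DysfunctionSpec | None] = [None]
    all_specs += list(ALL_CASES if cases is None else cases)
    for spec in all_specs:
        label = "Healthy" if spec is None else spec.label
        m = model if spec is None else dysfunction_model(model, spec, config)
        try:
            comp = find_compensated_tbv(m, n_transient=n_transient,
                                        n_record=n_record, settings=settings)
            metrics = cardiac_metrics(comp.result)
            curv = septal_curvature_timecourse(comp.result)
            report.cases.append(StudyCase(label, spec, comp, metrics, curv))
        except Exception as exc:  # isolate per-case failures
            report.cases.append(StudyCase(label, spec, None, None, None,
                                          error=str(exc)))
    if out_dir is not None:
        write_study(report, out_dir)
    return report


def write_study(report: StudyReport, out_dir: str) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.metrics_frame().to_csv(out / "metrics.csv", index=False)
    manifest = {
        "calibration": {
            "gamma": report.calibration["gamma"],
            "k_pas": report.calibration["k_pas"],
            "k_act": report.calibration["k_act"],
        },
        "subject": dataclasses.asdict(report.model.subject),
        "cases": [{"label": c.label,
                   "compensated": (c.compensation.compensated
                                   if c.compensation else None),
                   "TBV_mL": c.compensation.tbv if c.compensation else None,
                   "error": c.error} for c in report.cases],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    for c in report.cases:
        if c.compensation is not None:
            df = c.compensation.result.to_dataframe()
            df.to_csv(out / f"timeseries_{c.label}.csv", index=False)
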