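"""Spherical reference geometry of the three TriSeg walls.

The left ventricle is modeled as a thick sphere whose wall is split 2/3
(left free wall, LW) : 1/3 (septum, SW); the right free wall (RW) comes
from its own sphere built on the RV end-diastolic volume.  All reference
areas are midwall quantities (the surface halfway through the thickness).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

WALLS = ("LW", "SW", "RW")


class InvalidGeometryError(ValueError):
    """Raised for non-physical volumes or thicknesses."""


def inner_radius(volume: float) -> float:
    """Radius (cm) of a sphere holding ``volume`` mL: (3V / 4 pi)^(1/3)."""
    if not volume > 0:
        raise InvalidGeometryError(f"chamber volume must be > 0, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class WallGeometry:
    """Reference geometry of one wall segment."""

    h: float        # thickness, cm
    r_i: float      # inner radius of the generating sphere, cm
    r_m: float      # midwall radius, cm
    r_o: float      # outer radius, cm
    Am_ref: float   # midwall reference area, cm^2
    Vw: float       # wall volume, mL


@dataclass(frozen=True)
class ReferenceGeometry:
    """Per-wall reference areas and wall volumes derived from the EDVs."""

    LW: WallGeometry
    SW: WallGeometry
    RW: WallGeometry

    def wall(self, name: str) -> WallGeometry:
        return getattr(self, name)

    @property
    def Vw(self) -> dict[str, float]:
        return {w: self.wall(w).Vw for w in WALLS}

    @property
    def Am_ref(self) -> dict[str, float]:
        return {w: self.wall(w).Am_ref for w in WALLS}


def _sphere_wall(edv: float, h: float) -> tuple[float, float, float, float, float]:
    r_i = inner_radius(edv)
    if h < 0 or h >= r_i:
        raise InvalidGeometryError(
            f"wall thickness {h} cm is non-physical for inner radius {r_i:.3g}")
    r_m = r_i + 0.5 * h
    r_o = r_i + h
    am = 4.0 * math.pi * r_m ** 2
    vw = 4.0 / 3.0 * math.pi * r_o ** 3 - edv
    return r_i, r_m, r_o, am, vw


def build_reference_geometry(EDV_LV: float, EDV_RV: float,
                             h_LV: float = 0.8,
                             h_RW: float = 0.4) -> ReferenceGeometry:
    """Construct LW/SW/RW reference geometry from end-diastolic volumes.

    The whole-LV sphere (thickness ``h_LV`` for both LW and SW) is split
    2/3 : 1/3 into free wall and septum; the RW uses its own sphere of
    thickness ``h_RW``.
    """
    r_i, r_m, r_o, am_lv, vw_lv = _sphere_wall(EDV_LV, h_LV)
    lw = WallGeometry(h_LV, r_i, r_m, r_o, 2.0 / 3.0 * am_lv,
                      2.0 / 3.0 * vw_lv)
    sw = WallGeometry(h_LV, r_i, r_m, r_o, 1.0 / 3.0 * am_lv,
                      1.0 / 3.0 * vw_lv)
    r_i, r_m, r_o, am_rw, vw_rw = _sphere_wall(EDV_RV, h_RW)
    rw = WallGeometry(h_RW, r_i, r_m, r_o, am_rw, vw_rw)
    return ReferenceGeometry(LW=lw, SW=sw, RW=rw)


def end_systolic_geometry(esv: float, vw: float, h_ref: float) -> WallGeometry:
    """Spherical end-systolic configuration at chamber volume ``esv``.

    Wall volume is conserved from the end-diastolic construction, so the
    wall thickens as the chamber shrinks.  Used by the active-stress
    calibration.
    """
    r_i = inner_radius(esv)
    r_o = (r_i ** 3 + 3.0 * vw / (4.0 * math.pi)) ** (1.0 / 3.0)
    h = r_o - r_i
    r_m = r_i + 0.5 * h
    return WallGeometry(h, r_i, r_m, r_o, 4.0 * math.pi * r_m ** 2, vw)
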