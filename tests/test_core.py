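"""TriSeg wall mechanics: cap kinematics, tension balance, pressures."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from triseg import _core
from triseg.core import (DegenerateGeometryError, PericardiumParams,
                         cap_geometry, chamber_pressures, junction_residual,
                         pericardial_pressure, solve_wall_configuration,
                         wall_strain_and_length, wall_tension)
from triseg.geometry import ReferenceGeometry, build_reference_geometry
from triseg.sarcomere import SarcomereParams, WallProperties

SARC = SarcomereParams(gamma=7.5)
GEOM = build_reference_geometry(125.0, 125.0)
PASSIVE = {"LW": WallProperties(500.0, 0.0), "SW": WallProperties(500.0, 0.0),
           "RW": WallProperties(150.0, 0.0)}


class TestCapGeometry:
    def test_flat_disc(self):
        c = cap_geometry(0.0, 2.0)
        assert c["Cm"] == 0.0 and c["Vm"] == 0.0
        assert c["Am"] == pytest.approx(math.pi * 4.0)

    @given(r=st.floats(0.5, 8.0))
    def test_hemisphere_identity(self, r):
        c = cap_geometry(r, r)
        assert c["Am"] == pytest.approx(2.0 * math.pi * r ** 2)
        assert c["Cm"] == pytest.approx(1.0 / r)

    def test_hand_value(self):
        c = cap_geometry(1.0, 2.0)
        assert c["Am"] == pytest.approx(15.708, rel=1e-4)
        assert c["Cm"] == pytest.approx(0.4)
        assert c["Vm"] == pytest.approx(6.807, rel=1e-3)

    def test_degenerate_junction(self):
        with pytest.raises(DegenerateGeometryError):
            cap_geometry(1.0, 0.0)


class TestWallStrain:
    def test_reference_configuration(self):
        out = wall_strain_and_length(100.0, 0.0, 50.0, 100.0, L_ref=2.0)
        assert out["eps_f"] == 0.0 and out["Ls"] == 2.0

    def test_area_doubling_limit(self):
        # Am = Am_ref e^2 at zero curvature -> Ls = L_ref e
        out = wall_strain_and_length(100.0 * math.e ** 2, 0.0, 50.0, 100.0,
                                     L_ref=2.0)
        assert out["Ls"] == pytest.approx(2.0 * math.e, rel=1e-12)

    def test_generic_case_matches_independent_expansion(self):
        """Cross-check z, eps_f against a direct re-evaluation."""
        am, cm, vw, am_ref = 120.0, 0.25, 60.0, 100.0
        out = wall_strain_and_length(am, cm, vw, am_ref, L_ref=2.0)
        z = 3.0 * cm * vw / (2.0 * am)
        eps = 0.5 * math.log(am / am_ref) - z ** 2 / 12.0 - 0.019 * z ** 4
        assert out["z"] == pytest.approx(z, rel=1e-14)
        assert out["Ls"] == pytest.approx(2.0 * math.exp(eps), rel=1e-14)


class TestWallTension:
    def test_zero_stress(self):
        t = wall_tension(0.0, 50.0, 100.0, 0.2, 1.0, 2.0)
        assert t["Tm"] == t["Tx"] == t["Ty"] == 0.0

    def test_thin_wall_limit(self):
        t = wall_tension(10.0, 50.0, 100.0, 0.0, 1.0, 2.0)
        assert t["Tm"] == pytest.approx(10.0 * 50.0 / 200.0)

    @given(xm=st.floats(-4.0, 4.0), ym=st.floats(0.5, 5.0),
           sigma=st.floats(0.1, 50.0))
    def test_component_consistency(self, xm, ym, sigma):
        """Tx^2 + Ty^2 = Tm^2 (the components are a rotation of Tm)."""
        t = wall_tension(sigma, 50.0, 100.0, 0.3, xm, ym)
        assert t["Tx"] ** 2 + t["Ty"] ** 2 == pytest.approx(t["Tm"] ** 2,
                                                            rel=1e-12)


class TestPericardium:
    def test_zero_at_reference_volume(self):
        p = PericardiumParams(s=10.0, Vh_0=312.5)
        assert pericardial_pressure(156.25, 156.25, p) == 0.0

    def test_hand_value_ten_percent_over(self):
        p = PericardiumParams(s=10.0, Vh_0=300.0)
        assert pericardial_pressure(165.0, 165.0, p) == \
            pytest.approx(math.e - 1.0, rel=1e-12)

    @given(v=st.floats(50.0, 400.0), dv=st.floats(0.1, 50.0))
    def test_monotone_in_heart_volume(self, v, dv):
        p = PericardiumParams(s=10.0, Vh_0=312.5)
        assert pericardial_pressure(v + dv, v, p) > \
            pericardial_pressure(v, v, p)

    def test_from_edv(self):
        p = PericardiumParams.from_edv(125.0, 125.0)
        assert p.Vh_0 == pytest.approx(312.5)


class TestJunctionSolve:
    def test_residuals_vanish_at_solution(self):
        state, walls = solve_wall_configuration(
            125.0, 125.0, [2.0] * 3, 0.0, GEOM, PASSIVE, SARC)
        r = junction_residual(state.displacements, 125.0, 125.0, [2.0] * 3,
                              0.0, GEOM, PASSIVE, SARC)
        assert abs(r[0]) < 1e-6 and abs(r[1]) < 1e-6       # mL
        assert abs(r[2]) < 1e-7 and abs(r[3]) < 1e-7       # kPa cm
        assert state.ym > 0
        assert state.xm_LW < 0 < state.xm_RW
        assert walls["SW"].Cm > 0   # septum bows into the RV

    def test_fixed_point_restarts_quickly(self):
        """Re-solving from its own solution converges in <= 2 iterations."""
        state, _ = solve_wall_configuration(
            125.0, 125.0, [2.0] * 3, 0.0, GEOM, PASSIVE, SARC)
        from triseg.core import _heart_par
        par = _heart_par(GEOM, PASSIVE, SARC)
        u = state.displacements.copy()
        n = _core.solve_junction(u, 125.0, 125.0, np.full(3, 2.0), 0.0,
                                 par, 1.0e-9, 50)
        assert 0 <= n <= 2

    def test_tolerance_robustness(self):
        """Tightening the Newton tolerance 10x moves pressures < 0.1%."""
        out = []
        for tol in (1.0e-8, 1.0e-9):
            state, walls = solve_wall_configuration(
                125.0, 125.0, [2.0] * 3, 0.0, GEOM, PASSIVE, SARC, tol=tol)
            out.append(chamber_pressures(state, walls)["P_LV"])
        assert out[1] == pytest.approx(out[0], rel=1e-3)

    def test_ty_residual_monotone_near_equilibrium(self):
        """Perturbing ym off the solution flips the radial residual sign."""
        state, _ = solve_wall_configuration(
            125.0, 125.0, [2.0] * 3, 0.0, GEOM, PASSIVE, SARC)
        u = state.displacements
        up, um = u.copy(), u.copy()
        up[3] *= 1.01
        um[3] *= 0.99
        rp = junction_residual(up, 125.0, 125.0, [2.0] * 3, 0.0, GEOM,
                               PASSIVE, SARC)[3]
        rm = junction_residual(um, 125.0, 125.0, [2.0] * 3, 0.0, GEOM,
                               PASSIVE, SARC)[3]
        assert rp * rm < 0

    def test_mirror_symmetry(self):
        """Identical free walls and equal volumes give a flat, unloaded
        septum and mirrored displacements."""
        geom = ReferenceGeometry(LW=GEOM.RW, SW=GEOM.SW, RW=GEOM.RW)
        props = {"LW": WallProperties(200.0, 0.0),
                 "SW": WallProperties(200.0, 0.0),
                 "RW": WallProperties(200.0, 0.0)}
        state, walls = solve_wall_configuration(
            110.0, 110.0, [2.0] * 3, 0.0, geom, props, SARC)
        assert state.xm_RW == pytest.approx(-state.xm_LW, rel=1e-6)
        assert abs(state.xm_SW) < 1e-6 * state.ym
        assert abs(walls["SW"].Tx) < 1e-8 + 1e-6 * abs(walls["LW"].Tx)
        p = chamber_pressures(state, walls)
        assert p["P_LV"] == pytest.approx(p["P_RV"], rel=1e-6)


class TestChamberPressures:
    def test_unstressed_heart_is_pressureless(self):
        """Near-zero wall stress below reference volume gives ~0 pressure."""
        props = {w: WallProperties(1e-3, 0.0) for w in ("LW", "SW", "RW")}
        state, walls = solve_wall_configuration(
            100.0, 100.0, [2.0] * 3, 0.0, GEOM, props, SARC,
            u0=(-3.5, 1.5, 4.0, 3.0))
        p = chamber_pressures(state, walls, peri=None)
        assert abs(p["P_LV"]) < 1e-3 and abs(p["P_RV"]) < 1e-3

    def test_laplace_thin_sphere(self):
        """A thin spherical shell reproduces Laplace's law within 5%.

        The midwall tension is energy-conjugate to area with fiber strain
        half the area strain, so the transmural pressure of a thin sphere
        is 2 sigma_t h / r with tangential stress sigma_t = sigma_fiber/2.
        """
        rm, h, sf = 3.0, 0.1, 10.0
        ro, ri = rm + h / 2.0, rm - h / 2.0
        vw_half = 0.5 * 4.0 / 3.0 * math.pi * (ro ** 3 - ri ** 3)
        cap = cap_geometry(-rm, rm)            # one hemisphere of the shell
        st_out = wall_strain_and_length(cap["Am"], cap["Cm"], vw_half,
                                        cap["Am"], 2.0)
        t = wall_tension(sf, vw_half, cap["Am"], st_out["z"], -rm, rm)
        p_model = -2.0 * t["Tx"] / rm          # kPa
        sigma_t = sf / 2.0
        assert p_model == pytest.approx(2.0 * sigma_t * h / rm, rel=0.05)
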