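# Methods

## Scope and state

The package simulates a closed cardiovascular loop with nine ordinary
differential equations — six compartment volumes (LV, systemic arteries SA,
systemic veins SV, RV, pulmonary arteries PA, pulmonary veins PV) and three
contractile sarcomere lengths (one per wall segment).  The biventricular
heart is the TriSeg idealization introduced by Lumens and co-workers: three
thick-walled spherical caps (left free wall LW, septum SW, right free wall
RW) sharing a circular junction of radius `ym`, with the x axis pointing
from the LV free wall toward the RV free wall (`xm_LW < 0 < xm_RW`;
positive septal curvature = bowing into the RV).  At every instant the four
displacement unknowns `(xm_LW, xm_SW, xm_RW, ym)` satisfy two cap-volume
constraints and the axial/radial tension balance; they are solved
algebraically (quasi-static equilibrium) rather than integrated, keeping
the ODE state small and the solution consistent with the tension balance at
machine precision.

Unit system: cm / mL / mmHg / s for geometry and hemodynamics, kPa for
stress, µm for sarcomere lengths; 1 mmHg = 0.133322 kPa is the only
conversion constant.

## Wall mechanics

Midwall kinematics of a cap: `Am = π(xm² + ym²)`, `Cm = 2xm/(xm² + ym²)`,
cap volume `Vm = (π/6) xm (xm² + 3ym²)`.  The curvature-thickness ratio is
`z = 3 Cm Vw / (2 Am)`, the natural fiber strain
`ε_f = ½ ln(Am/Am_ref) − z²/12 − 0.019 z⁴` and the sarcomere length
`Ls = L_ref e^{ε_f}`.  The representative midwall tension
`Tm = (σ Vw / 2Am)(1 + z²/3 + z⁴/5)` is the energy conjugate of midwall
area (σ dε_f integrated over the wall volume equals Tm dAm); its junction
components are `Tx = Tm · 2 xm ym/(xm²+ym²)`, `Ty = Tm (ym²−xm²)/(xm²+ym²)`
and the transmural pressure of a chamber follows from the axial force
balance on the bounding cap as `2 Tx / ym`.

Because ε_f is *half* the logarithmic area strain, the fiber stress σ is a
biaxial resultant: a thin sphere under fiber stress σ_f sustains
`P = σ_f h / r = 2 σ_t h / r` with the per-direction tangential stress
`σ_t = σ_f / 2` (fibers distributed isotropically in the wall plane carry
half the load per direction).  The thin-shell test in the suite checks this
Laplace limit to better than 0.1 %.

## Sarcomere model

* passive: `σ_pas = (ν_L (Ls − L_c0))^γ`, with ν_L = 1 µm⁻¹ a pure unit
  conversion (any stress scale is absorbed by the calibrated k_pas).
  Below slack (`Ls < L_c0`) physical tension vanishes; a tiny linear
  compressive term (10⁻⁴ × ν_L (Ls − L_c0), well under 0.05 mmHg of chamber
  pressure anywhere) replaces the hard zero so the junction Newton solve
  never becomes singular when a wall goes slack.
* active: `σ_act = ν_L (Lc − L_c0) · ((Ls − Lc)/L_se,iso) · Y(t)`, the
  contractile element in series with an isometrically stressed elastic
  element; `dLc/dt = ((Ls − Lc)/L_se,iso − 1) v_max`.  The activation
  `Y(t)` is a half-cosine rise on `[0, k_TS·T]` and fall on
  `[k_TS·T, (k_TS+k_TR)·T]`, zero otherwise, identical in all three walls
  (no inter-wall delay), with beat onset at t = 0 modulo the period.  The
  activation gates stress only; the Lc kinetics are not gated.

Defaults (all overridable in the YAML config): `L_ref` 2 µm, `L_c0`
1.51 µm, `L_se,iso` 0.04 µm, `v_max` 3.5 µm/s, `k_TS = k_TR = 0.2`,
thicknesses `h_LW = h_SW` 8 mm and `h_RW` 4 mm, pericardial shape `s` 10.

## Reference geometry

The whole LV (LW + SW) and the RV are built as thick spheres on the
end-diastolic volumes: `r_i = (3 EDV/4π)^{1/3}`, `r_m = r_i + h/2`,
`r_o = r_i + h`, `Am_ref = 4π r_m²`, `Vw = (4/3)π r_o³ − EDV`.  The LV
sphere splits 2/3 : 1/3 into free wall and septum (areas and volumes
alike).  Thicknesses are fixed inputs, not derived from the volumes — an
imaging-informed override is the intended subject-specific path.

## Calibration

1. **Klotz single-beat EDPVR.**  From one (EDP, EDV) pair:
   `V0 = EDV(0.6 − 0.006·EDP)`,
   `V30 = V0 + (EDV − V0)/(EDP/An)^{1/Bn}` with the normalized template
   constants `An = 27.78 mmHg`, `Bn = 2.76`; the subject curve is the power
   law `P = α V^β` through (EDV, EDP) and (V30, 30 mmHg).  The RV is
   assumed to share the LV material behavior, so the same construction
   applies with the RV's (EDP, EDV).
2. **γ fit.**  For a trial γ the passive scalings are re-derived, the
   isolated heart (no pericardium, zero activation, both chambers inflated
   together) is solved statically on a 40-point volume grid spanning
   0.5–1.3 × EDV, and γ minimizes the joint LV+RV squared pressure
   residuals against the Klotz curves (`scipy.optimize.least_squares`,
   bounds 1.5–30).  The fit is insensitive to the grid (doubling its
   density moves γ by < 0.1 %) and recovers a generating exponent from
   model-made references to ~10⁻⁵ relative error.
3. **k_pas / k_act.**  Each factor is `target pressure / (Γ · σ)` with Γ
   the chamber pressure produced by unit wall stress at the frozen
   end-diastolic (resp. end-systolic) configuration.  Γ is evaluated
   numerically: a closed-form spherical estimate seeds a fixed-point
   iteration in which the actual TriSeg configuration at (EDV, EDV) — or
   (ESV, ESV) with 60 % activation and isometric contractile lengths
   `Lc = Ls − L_se,iso` — is solved and the LV-side (LW and SW jointly,
   the septum sharing LV material) and RW factors are rescaled until the
   chamber pressures match the measured EDPs/ESPs to 10⁻¹⁰.  The
   end-systolic seed geometry conserves wall volume from end-diastole (the
   wall thickens as the chamber shrinks); re-deriving the wall volume at
   ESV with the end-diastolic thickness instead would push the sarcomere
   below slack and is rejected as unphysical.

## Circulation

Compartment volume = fraction × TBV (fractions 0.03/0.20/0.54/0.03/
0.05/0.15 for LV/SA/SV/RV/PA/PV); unstressed volume = unstressed fraction ×
compartment volume (0.70/0.90/0.40/0.90 for SA/SV/PA/PV healthy; 0.60/0.80/
0.35/0.75 in all dysfunction runs, raising the stressed fraction);
compliance = maximal stressed volume / maximal pressure (giving C_SA 2.5,
C_SV 45, C_PA 6, C_PV 9.375 mL/mmHg at TBV 5 L).  `R_sys = (P̄_SA −
P̄_SV)/CO` and `R_pul = (P̄_PA − P̄_PV)/CO` with CO = SV × HR from the
subject block (1.213 and 0.133 mmHg·s/mL for the default subject).
Ejection passes a diode in series with the viscoelastic resistances
(Rt_SA 0.08, Rt_PA 0.02 mmHg·s/mL); venous-to-ventricular filling passes
the mitral/tricuspid resistances (5·10⁻⁴ mmHg·s/mL).  Valve and
inter-compartment flows are driven by the elastic pressures `(V − Vu)/C`;
the *reported* arterial pressures add the viscoelastic term `Rt · dV/dt`
(which integrates to zero over a periodic beat, so cycle means are
unaffected).  The ventricles have no compliance of their own — their
pressures come exclusively from the wall mechanics — and the ventricular
volume fractions only seed the initial condition.

## Protocols and metrics

Every simulation runs 20 transient beats plus 2 recorded beats sampled at
1000 points per beat (stiff BDF integrator, rtol 10⁻⁶, atol 10⁻⁸ mL;
junction Newton relative tolerance 10⁻⁹, warm-started, cold-restarted from
the nominal displacements on the rare failure).  Beat-to-beat state drift
after the transient is checked against 0.1 % and closed-loop volume against
10⁻⁶ relative.

Metrics come from the final beat's PV-loop corners: EDV/ESV are the volume
extrema; among samples within 10⁻³ × SV of the extremum, end-diastole takes
the lowest and end-systole the highest pressure (the volume trace is
exactly flat through the isovolumic phases, so the pressure at a bare
argmax/argmin is ill-defined).  CPO = loop area × heart rate
(1 mmHg·mL = 1.33322·10⁻⁴ J); the clinical MAP × CO product is attached as
a secondary diagnostic.  Septal phases are read from the valve flows:
ejection while the aortic valve carries flow, isovolumic relaxation from
aortic closure to mitral opening, filling while the mitral valve carries
flow.

Dysfunction is acute: systolic scales k_act of the targeted walls to 0.6
(moderate) / 0.4 (severe), diastolic scales k_pas by 7 / 15; LV targeting
includes the septum, RV targeting is the free wall only; geometry is not
re-derived (no remodeling).  Volume loading sweeps circulating volume
100–350 % in 10 % steps; the compensation search finds the volume at which
the cycle-mean systemic arterial pressure is 95 ± 0.5 mmHg by a safeguarded
secant iteration on the monotone pressure-volume relation, walking out from
the nominal volume (lower bracket 0.7 × nominal — the healthy subject
compensates *below* its nominal 5 L — upper 3.5 ×; an unreachable target
returns the boundary flagged, never an exception).  ES points for ESPVR
loci use the maximal-elastance proxy; ED points the maximal volume.  Heart
rate enters only through the cycle period (default 60 bpm; 80/100 exposed
in the CLI study command).

## Design choices where the formulation was open

* The pericardial law is implemented as `exp(s(Vh/Vh0 − 1)) − 1` — zero at
  the reference heart volume `Vh0 = 1.25 × (EDV_LV + EDV_RV)`, small
  negative (> −1 mmHg) below it, steep above — with `Vh = V_LV + V_RV`
  (atria are folded into the venous compartments and do not occupy
  pericardial space).
* Γ factors are numerical (frozen-configuration pressure per unit stress),
  not closed-form; this makes the calibration idempotent by construction.
* The four-unknown displacement system is solved with a finite-difference
  Jacobian and damped Newton steps (`ym` kept positive, step length capped
  at 2 cm); tolerance tightening by 10× moves chamber pressures by < 0.1 %.
* γ is fit jointly to both ventricles with equal weights; the fit grid is
  part of the protocol, not a tuning knob.

## What the defaults emulate, and known limitations

The default configuration is a normative healthy 70 kg adult (120/80 mmHg
arterial pressure, LV EDV 125 mL, SV 75 mL, HR 60, TBV 5 L, LV/RV EDP 5 /
1.25 mmHg, LV/RV ESP 126 / 25 mmHg).  Simulated behavior is emergent from
that parameterization; nothing downstream is fit to outcomes.  Passing
tests therefore show internal consistency and the qualitative physiology of
ventricular interdependence — they do not validate the model against any
individual patient's data.

Known limitations, all visible in the acceptance outputs:

* **Venous return bounds the compensated output.**  With near-zero printed
  valve resistances the venous pressures equilibrate with the diastolic
  ventricular pressures (~0.5–1 mmHg), so at the compensated mean arterial
  pressure of 95 mmHg the steady-state flow is pinned near
  `(95 − P̄_SV)/R_sys ≈ 77 mL/s`.  The compensated stroke volume, LV power
  and filling pressures inherit this bound; reference descriptions of the
  same configuration that pair a 95 mmHg mean with ~68 mL stroke volume
  imply a systemic resistance ~15 % larger (or a finite venous resistance)
  than the stated derivation yields.  The derivation is kept as stated.
* **Normalized-EDPVR collapse is thickness-limited.**  Holding wall
  thickness at 8 mm across heart sizes (62.5–250 mL) breaks geometric
  self-similarity: normalized passive curves coincide to < 0.4 mmHg up to
  60 % of the normalized volume range but spread ~7 mmHg near V30 for the
  thick-walled LV (the 4 mm RV collapses much tighter).  Scaling thickness
  with size would restore the collapse; thickness is kept a fixed input.
* At severely loaded compensated states (e.g. severe LV systolic
  dysfunction compensating at ~7 L), the pericardial constraint flattens
  the RV loop enough that RV power no longer rises monotonically with
  severity.
* No baroreflex or autonomic control (volume loading is the only
  compensation), only forward valve flow (no regurgitation or stenosis),
  no atria as chambers, no pulse-wave propagation, spherical-cap geometry
  without regional heterogeneity, and acute dysfunction without
  remodeling.
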