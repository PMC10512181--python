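"""Myofiber stress model: passive stretch, active contraction, activation.

Passive stress follows a Klotz-form power law in sarcomere extension; active
stress is generated by a contractile element in series with an isometrically
stressed elastic element and is gated by a half-cosine activation waveform.
Per-wall scaling factors k_pas / k_act (calibrated in
:mod:`triseg.calibration`) convert these unit-scale stresses to kPa.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _core


@dataclass(frozen=True)
class SarcomereParams:
    """Sarcomere constants (lengths in um, velocity in um/s)."""

    nu_L: float = 1.0
    L_c0: float = 1.51
    L_se_iso: float = 0.04
    v_max: float = 3.5
    gamma: float = 7.5
    L_ref: float = 2.0

    def __post_init__(self) -> None:
        if not (self.L_c0 < self.L_ref):
            raise ValueError("slack length must be below reference length")
        for name in ("nu_L", "L_c0", "L_se_iso", "v_max", "gamma", "L_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ActivationParams:
    """Timing of the activation waveform for one cardiac cycle."""

    T: float              # cycle period, s (= 60 / HR)
    k_TS: float = 0.2     # rise fraction (time of maximal activation)
    k_TR: float = 0.2     # relaxation fraction

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("cycle period must be positive")
        if not self.k_TS + self.k_TR < 1:
            raise ValueError("k_TS + k_TR must be < 1")

    @property
    def T_S(self) -> float:
        return self.k_TS * self.T

    @property
    def T_R(self) -> float:
        return self.k_TR * self.T


@dataclass(frozen=True)
class WallProperties:
    """Per-wall stress scaling factors (kPa)."""

    k_pas: float
    k_act: float

    def __post_init__(self) -> None:
        if self.k_pas < 0 or self.k_act < 0:
            raise ValueError("scaling factors must be nonnegative")


def activation(t: float, params: ActivationParams) -> float:
    """Activation fraction in [0, 1]; rising half-cosine to t = T_S, falling
    half-cosine to T_S + T_R, zero for the rest of the beat.  ``t`` is
    reduced modulo the cycle period."""
    return _core.activation(t % params.T, params.T_S, params.T_R)


def passive_stress(L: float, params: SarcomereParams) -> float:
    """Passive myofiber stress (nu_L (L - L_c0))^gamma, clamped at slack.

    Below the slack length a tiny linear compressive term (regularization,
    well under measurement scale) replaces the power law.
    """
    return _core.passive_stress(L, params.L_c0, params.gamma, params.nu_L)


def active_stress(L: float, Lc: float, Y: float,
                  params: SarcomereParams) -> float:
    """Active stress nu_L (Lc - L_c0) ((L - Lc)/L_se_iso) Y."""
    if not 0.0 <= Y <= 1.0:
        raise ValueError("activation fraction must lie in [0, 1]")
    return _core.active_stress(L, Lc, Y, params.L_c0, params.L_se_iso,
                               params.nu_L)


def contractile_length_rate(L: float, Lc: float,
                            params: SarcomereParams) -> float:
    """dLc/dt = ((L - Lc)/L_se_iso - 1) v_max (um/s)."""
    return _core.contractile_rate(L, Lc, params.L_se_iso, params.v_max)


def total_wall_stress(L: float, Lc: float, Y: float, props: WallProperties,
                      params: SarcomereParams) -> float:
    """Total fiber stress k_pas sigma_pas + k_act sigma_act (kPa)."""
    return (props.k_pas * passive_stress(L, params)
            + props.k_act * active_stress(L, Lc, Y, params))
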