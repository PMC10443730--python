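"""Vascular and cardiac curve physics.

Canonical units throughout the package: pressures in mmHg; flows
weight-indexed in mL·kg⁻¹·min⁻¹; resistances in mmHg·kg·min·mL⁻¹ (the
reciprocal of a weight-indexed conductance). Absolute L/min is only ever
produced by an explicit body-mass conversion at the I/O layer, so the
literature's per-kg conductance estimates (G_cardiac = 35, G_VR = 10
mL/kg/min per mmHg) are usable verbatim.

The two half-models are deliberately piecewise linear:

* the venous-return curve is linear in right atrial pressure (P_RA) down to
  the great-vein collapse pressure P_CRIT, below which flow plateaus
  (vascular waterfall / Starling resistor);
* the cardiac-function (Starling-Sarnoff) curve rises linearly in P_RA from
  its x-intercept — the pericardial pressure P_PC — up to a plateau onset
  P_RAplat, above which the heart is preload-unresponsive.

Pericardial pressure is decomposed into pleural pressure, the
ventilator-transmitted component P_AW·(E_CW/E_RS), and pericardial elastic
recoil, which couples lung mechanics into the cardiac half of the model.
"""

from __future__ import annotations

from typing import Sequence

from pydantic import BaseModel, ConfigDict

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "VesselVolumeState",
    "VascularSegment",
    "VenousReturnCurve",
    "CardiacFunctionCurve",
    "PericardialComponents",
    "RecoilModel",
    "stressed_volume",
    "recoil_pressure",
    "pressure_gradient_for_vr",
    "venous_return_flow",
    "cardiac_output_flow",
    "segment_time_constant",
    "compose_rvr",
    "vessel_geometry_scaling",
    "pericardial_pressure",
    "pericardial_recoil",
]


class _FrozenModel(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class VesselVolumeState(_FrozenModel):
    """Blood volume held in a compliant vessel or vascular compartment.

    Attributes
    ----------
    v_total : float
        Total contained volume, mL.
    v_us : float
        Unstressed volume (capacitance), mL — the fill that generates no
        elastic recoil.
    compliance : float
        Volume change per unit recoil pressure, mL/mmHg.
    """

    v_total: float
    v_us: float
    compliance: float

    def model_post_init(self, context, /) -> None:
        if self.v_total < 0 or self.v_us < 0:
            raise InvalidParameterError("volumes must be non-negative")
        if self.compliance <= 0:
            raise InvalidParameterError("compliance must be positive")


class VascularSegment(_FrozenModel):
    """One resistive/compliant segment of the systemic circulation.

    ``flow_fraction`` is the share of total circulatory flow routed through
    this segment (1.0 for a purely serial arrangement).
    """

    resistance: float
    compliance: float
    flow_fraction: float = 1.0

    def model_post_init(self, context, /) -> None:
        if self.resistance < 0:
            raise InvalidParameterError("resistance must be non-negative")
        if self.compliance <= 0:
            raise InvalidParameterError("compliance must be positive")
        if not 0.0 <= self.flow_fraction <= 1.0:
            raise InvalidParameterError("flow_fraction must lie in [0, 1]")


class VenousReturnCurve(_FrozenModel):
    """Peripheral side of the equilibrium.

    Attributes
    ----------
    p_msf : float
        Mean systemic filling pressure, mmHg; x-intercept of the curve.
    r_vr : float
        Resistance to venous return, mmHg·kg·min/mL (inverse slope).
    p_crit : float
        Great-vein collapse pressure, mmHg; below it the curve plateaus.
    """

    p_msf: float
    r_vr: float
    p_crit: float

    def model_post_init(self, context, /) -> None:
        if self.r_vr <= 0:
            raise InvalidParameterError("r_vr must be positive")
        if self.p_crit >= self.p_msf:
            raise InvalidParameterError(
                f"p_crit ({self.p_crit}) must be below p_msf ({self.p_msf})"
            )

    @property
    def plateau_flow(self) -> float:
        """Maximal venous return, reached for P_RA <= P_CRIT."""
        return (self.p_msf - self.p_crit) / self.r_vr


class CardiacFunctionCurve(_FrozenModel):
    """Cardiac (Starling-Sarnoff) side of the equilibrium.

    Attributes
    ----------
    p_pc : float
        Pericardial (ambient cardiac) pressure, mmHg; x-intercept.
    r_cardiac : float
        Inverse slope of the cardiac function curve, mmHg·kg·min/mL.
    p_ra_plat : float
        Right atrial pressure at plateau onset, mmHg.
    """

    p_pc: float
    r_cardiac: float
    p_ra_plat: float

    def model_post_init(self, context, /) -> None:
        if self.r_cardiac <= 0:
            raise InvalidParameterError("r_cardiac must be positive")
        if self.p_ra_plat <= self.p_pc:
            raise InvalidParameterError(
                f"p_ra_plat ({self.p_ra_plat}) must exceed p_pc ({self.p_pc})"
            )

    @property
    def plateau_flow(self) -> float:
        """Maximal cardiac output, reached for P_RA >= P_RAplat."""
        return (self.p_ra_plat - self.p_pc) / self.r_cardiac


class PericardialComponents(_FrozenModel):
    """Additive decomposition of pericardial pressure.

    P_PC = P_PL + P_AW · (E_CW / E_RS) + P_PC_EL, i.e. pleural pressure plus
    the share of mean airway pressure transmitted through the lung to the
    pleural space by the relative stiffness of the chest wall, plus the
    elastic recoil of the pericardial sac itself. Elastance units cancel in
    the ratio; when a configuration supplies only the ratio, ``e_rs`` is 1.
    """

    p_pl: float = 0.0
    p_aw: float = 0.0
    e_cw: float = 0.0
    e_rs: float = 1.0
    p_pc_el: float = 0.0

    def model_post_init(self, context, /) -> None:
        if self.e_rs <= 0:
            raise InvalidParameterError("e_rs must be positive")
        if self.e_cw < 0:
            raise InvalidParameterError("e_cw must be non-negative")
        if self.e_cw > self.e_rs:
            raise InvalidParameterError(
                "e_cw must not exceed e_rs (ratio confined to [0, 1])"
            )
        if self.p_pc_el < 0:
            raise InvalidParameterError("p_pc_el must be non-negative")

    @property
    def elastance_ratio(self) -> float:
        return self.e_cw / self.e_rs


class RecoilModel(_FrozenModel):
    """Piecewise-linear pericardial volume-pressure relationship.

    Below ``engage_threshold`` (transmural P_RA, mmHg) the sac is slack and
    generates no recoil; between the thresholds it recoils at ``slope_low``
    mmHg per mmHg of transmural pressure; above ``steep_threshold`` the sac
    is fully engaged and recoils at ``slope_high``. The curve is continuous
    and nondecreasing. Default thresholds follow the clinical observations
    that restraint is negligible below ~5 mmHg transmural pressure and
    pronounced above 10-12 mmHg; the slopes are configurable model choices.
    """

    engage_threshold: float = 5.0
    steep_threshold: float = 11.0
    slope_low: float = 0.5
    slope_high: float = 1.5

    def model_post_init(self, context, /) -> None:
        if not 0.0 <= self.engage_threshold < self.steep_threshold:
            raise InvalidParameterError(
                "need 0 <= engage_threshold < steep_threshold"
            )
        if self.slope_low < 0 or self.slope_high < 0:
            raise InvalidParameterError("recoil slopes must be non-negative")


def stressed_volume(vessel: VesselVolumeState) -> float:
    """Volume generating elastic recoil, mL: max(0, v_total - v_us)."""
    return max(0.0, vessel.v_total - vessel.v_us)


def recoil_pressure(vessel: VesselVolumeState) -> float:
    """Elastic recoil pressure, mmHg: stressed volume over compliance.

    For a one-compartment systemic circulation this is the mean systemic
    filling pressure.
    """
    return stressed_volume(vessel) / vessel.compliance


def pressure_gradient_for_vr(p_msf: float, p_ra: float) -> float:
    """Driving gradient for venous return, mmHg: P_MSF - P_RA.

    May be negative; callers interpret the sign.
    """
    return p_msf - p_ra


def venous_return_flow(p_ra: float, curve: VenousReturnCurve) -> float:
    """Venous return at a given right atrial pressure, mL/kg/min.

    Linear limb ``(p_msf - p_ra) / r_vr`` for P_RA >= P_CRIT; constant
    maximum below P_CRIT (waterfall: downstream pressure no longer matters).
    Values for P_RA > P_MSF are returned negative, unclamped — physical
    validity is the solver's concern, not the curve's.
    """
    return (curve.p_msf - max(p_ra, curve.p_crit)) / curve.r_vr


def cardiac_output_flow(p_ra: float, curve: CardiacFunctionCurve) -> float:
    """Cardiac output at a given right atrial pressure, mL/kg/min.

    Zero below the x-intercept P_PC (a heart cannot pump negative flow),
    linear with slope 1/r_cardiac up to P_RAplat, then constant at the
    plateau value.
    """
    clamped = min(max(p_ra, curve.p_pc), curve.p_ra_plat)
    return (clamped - curve.p_pc) / curve.r_cardiac


def segment_time_constant(segment: VascularSegment) -> float:
    """Time constant of a vascular segment: resistance x compliance."""
    return segment.resistance * segment.compliance


def compose_rvr(segments: Sequence[VascularSegment]) -> float:
    """Resistance to venous return of a segment network.

    Each segment contributes its time constant (R·C) weighted by the
    fraction of total circulatory flow it carries; the sum is normalised by
    the total compliance. Serial composition is the special case of all
    flow fractions equal to 1: R_VR = sum(R_i C_i) / C_TOT. Routing flow
    toward a long-time-constant (high-compliance, splanchnic-like) segment
    raises R_VR; routing toward a short-time-constant bed lowers it.
    """
    if len(segments) == 0:
        raise InvalidInputError("compose_rvr requires at least one segment")
    c_tot = sum(s.compliance for s in segments)
    return sum(
        s.flow_fraction * s.resistance * s.compliance for s in segments
    ) / c_tot


def vessel_geometry_scaling(diameter_ratio: float) -> tuple[float, float]:
    """Volume and resistance ratios after a change in vessel diameter.

    Contained volume scales with the second power of diameter, Poiseuille
    resistance with the inverse fourth power. A 20% diameter reduction
    (ratio 0.8) therefore cuts volume to 64% of baseline while resistance
    rises to ~244% — the mechanism by which alpha-agonism recruits stressed
    volume (raising P_MSF) at the cost of a higher R_VR.

    Returns
    -------
    (volume_ratio, resistance_ratio)
    """
    if diameter_ratio <= 0:
        raise InvalidParameterError("diameter_ratio must be positive")
    return diameter_ratio**2, diameter_ratio**-4


def pericardial_pressure(components: PericardialComponents) -> float:
    """Total pericardial pressure, mmHg: P_PL + P_AW·(E_CW/E_RS) + P_PC_EL."""
    return (
        components.p_pl
        + components.p_aw * components.elastance_ratio
        + components.p_pc_el
    )


def pericardial_recoil(transmural_pressure: float, model: RecoilModel) -> float:
    """Pericardial elastic recoil pressure at a given transmural P_RA, mmHg.

    Continuous piecewise-linear and nondecreasing: zero while the sac is
    slack, shallow slope once engaged, steep slope once fully engaged.
    """
    t = transmural_pressure
    if t <= model.engage_threshold:
        return 0.0
    if t <= model.steep_threshold:
        return model.slope_low * (t - model.engage_threshold)
    return model.slope_low * (
        model.steep_threshold - model.engage_threshold
    ) + model.slope_high * (t - model.steep_threshold)
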