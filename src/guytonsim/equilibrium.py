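"""Operating-point solver, regime classification and sensitivities.

The circulation's dependent variable is the *operating point*: the
intersection of the venous-return and cardiac-function curves in the
(P_RA, flow) plane. Both of its coordinates — right atrial pressure and
total circulatory flow Q — fall out of the equilibrium; the independent
variables are P_MSF, P_PC, R_VR, R_cardiac and the two plateau breakpoints.

Because both curves are piecewise linear, the intersection has a closed
form. Four regimes exist:

``unlimited``
    both curves on their sloped limbs; Q = (P_MSF - P_PC)/(R_cardiac + R_VR).
``cardiac_limited``
    operating point on the cardiac plateau (preload-unresponsive);
    Q = (P_RAplat - P_PC)/R_cardiac, peripheral variables move only P_RA.
``venous_limited``
    operating point on the venous plateau (waterfall);
    Q = (P_MSF - P_CRIT)/R_VR, cardiac variables move only P_RA.
``doubly_limited``
    both plateaus at the same flow; P_RA is indeterminate over the
    overlapping flat interval and is reported at its midpoint.

A grid + bisection oracle (`oracle_intersection`) provides an independent
numerical route used by the test suite to validate the closed form.
"""

from __future__ import annotations

from typing import Literal

import pandas as pd
from scipy.optimize import brentq

from .curves import (
    CardiacFunctionCurve,
    RecoilModel,
    VenousReturnCurve,
    _FrozenModel,
    cardiac_output_flow,
    pericardial_pressure,
    pericardial_recoil,
    venous_return_flow,
)
from .errors import (
    ConvergenceError,
    InvalidParameterError,
    NoEquilibriumError,
    NondifferentiablePointError,
)

__all__ = [
    "Regime",
    "OperatingPoint",
    "SolverSettings",
    "solve_operating_point",
    "oracle_intersection",
    "sensitivities",
    "self_consistent_solve",
    "transmural_pra",
]

Regime = Literal["unlimited", "cardiac_limited", "venous_limited", "doubly_limited"]


class SolverSettings(_FrozenModel):
    """Numerical tolerances for the solver (artifact plumbing, not physics)."""

    flow_tolerance: float = 1e-9
    pressure_tolerance: float = 1e-9
    doubly_limited_tolerance: float = 1e-6

    def model_post_init(self, context, /) -> None:
        if min(
            self.flow_tolerance,
            self.pressure_tolerance,
            self.doubly_limited_tolerance,
        ) <= 0:
            raise InvalidParameterError("tolerances must be positive")


class OperatingPoint(_FrozenModel):
    """Equilibrium of the circulation.

    Attributes
    ----------
    p_ra : float
        Right atrial (intravascular) pressure, mmHg.
    q_circulatory : float
        Total circulatory flow (= venous return = cardiac output), mL/kg/min.
    regime : str
        Which limb(s) of the curves the point sits on.
    p_ra_transmural : float
        P_RA - P_PC, mmHg — the pressure that actually stretches the
        myocardium (Starling input).
    """

    p_ra: float
    q_circulatory: float
    regime: Regime
    p_ra_transmural: float


def transmural_pra(p_ra: float, p_pc: float) -> float:
    """Transmural right atrial pressure, mmHg: intravascular minus ambient."""
    return p_ra - p_pc


def solve_operating_point(
    vr: VenousReturnCurve,
    cf: CardiacFunctionCurve,
    settings: SolverSettings | None = None,
) -> OperatingPoint:
    """Closed-form intersection of the two piecewise-linear curves.

    Tries the unconstrained (both-sloped-limbs) candidate first and accepts
    it when its P_RA lies between the venous and cardiac breakpoints;
    otherwise the operating point sits on exactly one plateau (whichever is
    lower), or on both when the plateau flows coincide within tolerance.

    Raises
    ------
    NoEquilibriumError
        If P_PC >= P_MSF: the model admits no positive-flow equilibrium.
    """
    settings = settings or SolverSettings()
    if cf.p_pc >= vr.p_msf:
        raise NoEquilibriumError(
            f"p_pc ({cf.p_pc}) >= p_msf ({vr.p_msf}): equilibrium flow "
            "would be non-positive"
        )

    # Unconstrained candidate: both curves on their sloped limbs.
    q = (vr.p_msf - cf.p_pc) / (cf.r_cardiac + vr.r_vr)
    p_ra = cf.p_pc + q * cf.r_cardiac
    if vr.p_crit <= p_ra <= cf.p_ra_plat:
        return OperatingPoint(
            p_ra=p_ra,
            q_circulatory=q,
            regime="unlimited",
            p_ra_transmural=transmural_pra(p_ra, cf.p_pc),
        )

    q_plat = cf.plateau_flow
    q_max = vr.plateau_flow
    tol = settings.doubly_limited_tolerance
    if q_plat < q_max - tol:
        # Cardiac plateau is the binding limit.
        q = q_plat
        p_ra = vr.p_msf - q * vr.r_vr
        regime: Regime = "cardiac_limited"
    elif q_max < q_plat - tol:
        # Venous plateau is the binding limit.
        q = q_max
        p_ra = cf.p_pc + q * cf.r_cardiac
        regime = "venous_limited"
    else:
        # Both plateaus at (tolerance-level) the same flow: P_RA is not
        # uniquely determined; report the midpoint of the flat overlap.
        q = q_plat
        p_ra = 0.5 * (cf.p_ra_plat + vr.p_crit)
        regime = "doubly_limited"
    if q <= 0:
        raise NoEquilibriumError("equilibrium flow is non-positive")
    return OperatingPoint(
        p_ra=p_ra,
        q_circulatory=q,
        regime=regime,
        p_ra_transmural=transmural_pra(p_ra, cf.p_pc),
    )


def oracle_intersection(
    vr: VenousReturnCurve,
    cf: CardiacFunctionCurve,
    settings: SolverSettings | None = None,
    xtol: float = 1e-10,
) -> OperatingPoint:
    """Intersection by root bracketing, independent of the closed form.

    Bisects ``cardiac_output - venous_return`` (nondecreasing in P_RA) over
    [min(p_crit, p_pc) - 5, p_msf + 5]; the sign change is guaranteed by
    the curve shapes whenever p_pc < p_msf. Exists as a numerical oracle
    for validating `solve_operating_point`, never as the production path.
    """
    settings = settings or SolverSettings()
    if cf.p_pc >= vr.p_msf:
        raise NoEquilibriumError(
            f"p_pc ({cf.p_pc}) >= p_msf ({vr.p_msf})"
        )

    def mismatch(p: float) -> float:
        return cardiac_output_flow(p, cf) - venous_return_flow(p, vr)

    lo = min(vr.p_crit, cf.p_pc) - 5.0
    hi = vr.p_msf + 5.0
    p_ra = float(brentq(mismatch, lo, hi, xtol=xtol))
    q = venous_return_flow(p_ra, vr)

    eps = 10 * xtol
    on_cardiac_plateau = p_ra >= cf.p_ra_plat - eps
    on_venous_plateau = p_ra <= vr.p_crit + eps
    if abs(cf.plateau_flow - vr.plateau_flow) < settings.doubly_limited_tolerance and (
        on_cardiac_plateau or on_venous_plateau
    ):
        regime: Regime = "doubly_limited"
        p_ra = 0.5 * (cf.p_ra_plat + vr.p_crit)
        q = cf.plateau_flow
    elif on_cardiac_plateau:
        regime = "cardiac_limited"
    elif on_venous_plateau:
        regime = "venous_limited"
    else:
        regime = "unlimited"
    if q <= 0:
        raise NoEquilibriumError("equilibrium flow is non-positive")
    return OperatingPoint(
        p_ra=p_ra,
        q_circulatory=q,
        regime=regime,
        p_ra_transmural=transmural_pra(p_ra, cf.p_pc),
    )


def sensitivities(
    vr: VenousReturnCurve,
    cf: CardiacFunctionCurve,
    breakpoint_tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Analytic partials of Q and P_RA w.r.t. the independent variables.

    Returns a DataFrame indexed by ('q_circulatory', 'p_ra') with columns
    ('p_msf', 'p_pc', 'r_vr', 'r_cardiac'), regime-specific:

    * unlimited — both outputs respond to all four variables;
    * cardiac-limited — P_MSF and R_VR move only P_RA (dQ = 0);
    * venous-limited — R_cardiac and P_PC move only P_RA (dQ = 0).

    Raises
    ------
    NondifferentiablePointError
        If the operating point lies within ``breakpoint_tolerance`` of a
        curve breakpoint, where the partials jump.
    """
    op = solve_operating_point(vr, cf)
    if (
        abs(op.p_ra - cf.p_ra_plat) < breakpoint_tolerance
        or abs(op.p_ra - vr.p_crit) < breakpoint_tolerance
    ):
        raise NondifferentiablePointError(
            f"operating point p_ra={op.p_ra} is at a curve breakpoint"
        )
    q = op.q_circulatory
    r_c, r_v = cf.r_cardiac, vr.r_vr
    if op.regime == "unlimited":
        s = r_c + r_v
        dq = {
            "p_msf": 1.0 / s,
            "p_pc": -1.0 / s,
            "r_vr": -q / s,
            "r_cardiac": -q / s,
        }
        dp = {
            "p_msf": r_c / s,
            "p_pc": r_v / s,
            "r_vr": -q * r_c / s,
            "r_cardiac": q * r_v / s,
        }
    elif op.regime == "cardiac_limited":
        dq = {"p_msf": 0.0, "p_pc": -1.0 / r_c, "r_vr": 0.0, "r_cardiac": -q / r_c}
        dp = {
            "p_msf": 1.0,
            "p_pc": r_v / r_c,
            "r_vr": -q,
            "r_cardiac": q * r_v / r_c,
        }
    elif op.regime == "venous_limited":
        dq = {"p_msf": 1.0 / r_v, "p_pc": 0.0, "r_vr": -q / r_v, "r_cardiac": 0.0}
        dp = {
            "p_msf": r_c / r_v,
            "p_pc": 1.0,
            "r_vr": -q * r_c / r_v,
            "r_cardiac": q,
        }
    else:
        raise NondifferentiablePointError(
            "doubly-limited operating point has no well-defined partials"
        )
    return pd.DataFrame([dq, dp], index=["q_circulatory", "p_ra"])


def self_consistent_solve(state, settings: SolverSettings | None = None,
                          max_iterations: int = 100, damping: float = 0.5) -> OperatingPoint:
    """Solve with pericardial recoil fed back from the solution itself.

    Pericardial elastic recoil depends on transmural P_RA, which depends on
    P_PC, which contains the recoil — a fixed point. Iterates: solve at the
    current P_PC_EL, evaluate the recoil model at the resulting transmural
    P_RA, move P_PC_EL halfway toward that value (damping), repeat until
    successive P_PC changes fall below the pressure tolerance.

    With a zero-slope recoil model (and zero stated P_PC_EL) the first
    iterate is already the fixed point and the result equals the plain
    solver exactly.

    Parameters
    ----------
    state : PatientState
        Bundle of venous curve, cardiac parameters with pericardial
        decomposition, and recoil model.
    """
    settings = settings or SolverSettings()
    pericardium = state.cardiac.pericardium
    recoil_model: RecoilModel = state.recoil_model
    base = pericardial_pressure(
        pericardium.model_copy(update={"p_pc_el": 0.0})
    )
    p_pc_el = pericardium.p_pc_el
    op = None
    for _ in range(max_iterations):
        p_pc = base + p_pc_el
        cf = CardiacFunctionCurve(
            p_pc=p_pc,
            r_cardiac=state.cardiac.r_cardiac,
            p_ra_plat=state.cardiac.p_ra_plat,
        )
        op = solve_operating_point(state.vr_curve, cf, settings)
        target = pericardial_recoil(op.p_ra_transmural, recoil_model)
        step = damping * (target - p_pc_el)
        p_pc_el += step
        if abs(step) < settings.pressure_tolerance:
            return op
    raise ConvergenceError(
        f"pericardial fixed point not reached in {max_iterations} iterations",
        last_iterate=op,
    )
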