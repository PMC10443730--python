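"""Intervention algebra over patient states.

A `PatientState` bundles everything the model treats as independent: the
venous-return curve, the cardiac-function parameters (with pericardial
pressure given by its decomposition), the pericardial recoil model and body
mass. Interventions — fluids, vasoactives, ventilator changes, positional
changes — act only on these independent variables, never on P_RA or Q,
which are read off the solved operating point. This enforces the model's
central claim: right atrial pressure and circulatory flow are outputs of
the system, not knobs.

The module also provides the prone-position transition with two packaged
fixture scenarios (a preload-responsive baseline and a cardiac-limited
baseline), a passive-leg-raise-style preload-responsiveness probe,
parameter sweeps, and a seeded synthetic cohort generator.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .curves import (
    CardiacFunctionCurve,
    PericardialComponents,
    RecoilModel,
    VenousReturnCurve,
    _FrozenModel,
    pericardial_pressure,
)
from .equilibrium import OperatingPoint, SolverSettings, solve_operating_point
from .errors import GenerationError, InvalidInputError, InvalidParameterError, NoEquilibriumError

logger = logging.getLogger(__name__)

__all__ = [
    "CardiacSpec",
    "PatientState",
    "Intervention",
    "TransitionResult",
    "apply_intervention",
    "prone_transition",
    "preload_responsiveness",
    "parameter_sweep",
    "generate_cohort",
    "load_prone_fixture",
    "DEFAULT_COHORT_RANGES",
]


class CardiacSpec(_FrozenModel):
    """Cardiac-function parameters with P_PC given by its decomposition."""

    pericardium: PericardialComponents
    r_cardiac: float
    p_ra_plat: float

    def curve(self) -> CardiacFunctionCurve:
        """Collapse the pericardial decomposition into a concrete curve."""
        return CardiacFunctionCurve(
            p_pc=pericardial_pressure(self.pericardium),
            r_cardiac=self.r_cardiac,
            p_ra_plat=self.p_ra_plat,
        )


class PatientState(_FrozenModel):
    """Full independent-variable set of one simulated patient."""

    vr_curve: VenousReturnCurve
    cardiac: CardiacSpec
    recoil_model: RecoilModel = RecoilModel()
    body_mass: float = 70.0
    label: str = ""

    def model_post_init(self, context, /) -> None:
        if self.body_mass <= 0:
            raise InvalidParameterError("body_mass must be positive")

    def solve(self, settings: SolverSettings | None = None) -> OperatingPoint:
        """Operating point with the pericardial components as stated."""
        # Interventions may push P_PC past P_MSF; that is a no-equilibrium
        # condition of the solved system, not a malformed parameter set.
        p_pc = pericardial_pressure(self.cardiac.pericardium)
        if p_pc >= self.vr_curve.p_msf:
            raise NoEquilibriumError(
                f"p_pc ({p_pc}) >= p_msf ({self.vr_curve.p_msf}): equilibrium "
                "flow would be non-positive"
            )
        # model_copy-based updates skip validation, so re-validate the venous
        # curve here: a structurally invalid post-intervention state must
        # fail at solve time with a typed error.
        vr = VenousReturnCurve.model_validate(self.vr_curve.model_dump())
        return solve_operating_point(vr, self.cardiac.curve(), settings)


class Intervention(_FrozenModel):
    """A change to the independent variables only.

    Deltas are additive (mmHg or elastance-ratio units); factors are
    multiplicative. ``venous_diameter_ratio``, if given, applies the
    fourth-power diameter law to R_VR on top of ``r_vr_factor`` — the
    vasoconstriction coupling by which stressed-volume recruitment also
    raises the resistance to venous return.
    """

    name: str = "intervention"
    delta_p_msf: float = 0.0
    r_vr_factor: float = 1.0
    r_cardiac_factor: float = 1.0
    delta_p_aw: float = 0.0
    delta_e_cw_ratio: float = 0.0
    delta_p_pl: float = 0.0
    venous_diameter_ratio: float | None = None
    note: str = ""

    def model_post_init(self, context, /) -> None:
        if self.r_vr_factor <= 0 or self.r_cardiac_factor <= 0:
            raise InvalidParameterError("resistance multipliers must be positive")
        if self.venous_diameter_ratio is not None and self.venous_diameter_ratio <= 0:
            raise InvalidParameterError("venous_diameter_ratio must be positive")


class TransitionResult(_FrozenModel):
    """Before/after pair of operating points for one intervention."""

    before: OperatingPoint
    after: OperatingPoint
    delta_q: float
    delta_p_ra: float
    regime_change: tuple[str, str]

    def model_post_init(self, context, /) -> None:
        if self.delta_q != self.after.q_circulatory - self.before.q_circulatory:
            raise InvalidParameterError("delta_q must equal after - before")
        if self.delta_p_ra != self.after.p_ra - self.before.p_ra:
            raise InvalidParameterError("delta_p_ra must equal after - before")


def apply_intervention(state: PatientState, intervention: Intervention) -> PatientState:
    """Return a new state with the intervention applied; input unmodified."""
    r_vr_factor = intervention.r_vr_factor
    if intervention.venous_diameter_ratio is not None:
        r_vr_factor *= intervention.venous_diameter_ratio**-4
        logger.info(
            "intervention %r: venous diameter ratio %.3f multiplies R_VR by "
            "%.3f; the matching capacitance change should be reflected in "
            "delta_p_msf (volume scales with diameter^2)",
            intervention.name,
            intervention.venous_diameter_ratio,
            intervention.venous_diameter_ratio**-4,
        )
    vr = state.vr_curve.model_copy(
        update={
            "p_msf": state.vr_curve.p_msf + intervention.delta_p_msf,
            "r_vr": state.vr_curve.r_vr * r_vr_factor,
        }
    )
    peri = state.cardiac.pericardium
    new_ratio = peri.elastance_ratio + intervention.delta_e_cw_ratio
    peri = peri.model_copy(
        update={
            "p_aw": peri.p_aw + intervention.delta_p_aw,
            "p_pl": peri.p_pl + intervention.delta_p_pl,
            "e_cw": new_ratio * peri.e_rs,
        }
    )
    cardiac = state.cardiac.model_copy(
        update={
            "pericardium": peri,
            "r_cardiac": state.cardiac.r_cardiac * intervention.r_cardiac_factor,
        }
    )
    return state.model_copy(update={"vr_curve": vr, "cardiac": cardiac})


def prone_transition(
    state: PatientState,
    prone: Intervention,
    settings: SolverSettings | None = None,
) -> TransitionResult:
    """Apply a prone-position intervention and report both operating points.

    Prone positioning raises P_MSF (volume redistribution, adrenergic
    tone), raises R_VR, stiffens the chest wall (higher E_CW/E_RS, so a
    larger share of airway pressure reaches the pericardium) and — via
    pulmonary vascular recruitment — may lower R_cardiac. Whether Q rises
    depends on where the baseline operating point sits: cardiac-limited
    baselines see only a P_RA shift unless R_cardiac itself improves.
    """
    before = state.solve(settings)
    after = apply_intervention(state, prone).solve(settings)
    return TransitionResult(
        before=before,
        after=after,
        delta_q=after.q_circulatory - before.q_circulatory,
        delta_p_ra=after.p_ra - before.p_ra,
        regime_change=(before.regime, after.regime),
    )


def preload_responsiveness(
    state: PatientState,
    probe_delta_p_msf: float = 2.0,
    threshold_fraction: float = 0.10,
    settings: SolverSettings | None = None,
) -> tuple[bool, float]:
    """Probe the state with a transient P_MSF rise (a passive leg raise).

    Returns ``(responsive, relative_delta_q)`` where responsiveness means
    the relative flow increase meets ``threshold_fraction``. The probe is
    non-destructive: the caller's state is never modified. A
    cardiac-limited state is preload-unresponsive by construction — its
    flow is set entirely by the cardiac side.
    """
    if probe_delta_p_msf <= 0:
        raise InvalidParameterError("probe_delta_p_msf must be positive")
    before = state.solve(settings)
    probed = apply_intervention(
        state, Intervention(name="preload_probe", delta_p_msf=probe_delta_p_msf)
    )
    after = probed.solve(settings)
    relative = (after.q_circulatory - before.q_circulatory) / before.q_circulatory
    return relative >= threshold_fraction, relative


_SWEEPABLE = (
    "p_msf",
    "p_pc_el",
    "p_aw",
    "p_pl",
    "e_cw_ratio",
    "r_vr",
    "r_cardiac",
    "p_crit",
    "p_ra_plat",
)


def _with_parameter(state: PatientState, parameter: str, value: float) -> PatientState:
    vr, cardiac, peri = state.vr_curve, state.cardiac, state.cardiac.pericardium
    if parameter in ("p_msf", "r_vr", "p_crit"):
        vr = vr.model_copy(update={parameter: value})
    elif parameter in ("r_cardiac", "p_ra_plat"):
        cardiac = cardiac.model_copy(update={parameter: value})
    elif parameter == "e_cw_ratio":
        cardiac = cardiac.model_copy(
            update={"pericardium": peri.model_copy(update={"e_cw": value * peri.e_rs})}
        )
    else:  # p_pc_el, p_aw, p_pl
        cardiac = cardiac.model_copy(
            update={"pericardium": peri.model_copy(update={parameter: value})}
        )
    return state.model_copy(update={"vr_curve": vr, "cardiac": cardiac})


def parameter_sweep(
    state: PatientState,
    parameter: str,
    values: Sequence[float],
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Solve the state at each value of one independent variable.

    Returns a DataFrame with columns (value, p_ra, q_circulatory, regime);
    values where the model or solver rejects the state carry the regime
    marker ``no_equilibrium`` with NaN coordinates rather than being
    dropped.
    """
    if parameter not in _SWEEPABLE:
        raise InvalidInputError(
            f"unknown sweep parameter {parameter!r}; choose one of {_SWEEPABLE}"
        )
    rows = []
    for v in values:
        try:
            op = _with_parameter(state, parameter, v).solve(settings)
            rows.append(
                {"value": v, "p_ra": op.p_ra, "q_circulatory": op.q_circulatory,
                 "regime": op.regime}
            )
        except (NoEquilibriumError, InvalidParameterError):
            rows.append(
                {"value": v, "p_ra": np.nan, "q_circulatory": np.nan,
                 "regime": "no_equilibrium"}
            )
    df = pd.DataFrame(rows, columns=["value", "p_ra", "q_circulatory", "regime"])
    df.attrs["parameter"] = parameter
    return df


#: Uniform sampling bounds for the synthetic cohort. Chosen to span the
#: clinically plausible adult ICU range around the canonical estimates
#: (P_MSF ~ 8 mmHg, G_cardiac ~ 35, G_VR ~ 10 per-kg units) with no claim
#: of population realism — the cohort is synthetic by design.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "p_msf": (4.0, 16.0),
    "p_crit": (-4.0, 2.0),
    "r_vr": (0.05, 0.2),
    "r_cardiac": (1.0 / 70.0, 1.0 / 15.0),
    "p_pl": (-5.0, 2.0),
    "p_aw": (0.0, 15.0),
    "e_cw_ratio": (0.1, 0.6),
    "p_ra_plat": (2.0, 12.0),
    "body_mass": (50.0, 100.0),
}


def generate_cohort(
    n: int,
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    max_rejections: int = 1000,
) -> list[PatientState]:
    """Draw ``n`` solvable synthetic patients from uniform bounds.

    Deterministic for a given seed. Each draw is rejection-sampled until
    the state is structurally valid (p_crit < p_msf, p_ra_plat > p_pc,
    p_pc < p_msf) and has an equilibrium; exceeding ``max_rejections``
    attempts for any single patient raises `GenerationError`.
    """
    if n <= 0:
        raise InvalidInputError("n must be positive")
    bounds = dict(DEFAULT_COHORT_RANGES)
    if ranges:
        unknown = set(ranges) - set(bounds)
        if unknown:
            raise InvalidInputError(f"unknown range keys: {sorted(unknown)}")
        bounds.update(ranges)
    rng = np.random.default_rng(seed)
    cohort: list[PatientState] = []
    for i in range(n):
        for attempt in range(max_rejections):
            draw = {k: rng.uniform(*bounds[k]) for k in bounds}
            try:
                state = PatientState(
                    vr_curve=VenousReturnCurve(
                        p_msf=draw["p_msf"], r_vr=draw["r_vr"], p_crit=draw["p_crit"]
                    ),
                    cardiac=CardiacSpec(
                        pericardium=PericardialComponents(
                            p_pl=draw["p_pl"], p_aw=draw["p_aw"],
                            e_cw=draw["e_cw_ratio"], e_rs=1.0,
                        ),
                        r_cardiac=draw["r_cardiac"],
                        p_ra_plat=draw["p_ra_plat"],
                    ),
                    body_mass=draw["body_mass"],
                    label=f"synthetic-{i}",
                )
                state.solve()
            except (InvalidParameterError, NoEquilibriumError):
                continue
            cohort.append(state)
            break
        else:
            raise GenerationError(
                f"no solvable state within {max_rejections} draws for patient "
                f"{i}; bounds are likely infeasible"
            )
    return cohort


def load_prone_fixture(name: str) -> tuple[PatientState, Intervention]:
    """Load a packaged prone-position scenario.

    ``name`` is ``"preload_responsive"`` (steep-limb baseline whose flow
    and P_RA both rise with pronation) or ``"cardiac_limited"`` (plateau
    baseline where pronation only shifts P_RA).
    """
    fname = f"prone_{name}.yaml"
    try:
        text = resources.files("guytonsim.fixtures").joinpath(fname).read_text()
    except FileNotFoundError:
        raise InvalidInputError(
            f"unknown prone fixture {name!r}; expected 'preload_responsive' "
            "or 'cardiac_limited'"
        ) from None
    data = yaml.safe_load(text)
    return (
        PatientState.model_validate(data["patient"]),
        Intervention.model_validate(data["prone"]),
    )
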