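"""Scenario configuration, serialization, curve sampling, unit conversion.

Human-authored configurations are YAML (JSON is a YAML subset and is
accepted transparently); machine output is JSON or CSV. Configurations are
flat maps of the model's independent variables; the paper-of-record
conductance estimates are the defaults, so an empty config ``{}`` is the
canonical resting adult circulation: P_MSF 8 mmHg, G_cardiac 35 and G_VR
10 mL/kg/min per mmHg, collapse pressure -2 mmHg, cardiac plateau 6 mmHg,
no ventilator, slack pericardium.

CSV output uses a fixed dialect ('.' decimal, ',' separator, header row,
'#'-prefixed units metadata lines) so outputs compare bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import ConfigDict, ValidationError

from ._version import __version__
from .curves import (
    PericardialComponents,
    RecoilModel,
    VenousReturnCurve,
    _FrozenModel,
)
from .equilibrium import OperatingPoint, SolverSettings
from .errors import InvalidInputError, InvalidParameterError
from .scenarios import CardiacSpec, Intervention, PatientState, TransitionResult

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "dump_scenario",
    "sample_curves",
    "flow_to_absolute",
    "operating_point_to_dict",
    "transition_to_dict",
    "write_curve_table",
    "write_sweep_table",
    "write_cohort_table",
    "UNITS",
]

#: Units of every quantity the package reads or writes.
UNITS = {
    "p_msf": "mmHg",
    "p_crit": "mmHg",
    "p_ra_plat": "mmHg",
    "p_pl": "mmHg",
    "p_aw": "mmHg",
    "p_pc_el": "mmHg",
    "p_ra": "mmHg",
    "p_ra_transmural": "mmHg",
    "g_vr": "mL/kg/min/mmHg",
    "g_cardiac": "mL/kg/min/mmHg",
    "r_vr": "mmHg*kg*min/mL",
    "r_cardiac": "mmHg*kg*min/mL",
    "q_circulatory": "mL/kg/min",
    "venous_return": "mL/kg/min",
    "cardiac_output": "mL/kg/min",
    "q_absolute": "L/min",
    "e_cw_ratio": "dimensionless",
    "body_mass": "kg",
    "value": "parameter units",
}


class ScenarioConfig(_FrozenModel):
    """Flat, validated description of one scenario.

    Conductances are accepted in the literature's per-kg units and stored
    as given; resistances are derived (R = 1/G) when building the
    `PatientState`. The chest-wall/respiratory elastance coupling may be
    supplied either as two elastances (``e_cw``, ``e_rs``) or as a single
    ``e_cw_ratio`` (then stored internally against e_rs = 1). Unknown keys
    are rejected with the offending key named.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    # venous side
    p_msf: float = 8.0
    g_vr: float = 10.0
    p_crit: float = -2.0
    # cardiac side
    g_cardiac: float = 35.0
    p_ra_plat: float = 6.0
    # pericardial decomposition
    p_pl: float = 0.0
    p_aw: float = 0.0
    e_cw: float | None = None
    e_rs: float | None = None
    e_cw_ratio: float | None = None
    p_pc_el: float = 0.0
    # pericardial recoil
    recoil: RecoilModel = RecoilModel()
    # patient / plumbing
    body_mass: float = 70.0
    label: str = ""
    interventions: tuple[Intervention, ...] = ()
    solver: SolverSettings = SolverSettings()
    out: str | None = None

    def model_post_init(self, context, /) -> None:
        if self.g_vr <= 0 or self.g_cardiac <= 0:
            raise InvalidParameterError("g_vr and g_cardiac must be positive")
        if self.p_crit >= self.p_msf:
            raise InvalidParameterError(
                f"p_crit ({self.p_crit}) must be below p_msf ({self.p_msf})"
            )
        if self.e_cw_ratio is not None and (self.e_cw is not None or self.e_rs is not None):
            raise InvalidParameterError(
                "give either e_cw_ratio or the e_cw/e_rs pair, not both"
            )
        if (self.e_cw is None) != (self.e_rs is None):
            raise InvalidParameterError("e_cw and e_rs must be given together")
        if self.body_mass <= 0:
            raise InvalidParameterError("body_mass must be positive")

    def pericardium(self) -> PericardialComponents:
        if self.e_cw_ratio is not None:
            e_cw, e_rs = self.e_cw_ratio, 1.0
        elif self.e_cw is not None:
            e_cw, e_rs = self.e_cw, self.e_rs
        else:
            e_cw, e_rs = 0.0, 1.0
        return PericardialComponents(
            p_pl=self.p_pl, p_aw=self.p_aw, e_cw=e_cw, e_rs=e_rs,
            p_pc_el=self.p_pc_el,
        )

    def patient_state(self) -> PatientState:
        return PatientState(
            vr_curve=VenousReturnCurve(
                p_msf=self.p_msf, r_vr=1.0 / self.g_vr, p_crit=self.p_crit
            ),
            cardiac=CardiacSpec(
                pericardium=self.pericardium(),
                r_cardiac=1.0 / self.g_cardiac,
                p_ra_plat=self.p_ra_plat,
            ),
            recoil_model=self.recoil,
            body_mass=self.body_mass,
            label=self.label,
        )


def load_scenario(source: str | Path) -> ScenarioConfig:
    """Parse a scenario from a YAML/JSON file path or literal text.

    A `Path` (or a string naming an existing file) is read from disk;
    any other string is parsed directly.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif len(source) < 4096 and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    else:
        text = source
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InvalidInputError(f"malformed scenario text: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise InvalidInputError("scenario must be a mapping of parameters")
    try:
        return ScenarioConfig.model_validate(data)
    except ValidationError as exc:
        # keep pydantic's field-naming message but raise our own type
        raise InvalidParameterError(str(exc)) from exc


def dump_scenario(config: ScenarioConfig) -> str:
    """Serialize a config to YAML that `load_scenario` round-trips losslessly."""
    data = config.model_dump(mode="json", exclude_none=True)
    if not config.interventions:
        data.pop("interventions", None)
    return yaml.safe_dump(data, sort_keys=True)


def sample_curves(
    state: PatientState,
    p_ra_min: float,
    p_ra_max: float,
    n_points: int,
) -> pd.DataFrame:
    """Evaluate both curves on a uniform P_RA grid (diagram export).

    Returns exactly ``n_points`` rows with columns (p_ra, venous_return,
    cardiac_output, is_operating_point); the flag marks the grid row
    nearest the solved operating point. Generating parameters and units
    travel in ``DataFrame.attrs``.
    """
    if p_ra_min >= p_ra_max:
        raise InvalidInputError("p_ra_min must be below p_ra_max")
    if n_points < 2:
        raise InvalidInputError("n_points must be at least 2")
    from .curves import cardiac_output_flow, venous_return_flow

    cf = state.cardiac.curve()
    grid = np.linspace(p_ra_min, p_ra_max, n_points)
    df = pd.DataFrame(
        {
            "p_ra": grid,
            "venous_return": [venous_return_flow(p, state.vr_curve) for p in grid],
            "cardiac_output": [cardiac_output_flow(p, cf) for p in grid],
        }
    )
    op = state.solve()
    flag = np.zeros(n_points, dtype=bool)
    flag[int(np.argmin(np.abs(grid - op.p_ra)))] = True
    df["is_operating_point"] = flag
    df.attrs["parameters"] = {
        "p_msf": state.vr_curve.p_msf,
        "r_vr": state.vr_curve.r_vr,
        "p_crit": state.vr_curve.p_crit,
        "p_pc": cf.p_pc,
        "r_cardiac": cf.r_cardiac,
        "p_ra_plat": cf.p_ra_plat,
    }
    df.attrs["operating_point"] = operating_point_to_dict(op, raw=True)
    df.attrs["units"] = {k: UNITS[k] for k in ("p_ra", "venous_return", "cardiac_output")}
    return df


def flow_to_absolute(q: float, body_mass: float) -> float:
    """Convert a weight-indexed flow (mL/kg/min) to absolute L/min."""
    if body_mass <= 0:
        raise InvalidParameterError("body_mass must be positive")
    return q * body_mass / 1000.0


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def operating_point_to_dict(
    op: OperatingPoint, body_mass: float | None = None, raw: bool = False
) -> dict:
    """JSON-ready view of an operating point, with units metadata."""
    fmt = (lambda x: x) if raw else _round6
    out = {
        "p_ra": fmt(op.p_ra),
        "q_circulatory": fmt(op.q_circulatory),
        "regime": op.regime,
        "p_ra_transmural": fmt(op.p_ra_transmural),
        "units": {
            "p_ra": UNITS["p_ra"],
            "q_circulatory": UNITS["q_circulatory"],
            "p_ra_transmural": UNITS["p_ra_transmural"],
        },
    }
    if body_mass is not None:
        out["q_absolute"] = fmt(flow_to_absolute(op.q_circulatory, body_mass))
        out["units"]["q_absolute"] = UNITS["q_absolute"]
    return out


def transition_to_dict(result: TransitionResult, raw: bool = False) -> dict:
    fmt = (lambda x: x) if raw else _round6
    return {
        "before": operating_point_to_dict(result.before, raw=raw),
        "after": operating_point_to_dict(result.after, raw=raw),
        "delta_q": fmt(result.delta_q),
        "delta_p_ra": fmt(result.delta_p_ra),
        "regime_change": list(result.regime_change),
        "units": {"delta_q": UNITS["q_circulatory"], "delta_p_ra": UNITS["p_ra"]},
    }


def _units_header(columns) -> str:
    pairs = ", ".join(f"{c}={UNITS.get(c, 'n/a')}" for c in columns)
    return f"# guytonsim {__version__}\n# units: {pairs}\n"


class _maybe_open:
    """Open a path for writing, or pass a file object through unchanged."""

    def __init__(self, target):
        self.target = target
        self._fh = None

    def __enter__(self):
        if hasattr(self.target, "write"):
            return self.target
        self._fh = open(self.target, "w", newline="")
        return self._fh

    def __exit__(self, *exc):
        if self._fh is not None:
            self._fh.close()
        return False


def _write_csv(df: pd.DataFrame, path) -> None:
    numeric = df.select_dtypes(include=[np.number]).columns
    out = df.copy()
    for c in numeric:
        out[c] = out[c].map(lambda x: "" if pd.isna(x) else f"{x:.10g}")
    with _maybe_open(path) as fh:
        fh.write(_units_header(df.columns))
        out.to_csv(fh, index=False)


def write_curve_table(df: pd.DataFrame, path) -> None:
    """Write a `sample_curves` table as CSV with a units/parameters header."""
    with _maybe_open(path) as fh:
        fh.write(_units_header(df.columns))
        params = df.attrs.get("parameters")
        if params:
            fh.write("# parameters: " + json.dumps(params) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def write_sweep_table(df: pd.DataFrame, path) -> None:
    """Write a parameter-sweep table as CSV (no-equilibrium rows kept)."""
    _write_csv(df, path)


def write_cohort_table(cohort, path) -> None:
    """Write a synthetic cohort with solved operating points as CSV."""
    rows = []
    for s in cohort:
        op = s.solve()
        cf = s.cardiac.curve()
        rows.append(
            {
                "label": s.label,
                "p_msf": s.vr_curve.p_msf,
                "r_vr": s.vr_curve.r_vr,
                "p_crit": s.vr_curve.p_crit,
                "r_cardiac": s.cardiac.r_cardiac,
                "p_ra_plat": s.cardiac.p_ra_plat,
                "p_pc": cf.p_pc,
                "body_mass": s.body_mass,
                "p_ra": op.p_ra,
                "q_circulatory": op.q_circulatory,
                "regime": op.regime,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["units"] = {k: UNITS.get(k, "n/a") for k in df.columns}
    _write_csv(df, path)
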