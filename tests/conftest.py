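import numpy as np
import pytest

from guytonsim import (
    CardiacFunctionCurve,
    SolverSettings,
    VenousReturnCurve,
)

R_CARDIAC_DEFAULT = 1.0 / 35.0  # inverse of the canonical cardiac conductance
R_VR_DEFAULT = 1.0 / 10.0  # inverse of the canonical venous conductance


@pytest.fixture
def default_vr() -> VenousReturnCurve:
    """Canonical resting venous-return curve: P_MSF 8, G_VR 10, P_CRIT -2."""
    return VenousReturnCurve(p_msf=8.0, r_vr=R_VR_DEFAULT, p_crit=-2.0)


@pytest.fixture
def default_cf() -> CardiacFunctionCurve:
    """Canonical cardiac-function curve: P_PC 0, G_cardiac 35, plateau 6."""
    return CardiacFunctionCurve(p_pc=0.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=6.0)


@pytest.fixture
def settings() -> SolverSettings:
    return SolverSettings()


def random_valid_curves(rng: np.random.Generator):
    """One uniformly random structurally valid and solvable curve pair.

    Draws until p_crit < p_msf, p_ra_plat > p_pc and p_pc < p_msf all hold,
    so every returned pair admits an equilibrium.
    """
    while True:
        p_msf = rng.uniform(2.0, 20.0)
        p_crit = rng.uniform(-6.0, p_msf - 0.5)
        r_vr = rng.uniform(0.02, 0.5)
        p_pc = rng.uniform(-4.0, p_msf - 0.5)
        p_ra_plat = rng.uniform(p_pc + 0.5, p_pc + 14.0)
        r_cardiac = rng.uniform(0.01, 0.2)
        vr = VenousReturnCurve(p_msf=p_msf, r_vr=r_vr, p_crit=p_crit)
        cf = CardiacFunctionCurve(p_pc=p_pc, r_cardiac=r_cardiac, p_ra_plat=p_ra_plat)
        return vr, cf
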