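"""Operating-point solver: closed form, oracle agreement, sensitivities."""

import numpy as np
import pytest

from guytonsim import (
    CardiacFunctionCurve,
    ConvergenceError,
    NoEquilibriumError,
    NondifferentiablePointError,
    PericardialComponents,
    RecoilModel,
    SolverSettings,
    VenousReturnCurve,
    cardiac_output_flow,
    oracle_intersection,
    pericardial_recoil,
    self_consistent_solve,
    sensitivities,
    solve_operating_point,
    transmural_pra,
    venous_return_flow,
)
from guytonsim.scenarios import CardiacSpec, PatientState

from conftest import R_CARDIAC_DEFAULT, R_VR_DEFAULT, random_valid_curves


class TestSolveOperatingPoint:
    def test_canonical_resting_state_is_unlimited(self, default_vr, default_cf):
        op = solve_operating_point(default_vr, default_cf)
        assert op.regime == "unlimited"
        assert op.q_circulatory == pytest.approx(62.222222, abs=1e-5)
        assert op.p_ra == pytest.approx(1.777778, abs=1e-5)
        assert op.p_ra_transmural == pytest.approx(op.p_ra - default_cf.p_pc)

    def test_both_back_substitutions_recover_p_ra(self, default_vr, default_cf):
        """Cardiac and venous back-substitution agree at the solution."""
        op = solve_operating_point(default_vr, default_cf)
        via_cardiac = default_cf.p_pc + op.q_circulatory * default_cf.r_cardiac
        via_venous = default_vr.p_msf - op.q_circulatory * default_vr.r_vr
        assert abs(via_cardiac - via_venous) < 1e-9
        assert op.p_ra == pytest.approx(via_cardiac, abs=1e-9)

    def test_low_plateau_gives_cardiac_limitation(self, default_vr):
        cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=1.0)
        op = solve_operating_point(default_vr, cf)
        assert op.regime == "cardiac_limited"
        assert op.q_circulatory == pytest.approx(35.0)
        assert op.p_ra == pytest.approx(4.5)

    def test_waterfall_gives_venous_limitation(self):
        vr = VenousReturnCurve(p_msf=8.0, r_vr=R_VR_DEFAULT, p_crit=0.0)
        cf = CardiacFunctionCurve(p_pc=-3.5, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=6.0)
        op = solve_operating_point(vr, cf)
        assert op.regime == "venous_limited"
        assert op.q_circulatory == pytest.approx(80.0)
        assert op.p_ra == pytest.approx(-1.214285714, abs=1e-8)

    def test_pericardial_pressure_above_msf_has_no_equilibrium(self):
        vr = VenousReturnCurve(p_msf=8.0, r_vr=R_VR_DEFAULT, p_crit=-2.0)
        cf = CardiacFunctionCurve(p_pc=10.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=12.0)
        with pytest.raises(NoEquilibriumError):
            solve_operating_point(vr, cf)

    def test_coincident_plateaus_report_doubly_limited_midpoint(self):
        # venous plateau: (12 - 4)/0.1 = 80; cardiac plateau: (2 - 0)/0.025 = 80
        vr = VenousReturnCurve(p_msf=12.0, r_vr=0.1, p_crit=4.0)
        cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=0.025, p_ra_plat=2.0)
        op = solve_operating_point(vr, cf)
        assert op.regime == "doubly_limited"
        assert op.q_circulatory == pytest.approx(80.0)
        assert op.p_ra == pytest.approx(3.0)  # midpoint of [2, 4]

    def test_flows_balance_at_equilibrium(self, settings):
        rng = np.random.default_rng(7)
        for _ in range(200):
            vr, cf = random_valid_curves(rng)
            op = solve_operating_point(vr, cf, settings)
            if op.regime == "doubly_limited":
                continue
            assert venous_return_flow(op.p_ra, vr) == pytest.approx(
                op.q_circulatory, abs=1e-9
            )
            assert cardiac_output_flow(op.p_ra, cf) == pytest.approx(
                op.q_circulatory, abs=1e-9
            )

    def test_regimes_are_exhaustive(self):
        rng = np.random.default_rng(11)
        seen = set()
        for _ in range(500):
            vr, cf = random_valid_curves(rng)
            seen.add(solve_operating_point(vr, cf).regime)
        assert seen <= {"unlimited", "cardiac_limited", "venous_limited", "doubly_limited"}
        assert {"unlimited", "cardiac_limited", "venous_limited"} <= seen


class TestOracleEquivalence:
    def test_matches_closed_form_on_examples(self, default_vr, default_cf):
        closed = solve_operating_point(default_vr, default_cf)
        numeric = oracle_intersection(default_vr, default_cf)
        assert numeric.p_ra == pytest.approx(closed.p_ra, abs=1e-6)
        assert numeric.q_circulatory == pytest.approx(closed.q_circulatory, abs=1e-6)
        assert numeric.regime == closed.regime

    def test_matches_closed_form_on_random_sweep(self):
        rng = np.random.default_rng(42)
        max_dp = max_dq = 0.0
        for _ in range(1000):
            vr, cf = random_valid_curves(rng)
            closed = solve_operating_point(vr, cf)
            numeric = oracle_intersection(vr, cf)
            assert numeric.regime == closed.regime
            max_dp = max(max_dp, abs(numeric.p_ra - closed.p_ra))
            max_dq = max(max_dq, abs(numeric.q_circulatory - closed.q_circulatory))
        assert max_dp < 1e-6
        assert max_dq < 1e-6

    def test_cardiac_limited_label_identical(self, default_vr):
        cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=1.0)
        assert (
            oracle_intersection(default_vr, cf).regime
            == solve_operating_point(default_vr, cf).regime
            == "cardiac_limited"
        )


class TestMonotonicity:
    def test_flow_responds_monotonically_to_each_variable(self):
        """q* rises with P_MSF, falls with R_VR, R_cardiac and P_PC."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            vr, cf = random_valid_curves(rng)
            base = solve_operating_point(vr, cf).q_circulatory
            up_msf = solve_operating_point(
                vr.model_copy(update={"p_msf": vr.p_msf + 1}), cf
            ).q_circulatory
            up_rvr = solve_operating_point(
                vr.model_copy(update={"r_vr": vr.r_vr * 1.5}), cf
            ).q_circulatory
            up_rc = solve_operating_point(
                vr, cf.model_copy(update={"r_cardiac": cf.r_cardiac * 1.5})
            ).q_circulatory
            assert up_msf >= base - 1e-12
            assert up_rvr <= base + 1e-12
            assert up_rc <= base + 1e-12


class TestSensitivities:
    def test_unlimited_partials(self, default_vr, default_cf):
        table = sensitivities(default_vr, default_cf)
        s = R_CARDIAC_DEFAULT + R_VR_DEFAULT
        assert table.loc["q_circulatory", "p_msf"] == pytest.approx(1 / s)
        assert table.loc["q_circulatory", "p_msf"] == pytest.approx(7.7777778, abs=1e-6)
        assert table.loc["q_circulatory", "p_pc"] == pytest.approx(
            -table.loc["q_circulatory", "p_msf"]
        )

    def test_cardiac_limited_partials(self, default_vr):
        cf = CardiacFunctionCurve(p_pc=0.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=1.0)
        table = sensitivities(default_vr, cf)
        assert table.loc["q_circulatory", "p_msf"] == 0.0
        assert table.loc["q_circulatory", "r_vr"] == 0.0
        assert table.loc["p_ra", "p_msf"] == 1.0

    def test_venous_limited_cardiac_partials_vanish(self):
        vr = VenousReturnCurve(p_msf=8.0, r_vr=R_VR_DEFAULT, p_crit=0.0)
        cf = CardiacFunctionCurve(p_pc=-3.5, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=6.0)
        table = sensitivities(vr, cf)
        assert table.loc["q_circulatory", "r_cardiac"] == 0.0
        assert table.loc["q_circulatory", "p_pc"] == 0.0

    def test_breakpoint_is_nondifferentiable(self):
        vr = VenousReturnCurve(p_msf=8.0, r_vr=R_VR_DEFAULT, p_crit=-2.0)
        # place the unlimited solution exactly at the plateau onset
        cf = CardiacFunctionCurve(
            p_pc=0.0, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=1.7777777777777777
        )
        with pytest.raises(NondifferentiablePointError):
            sensitivities(vr, cf)

    def test_matches_central_finite_differences(self):
        """Analytic partials track numerical ones away from breakpoints."""
        rng = np.random.default_rng(17)
        h = 1e-5
        checked = 0
        while checked < 100:
            vr, cf = random_valid_curves(rng)
            op = solve_operating_point(vr, cf)
            # keep a safe margin so the perturbed solves stay in-regime
            if (
                min(abs(op.p_ra - cf.p_ra_plat), abs(op.p_ra - vr.p_crit)) < 0.05
                or op.regime == "doubly_limited"
            ):
                continue
            table = sensitivities(vr, cf)

            def perturbed(param, delta):
                if param in ("p_msf", "r_vr"):
                    return solve_operating_point(
                        vr.model_copy(update={param: getattr(vr, param) + delta}), cf
                    )
                return solve_operating_point(
                    vr, cf.model_copy(update={param: getattr(cf, param) + delta})
                )

            for param in ("p_msf", "p_pc", "r_vr", "r_cardiac"):
                hi, lo = perturbed(param, h), perturbed(param, -h)
                fd_q = (hi.q_circulatory - lo.q_circulatory) / (2 * h)
                fd_p = (hi.p_ra - lo.p_ra) / (2 * h)
                scale_q = max(1.0, abs(fd_q))
                scale_p = max(1.0, abs(fd_p))
                assert abs(table.loc["q_circulatory", param] - fd_q) / scale_q < 1e-4
                assert abs(table.loc["p_ra", param] - fd_p) / scale_p < 1e-4
            checked += 1


class TestTransmuralPressure:
    @pytest.mark.parametrize(
        "p_ra, p_pc, expected", [(1.778, 0.5, 1.278), (4.0, 4.0, 0.0), (5.0, -2.5, 7.5)]
    )
    def test_subtraction(self, p_ra, p_pc, expected):
        assert transmural_pra(p_ra, p_pc) == pytest.approx(expected)


def _state(p_msf, pericardium, recoil, p_ra_plat=6.0):
    return PatientState(
        vr_curve=VenousReturnCurve(p_msf=p_msf, r_vr=R_VR_DEFAULT, p_crit=-2.0),
        cardiac=CardiacSpec(
            pericardium=pericardium, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=p_ra_plat
        ),
        recoil_model=recoil,
    )


class TestSelfConsistentSolve:
    def test_zero_slope_recoil_equals_plain_solver(self, default_vr, default_cf):
        state = _state(
            8.0,
            PericardialComponents(),
            RecoilModel(slope_low=0.0, slope_high=0.0),
        )
        assert self_consistent_solve(state) == solve_operating_point(
            default_vr, default_cf
        )

    def test_below_engagement_threshold_recoil_stays_zero(self, default_vr, default_cf):
        state = _state(8.0, PericardialComponents(), RecoilModel())
        op = self_consistent_solve(state)
        # transmural P_RA 1.78 < engagement at 5 mmHg: no recoil feedback
        assert op == solve_operating_point(default_vr, default_cf)

    def test_engaged_recoil_matches_dense_fixed_point_scan(self):
        """High filling pressure engages the sac; iterate vs. grid search."""
        state = _state(24.0, PericardialComponents(), RecoilModel(), p_ra_plat=12.0)
        op = self_consistent_solve(state)
        assert op.p_ra_transmural > state.recoil_model.engage_threshold

        # independent route: scan P_PC_EL densely for self-consistency,
        # coarse pass then a fine pass around the best candidate
        vr = state.vr_curve

        def scan(lo, hi, n):
            best_el, best_err = lo, np.inf
            for el in np.linspace(lo, hi, n):
                cf = CardiacFunctionCurve(
                    p_pc=el, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=12.0
                )
                inner = solve_operating_point(vr, cf)
                err = abs(
                    pericardial_recoil(inner.p_ra_transmural, state.recoil_model) - el
                )
                if err < best_err:
                    best_el, best_err = el, err
            return best_el

        coarse = scan(0.0, 6.0, 6001)
        best_el = scan(coarse - 2e-3, coarse + 2e-3, 4001)
        cf = CardiacFunctionCurve(p_pc=best_el, r_cardiac=R_CARDIAC_DEFAULT, p_ra_plat=12.0)
        reference = solve_operating_point(vr, cf)
        assert op.p_ra == pytest.approx(reference.p_ra, abs=1e-6)
        assert op.q_circulatory == pytest.approx(reference.q_circulatory, abs=1e-5)

    def test_nonconvergence_reports_last_iterate(self):
        # the engaged fixed point needs more than two damped steps
        state = _state(24.0, PericardialComponents(), RecoilModel(), p_ra_plat=12.0)
        with pytest.raises(ConvergenceError) as excinfo:
            self_consistent_solve(state, max_iterations=2)
        assert excinfo.value.last_iterate is not None
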