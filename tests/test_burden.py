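"""Patient-level models: MCP, burden reduction, step curves, solvers."""

import math

import numpy as np
import pytest

from mbrplan import (
    Lesion,
    Patient,
    SynthConfig,
    ValidationError,
    generate_cohort,
    mbr,
    mbr_curve,
    mcp,
    plan_patient,
    solve_pmad_for_mbr,
    solve_pmad_for_mcp,
    tcp,
    tcp_threshold_dose,
)
from mbrplan.burden import (
    FLAG_MBR_UNREACHABLE,
    FLAG_MCP_UNREACHABLE,
    FLAG_ZERO_DOSE,
    lesion_threshold_doses,
)


def grid_scan_mbr(patient, params, scales):
    """Brute-force oracle: evaluate the MBR definition on a scale grid."""
    return np.array([mbr(patient, s, params) for s in scales])


class TestPatient:
    def test_derived_burden_and_pmad(self, toy_patient):
        assert toy_patient.burden == 40.0
        assert toy_patient.pmad == 1.5

    def test_needs_a_lesion(self):
        with pytest.raises(ValidationError):
            Patient("empty", ())

    def test_lesion_validation(self):
        with pytest.raises(ValidationError):
            Lesion("bad", -1.0, 5.0)
        with pytest.raises(ValidationError):
            Lesion("bad", 1.0, -5.0)


class TestMcp:
    def test_single_lesion_collapses_to_tcp(self, params, single_lesion_patient):
        lesion = single_lesion_patient.lesions[0]
        assert mcp(single_lesion_patient, 3.0, params) == pytest.approx(
            tcp(3.0 * lesion.dose, lesion.volume, params), rel=1e-12
        )

    def test_uncontrolled_lesion_annihilates_product(self, params):
        patient = Patient("p", (Lesion("a", 1.0, 100.0), Lesion("b", 500.0, 0.0)))
        assert mcp(patient, 1.0, params) == 0.0

    def test_two_threshold_lesions_square_the_probability(self, params):
        d = tcp_threshold_dose(1.0, params, 0.95)
        patient = Patient("p", (Lesion("a", 1.0, d), Lesion("b", 1.0, d)))
        assert mcp(patient, 1.0, params) == pytest.approx(0.95**2, abs=1e-6)

    def test_non_decreasing_in_scale(self, params, toy_patient):
        scales = np.linspace(0.0, 100.0, 50)
        values = [mcp(toy_patient, s, params) for s in scales]
        assert np.all(np.diff(values) >= 0)


class TestMbr:
    def test_no_dose_no_reduction(self, params, toy_patient):
        assert mbr(toy_patient, 0.0, params) == 0.0

    def test_everything_eradicated_beyond_all_thresholds(self, params, toy_patient):
        assert mbr(toy_patient, 1e3, params) == 1.0

    def test_partial_reduction_at_intermediate_scale(self, params, toy_patient):
        # At scale 50 only the 30 ml lesion (2 Gy -> 100 Gy, threshold
        # ~85.7 Gy) is eradicated; the 10 ml lesion (50 Gy < ~82.5 Gy) is not.
        assert mbr(toy_patient, 50.0, params) == pytest.approx(0.75)

    def test_at_most_n_plus_one_values(self, params, toy_patient):
        values = {mbr(toy_patient, s, params) for s in np.linspace(0, 200, 2000)}
        assert len(values) <= toy_patient.n_lesions + 1

    def test_eradication_inclusive_at_exact_cutoff(self, params):
        # A lesion sitting exactly at TCP = cutoff counts as eradicated.
        d = tcp_threshold_dose(5.0, params, 0.95)
        patient = Patient("p", (Lesion("a", 5.0, d),))
        assert tcp(d, 5.0, params) >= 0.95
        assert mbr(patient, 1.0, params) == 1.0


class TestMbrCurve:
    def test_toy_breakpoints(self, params, toy_patient):
        curve = mbr_curve(toy_patient, params)
        pmads = curve.pmad_values()
        assert pmads == pytest.approx([64.27, 123.74], abs=0.05)
        assert curve.mbr_values() == pytest.approx([0.75, 1.0])

    def test_single_lesion_single_jump(self, params, single_lesion_patient):
        curve = mbr_curve(single_lesion_patient, params)
        assert len(curve.breakpoints) == 1
        assert curve.mbr_values()[0] == 1.0
        assert curve(curve.pmad_values()[0] - 1e-9) == 0.0
        assert curve(curve.pmad_values()[0]) == 1.0  # right-continuous

    def test_tied_thresholds_merge_into_one_breakpoint(self, params):
        patient = Patient("p", (Lesion("a", 2.0, 4.0), Lesion("b", 2.0, 4.0),
                                Lesion("c", 8.0, 1.0)))
        curve = mbr_curve(patient, params)
        assert len(curve.breakpoints) == 2
        assert curve.mbr_values()[0] == pytest.approx(4.0 / 12.0)

    def test_matches_grid_scan_oracle(self, params):
        cohort = generate_cohort(SynthConfig(n_patients=20, seed=3))
        rng = np.random.default_rng(0)
        for patient in cohort:
            curve = mbr_curve(patient, params)
            top = curve.pmad_values().max() / patient.pmad
            scales = rng.uniform(0.0, 1.2 * top, size=500)
            oracle = grid_scan_mbr(patient, params, scales)
            analytic = curve(scales * patient.pmad)
            np.testing.assert_allclose(analytic, oracle, atol=1e-12)

    def test_zero_dose_lesion_caps_curve(self, params):
        patient = Patient("p", (Lesion("a", 10.0, 5.0), Lesion("b", 30.0, 0.0)))
        curve = mbr_curve(patient, params)
        assert FLAG_ZERO_DOSE in curve.flags
        assert FLAG_MBR_UNREACHABLE in curve.flags
        assert curve.mbr_values().max() == pytest.approx(0.25)

    def test_trivially_controlled_lesion_lifts_baseline(self, params):
        tiny = 0.01 / params.rho_c
        patient = Patient("p", (Lesion("a", tiny, 1.0), Lesion("b", tiny * 3, 1.0)))
        curve = mbr_curve(patient, params)
        assert curve.baseline == 1.0
        assert curve.breakpoints == ()


class TestSolvePmadForMcp:
    def test_single_lesion_matches_closed_form(self, params, single_lesion_patient):
        result = solve_pmad_for_mcp(single_lesion_patient, params, 0.95)
        assert result.pmad_mcp == pytest.approx(
            tcp_threshold_dose(227.0, params, 0.95), abs=0.01
        )
        assert result.pmad_mcp == pytest.approx(result.scale_mcp * 19.0, rel=1e-12)

    def test_two_identical_lesions_need_root_cutoff(self, params):
        patient = Patient("p", (Lesion("a", 1.0, 7.0), Lesion("b", 1.0, 7.0)))
        result = solve_pmad_for_mcp(patient, params, 0.95)
        expected = tcp_threshold_dose(1.0, params, math.sqrt(0.95))
        assert result.pmad_mcp == pytest.approx(expected, abs=0.01)

    def test_monotone_in_target(self, params, toy_patient):
        doses = [solve_pmad_for_mcp(toy_patient, params, t).pmad_mcp
                 for t in (0.9, 0.95, 0.99)]
        assert doses[0] <= doses[1] <= doses[2]

    def test_zero_dose_lesion_flags_unreachable(self, params):
        patient = Patient("p", (Lesion("a", 10.0, 5.0), Lesion("b", 30.0, 0.0)))
        result = solve_pmad_for_mcp(patient, params, 0.95)
        assert FLAG_MCP_UNREACHABLE in result.flags
        assert math.isinf(result.pmad_mcp)

    def test_solution_controls_every_lesion(self, params):
        cohort = generate_cohort(SynthConfig(n_patients=5, seed=9))
        for patient in cohort:
            result = solve_pmad_for_mcp(patient, params, 0.95)
            tcps = tcp(result.scale_mcp * patient.doses, patient.volumes, params)
            assert np.all(tcps >= 0.95 - 1e-9)


class TestSolvePmadForMbr:
    def test_toy_half_reduction(self, params, toy_patient):
        result = solve_pmad_for_mbr(toy_patient, params, 0.5)
        assert result.pmad_mbr == pytest.approx(64.27, abs=0.05)

    def test_single_lesion_any_fraction_hits_threshold(self, params,
                                                       single_lesion_patient):
        threshold = tcp_threshold_dose(227.0, params)
        for fraction in (0.1, 0.5, 1.0):
            result = solve_pmad_for_mbr(single_lesion_patient, params, fraction)
            assert result.pmad_mbr == pytest.approx(threshold, rel=1e-12)

    def test_full_reduction_cheaper_than_full_control(self, params):
        cohort = generate_cohort(SynthConfig(n_patients=20, seed=5))
        for patient in cohort:
            full = solve_pmad_for_mbr(patient, params, 1.0).pmad_mbr
            control = solve_pmad_for_mcp(patient, params, 0.95).pmad_mcp
            assert full <= control + 1e-9

    def test_unachievable_fraction_flagged(self, params):
        patient = Patient("p", (Lesion("a", 10.0, 5.0), Lesion("b", 30.0, 0.0)))
        result = solve_pmad_for_mbr(patient, params, 0.5)
        assert FLAG_MBR_UNREACHABLE in result.flags
        assert math.isinf(result.pmad_mbr)

    def test_achievable_fraction_despite_cold_lesion(self, params):
        patient = Patient("p", (Lesion("a", 30.0, 5.0), Lesion("b", 10.0, 0.0)))
        result = solve_pmad_for_mbr(patient, params, 0.5)
        assert math.isfinite(result.pmad_mbr)
        assert FLAG_MBR_UNREACHABLE not in result.flags


class TestScaleInvariance:
    """Planning depends only on the relative dose distribution."""

    @pytest.mark.parametrize("c", [0.01, 0.37, 100.0])
    def test_rescaled_doses_same_planned_pmads(self, params, c):
        cohort = generate_cohort(SynthConfig(n_patients=5, seed=13))
        for patient in cohort:
            base = plan_patient(patient, params)
            scaled = plan_patient(patient.scaled(c), params)
            assert scaled.pmad_mcp == pytest.approx(base.pmad_mcp, rel=1e-6)
            assert scaled.pmad_mbr == pytest.approx(base.pmad_mbr, rel=1e-6)


class TestAlphaSensitivity:
    def test_higher_alpha_lowers_both_planned_doses(self, params):
        hot = params.replace(alpha=0.25)
        cohort = generate_cohort(SynthConfig(n_patients=10, seed=21))
        for patient in cohort:
            assert (solve_pmad_for_mcp(patient, hot).pmad_mcp
                    < solve_pmad_for_mcp(patient, params).pmad_mcp)
            assert (solve_pmad_for_mbr(patient, hot, 0.5).pmad_mbr
                    < solve_pmad_for_mbr(patient, params, 0.5).pmad_mbr)


def test_threshold_doses_vector_matches_scalar(params, toy_patient):
    expected = [tcp_threshold_dose(l.volume, params) for l in toy_patient.lesions]
    np.testing.assert_allclose(lesion_threshold_doses(toy_patient, params), expected)
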