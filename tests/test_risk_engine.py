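"""Risk-engine unit and property tests: linear predictor arithmetic, the
piecewise race hazard, drug remapping, percentile risk groups and CKD-EPI."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iganpt.risk_engine import (
    CoefficientSet,
    CoefficientTerm,
    RacePiecewise,
    assign_risk_groups,
    ckd_epi_egfr,
    compute_linear_predictor,
    predict_risk,
    remap_novel_drugs,
)


def make_set(terms, baseline=((0, 1.0), (36, 0.95), (60, 0.9), (80, 0.85)),
             variant="without_race", piecewise=None):
    return CoefficientSet(
        name="test",
        model_id="at_biopsy",
        variant=variant,
        terms=tuple(terms),
        baseline_survival=tuple(baseline),
        race_piecewise=piecewise,
    )


class TestLinearPredictor:
    def test_all_covariates_at_centers_gives_zero(self, make_record, toy_coeffs):
        rec = make_record(proteinuria_g_day=1.0, egfr=76.0)  # ln(1) = 0 = center
        assert compute_linear_predictor(rec, toy_coeffs) == pytest.approx(0.0)

    def test_log_term_dot_product(self, make_record):
        cs = make_set([CoefficientTerm("proteinuria_g_day", "log", 0.0, 0.5)])
        rec = make_record(proteinuria_g_day=math.e)
        assert compute_linear_predictor(rec, cs) == pytest.approx(0.5)

    def test_two_term_dot_product(self, make_record):
        cs = make_set(
            [
                CoefficientTerm("egfr", "identity", 1.0, 0.3),
                CoefficientTerm("proteinuria_g_day", "identity", 0.0, -0.2),
            ]
        )
        rec = make_record(egfr=3.0, proteinuria_g_day=2.0)
        assert compute_linear_predictor(rec, cs) == pytest.approx(0.2)

    def test_additivity_over_terms(self, make_record):
        terms = [
            CoefficientTerm("proteinuria_g_day", "log", 0.34, 0.7),
            CoefficientTerm("egfr", "identity", 76.0, -0.017),
            CoefficientTerm("mest_t", "eq:2", 0.087, 1.3),
            CoefficientTerm("rasb_use", "bool", 0.337, -0.19),
        ]
        rec = make_record(proteinuria_g_day=2.3, egfr=51.0, mest_t=2, rasb_use=True)
        total = compute_linear_predictor(rec, make_set(terms))
        parts = sum(compute_linear_predictor(rec, make_set([t])) for t in terms)
        assert total == pytest.approx(parts, rel=1e-12)

    def test_missing_covariate_is_named(self, make_record):
        cs = make_set([CoefficientTerm("age_years", "identity", 22.0, 0.01)])
        rec = make_record(age_years=float("nan"))
        with pytest.raises(ValueError, match="age_years"):
            compute_linear_predictor(rec, cs)

    def test_unknown_transform_rejected(self, make_record):
        cs = make_set([CoefficientTerm("egfr", "cube-root", 0.0, 1.0)])
        with pytest.raises(ValueError, match="transform"):
            compute_linear_predictor(make_record(), cs)


class TestPredictRisk:
    def test_zero_lp_gives_baseline_risk(self, make_record, toy_coeffs):
        assert predict_risk(0.0, make_record(), toy_coeffs, 60.0) == pytest.approx(0.1)

    def test_power_transform_of_baseline(self, make_record, toy_coeffs):
        risk = predict_risk(math.log(2.0), make_record(), toy_coeffs, 60.0)
        assert risk == pytest.approx(1.0 - 0.9**2, rel=1e-12)

    def test_piecewise_race_hazard(self, make_record):
        # H0(36) = 0.1, H0(60) = 0.2
        baseline = ((0, 1.0), (36, math.exp(-0.1)), (60, math.exp(-0.2)),
                    (80, math.exp(-0.25)))
        cs = make_set(
            [CoefficientTerm("proteinuria_g_day", "log", 0.0, 0.5)],
            baseline=baseline,
            variant="with_race",
            piecewise=RacePiecewise("chinese", 36.0, 0.3, -0.2),
        )
        rec = make_record(proteinuria_g_day=1.0, race="chinese")
        expected = 1.0 - math.exp(-(0.1 * math.exp(0.3) + 0.1 * math.exp(-0.2)))
        assert predict_risk(0.0, rec, cs, 60.0) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.1950, abs=5e-4)

    def test_piecewise_inactive_for_other_races(self, make_record):
        baseline = ((0, 1.0), (36, 0.95), (60, 0.9), (80, 0.85))
        cs = make_set(
            [CoefficientTerm("proteinuria_g_day", "log", 0.0, 0.5)],
            baseline=baseline,
            variant="with_race",
            piecewise=RacePiecewise("chinese", 36.0, 0.3, -0.2),
        )
        rec = make_record(proteinuria_g_day=1.0, race="white")
        assert predict_risk(0.0, rec, cs, 60.0) == pytest.approx(0.1)

    def test_piecewise_with_equal_betas_matches_plain_formula(self, make_record):
        baseline = ((0, 1.0), (36, 0.93), (60, 0.88), (80, 0.84))
        beta = 0.4
        pw = make_set(
            [CoefficientTerm("proteinuria_g_day", "log", 0.0, 0.5)],
            baseline=baseline, variant="with_race",
            piecewise=RacePiecewise("chinese", 36.0, beta, beta),
        )
        plain = make_set(
            [CoefficientTerm("proteinuria_g_day", "log", 0.0, 0.5)],
            baseline=baseline,
        )
        rec = make_record(proteinuria_g_day=1.0, race="chinese")
        for lp in (-1.0, 0.0, 0.7):
            for h in (24.0, 36.0, 60.0, 80.0):
                assert predict_risk(lp, rec, pw, h) == pytest.approx(
                    predict_risk(lp + beta, rec, plain, h), rel=1e-10
                )

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        lp1=st.floats(-3, 3),
        lp2=st.floats(-3, 3),
        h1=st.floats(1, 80),
        h2=st.floats(1, 80),
    )
    def test_risk_monotone_in_lp_and_horizon(self, toy_coeffs, lp1, lp2, h1, h2):
        rec_kwargs = dict(
            patient_id="p", age_years=22.0, sex="male", egfr=76.0, map_mmHg=99.0,
            proteinuria_g_day=1.0, mest_m=0, mest_e=0, mest_s=0, mest_t=0,
        )
        from iganpt.risk_engine import CohortRecord

        rec = CohortRecord(**rec_kwargs)
        lo, hi = sorted((lp1, lp2))
        r_lo = predict_risk(lo, rec, toy_coeffs, 60.0)
        r_hi = predict_risk(hi, rec, toy_coeffs, 60.0)
        assert r_lo <= r_hi + 1e-12
        t_lo, t_hi = sorted((h1, h2))
        assert predict_risk(0.5, rec, toy_coeffs, t_lo) <= predict_risk(
            0.5, rec, toy_coeffs, t_hi
        ) + 1e-12

    def test_horizon_outside_span_rejected(self, make_record, toy_coeffs):
        with pytest.raises(ValueError, match="span"):
            predict_risk(0.0, make_record(), toy_coeffs, 120.0)

    def test_nonfinite_lp_rejected(self, make_record, toy_coeffs):
        with pytest.raises(ValueError):
            predict_risk(float("inf"), make_record(), toy_coeffs, 60.0)


class TestRemapNovelDrugs:
    def test_sglt2i_counts_as_rasb(self, make_record):
        rec = make_record(novel_drugs={"SGLT2i"}, rasb_use=False, is_use=False)
        out = remap_novel_drugs(rec)
        assert out.rasb_use is True
        assert out.is_use is False

    def test_empty_set_leaves_record_unchanged(self, make_record):
        rec = make_record(novel_drugs=frozenset())
        assert remap_novel_drugs(rec) == rec

    def test_telitacicept_counts_as_immunosuppressant(self, make_record):
        rec = make_record(novel_drugs={"telitacicept"}, is_use=False)
        out = remap_novel_drugs(rec)
        assert out.is_use is True
        assert out.novel_drugs == frozenset({"telitacicept"})

    def test_idempotent(self, make_record):
        rec = make_record(novel_drugs={"ERA", "Nefecon"})
        once = remap_novel_drugs(rec)
        assert remap_novel_drugs(once) == once

    def test_unknown_drug_rejected(self, make_record):
        with pytest.raises(ValueError, match="unknown novel drug"):
            make_record(novel_drugs={"aspirin"})


class TestRiskGroups:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (677, (109, 230, 229, 109)),
            (566, (91, 192, 192, 91)),
            (100, (16, 34, 34, 16)),
        ],
    )
    def test_tie_free_group_counts(self, rng, n, expected):
        lps = rng.permutation(np.linspace(-2, 2, n))
        grouping = assign_risk_groups(lps)
        counts = grouping.group_counts
        assert (
            counts["low"],
            counts["intermediate"],
            counts["higher"],
            counts["highest"],
        ) == expected

    def test_every_patient_assigned_once(self, rng):
        lps = rng.normal(size=123)
        grouping = assign_risk_groups(lps)
        assert sum(grouping.group_counts.values()) == 123
        assert len(grouping.assignments) == 123

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            assign_risk_groups([0.1, 0.2, 0.3])

    def test_degenerate_identical_lps_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            assign_risk_groups([1.0] * 10)

    def test_boundary_ties_warn(self):
        lps = np.concatenate([np.arange(50.0), np.arange(50.0)])
        with pytest.warns(UserWarning, match="ties"):
            assign_risk_groups(lps)


class TestCkdEpi:
    def test_female_at_kappa_knot(self):
        egfr = ckd_epi_egfr(61.88, 40.0, "female")
        assert egfr == pytest.approx(144.0 * 0.993**40, rel=1e-9)
        assert egfr == pytest.approx(108.7, abs=0.1)

    def test_male_at_kappa_knot(self):
        egfr = ckd_epi_egfr(79.56, 50.0, "male")
        assert egfr == pytest.approx(141.0 * 0.993**50, rel=1e-9)
        assert egfr == pytest.approx(99.3, abs=0.1)

    def test_monotone_decreasing_in_creatinine(self):
        for scr in (40.0, 70.0, 110.0, 200.0):
            assert ckd_epi_egfr(2 * scr, 45.0, "male") < ckd_epi_egfr(scr, 45.0, "male")

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            ckd_epi_egfr(0.0, 40.0, "female")
        with pytest.raises(ValueError):
            ckd_epi_egfr(80.0, -1.0, "male")


class TestCoefficientSet:
    def test_round_trip_through_dict(self, toy_coeffs):
        again = CoefficientSet.from_dict(toy_coeffs.to_dict())
        assert again == toy_coeffs

    def test_increasing_baseline_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            make_set(
                [CoefficientTerm("egfr", "identity", 76.0, -0.02)],
                baseline=((0, 1.0), (36, 0.9), (60, 0.95)),
            )

    def test_baseline_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="survival values"):
            make_set(
                [CoefficientTerm("egfr", "identity", 76.0, -0.02)],
                baseline=((0, 1.0), (60, 0.0)),
            )

    def test_variant_race_consistency_enforced(self):
        with pytest.raises(ValueError, match="race"):
            make_set(
                [CoefficientTerm("race", "eq:japanese", 0.0, 0.25)],
                variant="without_race",
            )
        with pytest.raises(ValueError, match="race"):
            make_set([CoefficientTerm("egfr", "identity", 76.0, -0.02)],
                     variant="with_race")

    def test_unknown_covariate_rejected(self):
        with pytest.raises(ValueError, match="unknown covariate"):
            make_set([CoefficientTerm("weight_kg", "identity", 70.0, 0.01)])
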