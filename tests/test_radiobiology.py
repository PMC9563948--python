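import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from lungdr.exceptions import LungDRError
from lungdr.models import RadioParams, get_model
from lungdr.radiobiology import (
    eqd2_normal_tissue,
    eqd2_tumour,
    predict_cohort_os,
    predict_stage_os,
    probit_response,
    slt_probability,
    weekday_duration,
)
from lungdr.reference import model5_reference_params

from conftest import make_cohort


class TestEqd2Tumour:
    def test_two_gray_fractions_give_physical_dose(self):
        for ab in (0.5, 3.0, 10.0, 100.0):
            assert eqd2_tumour(60, 2, alpha_beta=ab) == 60.0

    def test_hypofractionation_with_low_alpha_beta(self):
        assert eqd2_tumour(66, 3, alpha_beta=3.0) == pytest.approx(79.2)

    def test_repopulation_and_sensitisation(self):
        # 1.40 * 60 - 1.47 * (40 - 24)
        val = eqd2_tumour(60, 2, T=40, alpha_beta=32.1, lam=1.47, t_k=24,
                          rs=1.40)
        assert val == pytest.approx(60.48)

    def test_alpha_beta_domain(self):
        with pytest.raises(LungDRError, match="alpha_beta"):
            eqd2_tumour(60, 2, alpha_beta=-2.5)

    @given(D=st.floats(0, 100), d=st.floats(0, 3),
           ab=st.floats(-1.5, 50), lam=st.floats(0, 3),
           tk=st.floats(0, 47))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_dose_and_nonincreasing_in_duration(self, D, d, ab,
                                                            lam, tk):
        # dose monotonicity requires a positive fractionation numerator
        assume(ab + d > 0.01)
        lo = eqd2_tumour(D, d, 30, ab, lam, tk)
        hi = eqd2_tumour(D + 5, d, 30, ab, lam, tk)
        assert hi >= lo - 1e-9
        longer = eqd2_tumour(D, d, 50, ab, lam, tk)
        assert longer <= lo + 1e-9
        # constant before the kick-off time
        if tk >= 20:
            assert eqd2_tumour(D, d, 10, ab, lam, tk) == \
                eqd2_tumour(D, d, min(20, tk), ab, lam, tk)


class TestNormalTissueEqd2:
    @pytest.mark.parametrize("D,d,expected", [
        (60, 2, 60.0),
        (70, 2.8, 81.2),
        (0, 2, 0.0),
    ])
    def test_generic_alpha_beta_three(self, D, d, expected):
        assert eqd2_normal_tissue(D, d) == pytest.approx(expected)


class TestProbitResponse:
    def test_half_response_at_eqd50(self):
        assert probit_response(54, 54, 0.15) == pytest.approx(0.5)

    def test_one_sd_above(self):
        assert probit_response(62.1, 54, 0.15) == pytest.approx(0.8413, abs=1e-4)

    def test_deep_tail(self):
        assert probit_response(0, 54, 0.15) == pytest.approx(1.3e-11, rel=0.1)

    def test_domain_errors(self):
        with pytest.raises(LungDRError):
            probit_response(60, -1, 0.15)
        with pytest.raises(LungDRError):
            probit_response(60, 54, 0)

    def test_strictly_increasing(self):
        grid = [probit_response(x, 54, 0.15) for x in np.linspace(30, 90, 30)]
        assert all(b > a for a, b in zip(grid, grid[1:]))


class TestSltProbability:
    def test_zero_weight_means_no_toxicity(self):
        assert slt_probability(200, 54, 0.31, f_slt=0) == 0.0

    def test_half_of_weight_at_midpoint(self):
        assert slt_probability(54, 54, 0.31, 0.41) == pytest.approx(0.205)

    def test_weighted_upper_tail(self):
        assert slt_probability(74, 54, 0.31, 0.58) == pytest.approx(0.5127,
                                                                    abs=2e-4)


class TestWeekdayCalendar:
    @pytest.mark.parametrize("n,days", [(30, 40), (37, 51), (1, 1), (5, 5),
                                        (6, 8), (20, 26)])
    def test_five_fractions_per_week(self, n, days):
        assert weekday_duration(n) == days


class TestPrediction:
    def test_rt_alone_at_eqd50(self):
        # probit at 0 times the fixed 85% ceiling
        c = make_cohort(treatment="RT", publication_year=2016)
        p = RadioParams(alpha_beta=10.0, lam=0.0, t_k=20.0, m=0.3,
                        eqd2_tum50={s: 60.0 for s in ("I", "II", "IIIA", "IIIB")},
                        rs=1.0, os_max=91.0, eqd2_nt50=1e6, m_nt=0.01,
                        r_year=0.0, f_slt={s: 1.0 for s in ("I", "II", "IIIA", "IIIB")})
        spec = get_model("model5")
        assert predict_stage_os(c, "IIIA", p, spec) == pytest.approx(0.425,
                                                                     abs=1e-6)

    def test_full_model_stage_iiib_concurrent(self):
        c = make_cohort(treatment="cCRT", publication_year=2016)
        val = predict_stage_os(c, "IIIB", model5_reference_params(),
                               get_model("model5"), y=0.0)
        assert val == pytest.approx(0.4510, abs=2e-4)

    def test_model1_reduces_to_pure_probit(self):
        c = make_cohort(treatment="cCRT")
        p = RadioParams(alpha_beta=4.0, lam=0.64, t_k=33.0, m=0.72,
                        eqd2_tum50={s: 74.0 for s in ("I", "II", "IIIA", "IIIB")})
        spec1 = get_model("model1")
        expected = probit_response(
            eqd2_tumour(c.dose_gy, c.dose_per_fraction_gy, c.duration_days,
                        4.0, 0.64, 33.0, rs=1.0), 74.0, 0.72)
        assert predict_stage_os(c, "IIIA", p, spec1) == pytest.approx(expected)

    def test_cohort_prediction_is_stage_mixture(self):
        p = model5_reference_params()
        spec = get_model("model5")
        pure_a = make_cohort(treatment="sCRT")
        pure_b = make_cohort(stage_fractions={"I": 0, "II": 0, "IIIA": 0,
                                              "IIIB": 1.0}, treatment="sCRT")
        mixed = make_cohort(stage_fractions={"I": 0, "II": 0, "IIIA": 0.5,
                                             "IIIB": 0.5}, treatment="sCRT")
        osa = predict_cohort_os(pure_a, p, spec)
        osb = predict_cohort_os(pure_b, p, spec)
        osm = predict_cohort_os(mixed, p, spec)
        assert osa == pytest.approx(
            100 * predict_stage_os(pure_a, "IIIA", p, spec))
        assert osm == pytest.approx(0.5 * (osa + osb))
        assert min(osa, osb) - 1e-9 <= osm <= max(osa, osb) + 1e-9

    def test_model_family_degenerations(self, default_dataset):
        """Full-model predictions collapse to the nested models when the
        extra structure is switched off."""
        stages = ("I", "II", "IIIA", "IIIB")
        p5 = RadioParams(alpha_beta=3.0, lam=0.40, t_k=25.0, m=0.28,
                         eqd2_tum50={"I": 48.0, "II": 48.0, "IIIA": 49.0,
                                     "IIIB": 61.0},
                         rs=1.11, os_max=93.0, eqd2_nt50=96.0, m_nt=0.60,
                         r_year=0.016, f_slt={s: 1.0 for s in stages})
        p2 = RadioParams(alpha_beta=3.0, lam=0.40, t_k=25.0, m=0.28,
                         eqd2_tum50={"I": 48.0, "II": 48.0, "IIIA": 49.0,
                                     "IIIB": 61.0},
                         rs=1.11, os_max=93.0, eqd2_nt50=96.0, m_nt=0.60,
                         r_year=0.016)
        spec5, spec2, spec1 = (get_model(n) for n in
                               ("model5", "model2", "model1"))
        for c in default_dataset[:10]:
            assert predict_cohort_os(c, p5, spec5) == pytest.approx(
                predict_cohort_os(c, p2, spec2), rel=1e-12)
        # removing RS, OS_max, SLT and R reduces the chemo model to the probit
        p2_off = RadioParams(alpha_beta=3.0, lam=0.40, t_k=25.0, m=0.28,
                             eqd2_tum50={"I": 48.0, "II": 48.0, "IIIA": 49.0,
                                         "IIIB": 61.0},
                             rs=1.0, os_max=100.0, eqd2_nt50=1e9, m_nt=0.01,
                             r_year=0.0)
        p1 = RadioParams(alpha_beta=3.0, lam=0.40, t_k=25.0, m=0.28,
                         eqd2_tum50={"I": 48.0, "II": 48.0, "IIIA": 49.0,
                                     "IIIB": 61.0})
        for c in default_dataset[:10]:
            # the RT-alone ceiling stays fixed at 85% in the chemo-era models
            scale = 0.85 if c.treatment == "RT" else 1.0
            assert predict_cohort_os(c, p2_off, spec2) == pytest.approx(
                scale * predict_cohort_os(c, p1, spec1), rel=1e-12)
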