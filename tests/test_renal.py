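"""Renal-function estimators, BSA, and the CKD-EPI inverse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import carbodose as cd
from carbodose.renal import read_cohort_csv, write_cohort_csv


class TestCockcroftGault:
    def test_hand_arithmetic(self):
        # (140−60)·70/(72·0.8) = 97.222; ×0.85 for women
        assert cd.cockcroft_gault(60, 70, 0.8, "female") == pytest.approx(82.639, abs=1e-3)
        assert cd.cockcroft_gault(60, 70, 0.8, "male") == pytest.approx(97.222, abs=1e-3)

    def test_high_creatinine_limit(self):
        assert cd.cockcroft_gault(60, 70, 1e6, "male") < 1e-3

    def test_validation(self):
        with pytest.raises(ValueError):
            cd.cockcroft_gault(60, 70, 0.0, "female")
        with pytest.raises(ValueError):
            cd.cockcroft_gault(150, 70, 0.8, "female")
        with pytest.raises(ValueError):
            cd.cockcroft_gault(60, 70, 0.8, "other")


class TestCkdEpi:
    @pytest.mark.parametrize("version", [2009, 2021])
    @pytest.mark.parametrize("sex,kappa", [("female", 0.7), ("male", 0.9)])
    def test_piecewise_knot_continuity(self, version, sex, kappa):
        eps = 1e-9
        lo = cd.ckd_epi(kappa - eps, 50, sex, version)
        hi = cd.ckd_epi(kappa + eps, 50, sex, version)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_knot_value_is_intercept_times_decay(self):
        # at scr == kappa both power terms are 1
        v = cd.ckd_epi(0.7, 40, "female", 2021)
        assert v == pytest.approx(142 * 0.9938**40 * 1.012, rel=1e-12)

    def test_strictly_decreasing_in_creatinine(self):
        scr = np.linspace(0.3, 3.0, 50)
        vals = [cd.ckd_epi(s, 55, "female") for s in scr]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_version_validation(self):
        with pytest.raises(ValueError):
            cd.ckd_epi(0.8, 50, "female", version=2015)


class TestInvertCkdEpi:
    @pytest.mark.parametrize("version", [2009, 2021])
    @pytest.mark.parametrize("sex", ["female", "male"])
    @pytest.mark.parametrize("age", [30.0, 55.0, 75.0])
    @pytest.mark.parametrize("scr", [0.45, 0.7, 0.9, 1.3, 2.5])
    def test_roundtrip_identity(self, version, sex, age, scr):
        egfr = cd.ckd_epi(scr, age, sex, version)
        assert cd.invert_ckd_epi(egfr, age, sex, version) == pytest.approx(scr, abs=1e-9)

    @pytest.mark.parametrize("age,sex,egfr", [(40.0, "female", 95.0), (60.0, "male", 70.0), (70.0, "female", 110.0)])
    def test_matches_bisection_oracle(self, age, sex, egfr):
        scr_oracle = brentq(
            lambda s: cd.ckd_epi(s, age, sex) - egfr, 1e-3, 20.0, xtol=1e-12
        )
        assert cd.invert_ckd_epi(egfr, age, sex) == pytest.approx(scr_oracle, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cd.invert_ckd_epi(0.0, 50, "female")
        with pytest.raises(ValueError):
            cd.invert_ckd_epi(500.0, 50, "female")


class TestBsa:
    def test_mosteller_hand_values(self):
        assert cd.bsa(170, 65, "mosteller") == pytest.approx(np.sqrt(11050 / 3600), rel=1e-12)
        assert cd.bsa(60, 60, "mosteller") == pytest.approx(1.0, abs=1e-12)

    def test_dubois_close_to_mosteller(self):
        assert cd.bsa(170, 65, "dubois") == pytest.approx(1.7533, abs=1e-3)
        assert abs(cd.bsa(170, 65, "dubois") - cd.bsa(170, 65, "mosteller")) < 0.01

    def test_methods_agree_over_adult_range(self):
        """Transcription guard: the two formulas track each other — within
        3% for typical adult builds, and within 8% even at the extreme
        height/weight corners where they genuinely diverge."""
        for w in np.linspace(45, 110, 12):
            for h in np.linspace(145, 190, 12):
                m, d = cd.bsa(h, w, "mosteller"), cd.bsa(h, w, "dubois")
                assert abs(m - d) / m < 0.08
                bmi = w / (h / 100) ** 2
                if 150 <= h <= 185 and 18.5 <= bmi <= 28:
                    assert abs(m - d) / m < 0.03

    def test_validation(self):
        with pytest.raises(ValueError):
            cd.bsa(0, 60)
        with pytest.raises(ValueError):
            cd.bsa(170, 65, "boyd")


class TestBsaReadjust:
    def test_identity_at_reference_bsa(self):
        assert cd.bsa_readjust_egfr(100.0, 1.73) == pytest.approx(100.0)

    def test_hand_value(self):
        assert cd.bsa_readjust_egfr(98.3, 1.60) == pytest.approx(90.91, abs=5e-3)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cd.bsa_readjust_egfr(98.3, 0.0)


@settings(derandomize=True, max_examples=60)
@given(
    age=st.floats(20, 90),
    weight=st.floats(40, 120),
    scr=st.floats(0.3, 4.0),
    dscr=st.floats(0.05, 1.0),
    dw=st.floats(1.0, 30.0),
)
def test_estimator_monotonicity(age, weight, scr, dscr, dw):
    """CrCL and eGFR strictly decrease in creatinine; CrCL increases in weight."""
    assert cd.cockcroft_gault(age, weight, scr + dscr, "female") < cd.cockcroft_gault(
        age, weight, scr, "female"
    )
    assert cd.cockcroft_gault(age, weight + dw, scr, "female") > cd.cockcroft_gault(
        age, weight, scr, "female"
    )
    assert cd.ckd_epi(scr + dscr, age, "male") < cd.ckd_epi(scr, age, "male")


class TestCohortCsv:
    def test_umol_conversion_and_derived_columns(self, tmp_path):
        p = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "id": ["p1"],
                "sex": ["female"],
                "age": [60.0],
                "weight_kg": [70.0],
                "height_cm": [160.0],
                "scr": [0.8 * 88.4],
                "scr_unit": ["umol/L"],
                "target_auc": [5.0],
            }
        ).to_csv(p, index=False)
        df = read_cohort_csv(p)
        assert df.loc[0, "scr"] == pytest.approx(0.8)
        assert df.loc[0, "crcl"] == pytest.approx(cd.cockcroft_gault(60, 70, 0.8, "female"))
        assert df.loc[0, "egfr_absolute"] == pytest.approx(
            cd.bsa_readjust_egfr(df.loc[0, "egfr_normalized"], df.loc[0, "bsa"])
        )

    def test_precomputed_metrics_taken_verbatim(self, tmp_path):
        p = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "id": ["p1"],
                "target_auc": [6.0],
                "crcl": [88.0],
                "egfr_normalized": [95.0],
                "bsa": [1.6],
            }
        ).to_csv(p, index=False)
        df = read_cohort_csv(p)
        assert df.loc[0, "crcl"] == 88.0
        assert df.loc[0, "egfr_absolute"] == pytest.approx(95.0 * 1.6 / 1.73)

    def test_write_read_roundtrip(self, tmp_path, cohort_biased):
        p = tmp_path / "cohort.csv"
        write_cohort_csv(cohort_biased, p)
        back = read_cohort_csv(p)
        assert len(back) == len(cohort_biased)
        np.testing.assert_allclose(
            back["egfr_absolute"], cohort_biased["egfr_absolute"], rtol=1e-9
        )
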