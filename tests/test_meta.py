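"""Meta-analysis: uncertainty harmonization and random-effects pooling.

Reference values for the pooling machinery come from two independent
routes: hand inverse-variance arithmetic, and R metafor 4.8-0 run on the
same inputs (values frozen below).  statsmodels' combine_effects provides
a third, in-suite cross-check of the DerSimonian–Laird path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carbodose as cd
from carbodose.meta import PoolingConfig, pool_random_effects, to_standard_error


def se(study_id, parameter, estimate, unc, kind, n=None):
    return cd.StudyEstimate(study_id, parameter, estimate, unc, kind, n)


CL_ROWS = [
    se("ref1", "CL", 8.33, 19.1, "RSE_percent"),
    se("ref2", "CL", 6.99, 0.74, "SE"),
    se("ref3", "CL", 8.38, 1.41, "RSE_percent"),
]
TOY = [se("a", "CL", 1.0, 0.5, "SE"), se("b", "CL", 3.0, 0.5, "SE")]


@pytest.mark.parametrize(
    "est,unc,kind,scale,expected",
    [
        (8.33, 19.1, "RSE_percent", "linear", 8.33 * 0.191),
        (6.99, 0.74, "SE", "linear", 0.74),
        (8.38, 1.41, "RSE_percent", "log", 0.0141),
    ],
)
def test_to_standard_error_harmonization(est, unc, kind, scale, expected):
    e = se("s", "CL", est, unc, kind)
    assert to_standard_error(e, scale) == pytest.approx(expected, rel=1e-12)


def test_to_standard_error_sd_over_sqrt_n_scaling():
    e = se("s", "CL", 8.33, 19.1, "RSE_percent", n=25)
    assert to_standard_error(e, "linear", "sd_over_sqrt_n") == pytest.approx(
        8.33 * 0.191 / 5.0
    )
    # assumed_n used when the study table carries no N
    e2 = se("s", "CL", 8.33, 19.1, "RSE_percent")
    assert to_standard_error(
        e2, "linear", "sd_over_sqrt_n", assumed_n=100
    ) == pytest.approx(8.33 * 0.191 / 10.0)


def test_study_estimate_validation():
    with pytest.raises(ValueError):
        se("s", "CL", -1.0, 1.0, "SE")
    with pytest.raises(ValueError):
        se("s", "CL", 1.0, 0.0, "SE")
    with pytest.raises(ValueError):
        se("s", "XX", 1.0, 1.0, "SE")


def test_dl_toy_matches_hand_arithmetic_and_metafor():
    """Two studies (1 ± 0.5, 3 ± 0.5): FE weights 4/4 give mean 2,
    Q = 4·1 + 4·1 = 8, I² = 87.5%, τ²_DL = (8−1)/(8−32/8) = 1.75.
    CI frozen from an independent metafor run on the same input."""
    r = pool_random_effects(TOY, scale="linear", tau2_method="DL")
    assert r.estimate == pytest.approx(2.0, abs=1e-12)
    assert r.Q_stat == pytest.approx(8.0, abs=1e-12)
    assert r.I2_percent == pytest.approx(87.5, abs=1e-12)
    assert r.tau2 == pytest.approx(1.75, abs=1e-12)
    assert r.ci95_low == pytest.approx(0.040036, abs=1e-5)
    assert r.ci95_high == pytest.approx(3.959964, abs=1e-5)


def test_dl_three_study_brute_force_oracle():
    """DL path vs a from-scratch inverse-variance computation, 1e-12."""
    rows = [
        se("a", "V1", 2.0, 0.4, "SE"),
        se("b", "V1", 5.0, 1.0, "SE"),
        se("c", "V1", 3.5, 0.7, "SE"),
    ]
    y = np.array([2.0, 5.0, 3.5])
    s2 = np.array([0.4, 1.0, 0.7]) ** 2
    w = 1 / s2
    mu_fe = (w * y).sum() / w.sum()
    Q = (w * (y - mu_fe) ** 2).sum()
    C = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - 2) / C)
    wr = 1 / (s2 + tau2)
    mu_re = (wr * y).sum() / wr.sum()
    r = pool_random_effects(rows, scale="linear", tau2_method="DL")
    assert r.estimate == pytest.approx(mu_re, abs=1e-12)
    assert r.tau2 == pytest.approx(tau2, abs=1e-12)
    assert r.Q_stat == pytest.approx(Q, abs=1e-12)


def test_dl_cross_check_against_statsmodels():
    from statsmodels.stats.meta_analysis import combine_effects

    y = np.array([e.estimate for e in CL_ROWS])
    v = np.array([to_standard_error(e, "linear") for e in CL_ROWS]) ** 2
    sm = combine_effects(y, v, method_re="chi2")  # chi2 == DerSimonian–Laird
    r = pool_random_effects(CL_ROWS, scale="linear", tau2_method="DL")
    assert r.tau2 == pytest.approx(sm.tau2, rel=1e-10)
    smf = sm.summary_frame()
    assert r.estimate == pytest.approx(smf.loc["random effect", "eff"], rel=1e-10)


def test_linear_dl_matches_frozen_metafor_values():
    r = pool_random_effects(CL_ROWS, scale="linear", tau2_method="DL")
    assert r.estimate == pytest.approx(8.014598, abs=1e-6)
    assert r.tau2 == pytest.approx(0.33285083, abs=1e-7)
    assert r.Q_stat == pytest.approx(3.440680, abs=1e-6)


def test_reml_sdn_matches_frozen_metafor_values():
    """REML under the SD/√N construction vs metafor rma(method='REML')."""
    cfg = PoolingConfig("linear", "REML", "sd_over_sqrt_n", assumed_n=100)
    r = pool_random_effects(CL_ROWS, cfg.scale, cfg.tau2_method, cfg.se_mode, cfg.assumed_n)
    assert r.estimate == pytest.approx(7.896935, abs=1e-5)
    assert r.tau2 == pytest.approx(0.61726773, rel=1e-4)
    assert r.ci95_low == pytest.approx(7.000628, abs=1e-4)
    assert r.ci95_high == pytest.approx(8.793243, abs=1e-4)


def test_identical_studies_are_homogeneous():
    rows = [se(f"s{i}", "CL", 5.0, 0.5, "SE") for i in range(3)]
    r = pool_random_effects(rows, scale="linear", tau2_method="DL")
    assert r.estimate == pytest.approx(5.0, abs=1e-12)
    assert r.Q_stat == pytest.approx(0.0, abs=1e-12)
    assert r.I2_percent == 0.0
    assert r.tau2 == 0.0


def test_single_study_passthrough():
    r = pool_random_effects([se("only", "Q", 1.22, 2.7, "SE")])
    assert r.estimate == 1.22
    assert r.k_studies == 1
    assert r.tau2 == 0.0
    assert r.I2_percent is None
    assert r.ci95_low < 1.22 < r.ci95_high


def test_pooling_input_validation():
    with pytest.raises(ValueError):
        pool_random_effects([])
    with pytest.raises(ValueError):
        pool_random_effects([se("a", "CL", 1, 0.1, "SE"), se("b", "V1", 1, 0.1, "SE")])


def test_log_pooling_of_equal_cv_studies_is_geometric_mean():
    rows = [se(f"s{i}", "CL", v, 10.0, "RSE_percent") for i, v in enumerate([2.0, 8.0, 4.0])]
    for method in ("DL", "REML"):
        r = pool_random_effects(rows, scale="log", tau2_method=method)
        assert r.estimate == pytest.approx((2.0 * 8.0 * 4.0) ** (1 / 3), rel=1e-9)


def test_dominant_tau2_recovers_unweighted_mean():
    """As within-study variances vanish (huge N), RE weights equalize and
    the pooled mean converges to the plain study average."""
    cfg = PoolingConfig("linear", "DL", "sd_over_sqrt_n", assumed_n=10**6)
    r = pool_random_effects(CL_ROWS, cfg.scale, cfg.tau2_method, cfg.se_mode, cfg.assumed_n)
    assert r.estimate == pytest.approx(np.mean([8.33, 6.99, 8.38]), rel=1e-4)


@settings(derandomize=True, max_examples=50)
@given(
    vals=st.lists(st.floats(0.5, 50.0), min_size=2, max_size=6),
    rses=st.lists(st.floats(1.0, 60.0), min_size=6, max_size=6),
    scale=st.sampled_from(["linear", "log"]),
    method=st.sampled_from(["DL", "REML"]),
)
def test_pooled_estimate_convex_in_study_estimates(vals, rses, scale, method):
    rows = [
        se(f"s{i}", "CL", v, r, "RSE_percent")
        for i, (v, r) in enumerate(zip(vals, rses))
    ]
    pooled = pool_random_effects(rows, scale=scale, tau2_method=method)
    assert min(vals) - 1e-9 <= pooled.estimate <= max(vals) + 1e-9


@pytest.mark.parametrize("Q,df,expected", [(8.0, 1, 87.5), (3.0, 3, 0.0), (0.5, 1, 0.0), (0.0, 2, 0.0)])
def test_heterogeneity_i2(Q, df, expected):
    assert cd.heterogeneity(Q, df) == pytest.approx(expected)


def test_heterogeneity_rejects_negative_q():
    with pytest.raises(ValueError):
        cd.heterogeneity(-1.0, 1)


def test_standardize_units_exact_factors():
    s = cd.standardize_units(7.91, 15.39, 0.12, 0.18)
    assert round(s.cl_ml_min, 1) == 131.8  # 7.91 · 1000/60
    assert s.v1_l == 15.39
    assert s.k12_per_min == pytest.approx(0.002, abs=5e-5)
    assert s.k21_per_min == pytest.approx(0.003, abs=5e-5)
    with pytest.raises(ValueError):
        cd.standardize_units(0.0, 15.39, 0.12, 0.18)


def test_pool_study_table_passthrough_and_set(pooled_all):
    pset, pooled = pooled_all
    # single-study parameters pass through un-pooled and stay out of the set
    assert pooled["V2"].k_studies == 1 and pooled["Q"].k_studies == 1
    assert pooled["K12"].k_studies == 2 and pooled["CL"].k_studies == 3
    assert pset.cl_ml_min == pytest.approx(pooled["CL"].estimate * 1000 / 60)
    assert pset.k21_per_min == pytest.approx(pooled["K21"].estimate / 60)


def test_parameter_set_json_roundtrip(tmp_path, pset):
    p = tmp_path / "pooled.json"
    pset.to_json(p)
    back = cd.PooledParameterSet.from_json(p)
    assert back == pset
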