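"""Correlation, partial correlation, t-tests, and report generation."""

import math

import numpy as np
import pandas as pd
import pytest

from coherograph import (
    independent_t_test,
    partial_correlation,
    pearson,
    render_report,
    validation_report,
)
from coherograph.stats import StatsInputError, read_clinical_table


def test_pearson_perfect_line():
    x = [1.0, 2.0, 5.0, 7.0]
    res = pearson(x, [2 * v + 1 for v in x])
    assert res.r == pytest.approx(1.0, abs=1e-12)
    assert res.n == 4


def test_pearson_hand_computed_fixture():
    # r = cov / (sd_x sd_y) with x=(1,2,3), y=(1,2,4): cov=1, sd_x=sqrt(2/3),
    # sd_y=sqrt(14)/3 -> r = 3/sqrt(2*14/3) ... = 0.98198...
    expected = 1.0 / (math.sqrt(2.0 / 3.0) * math.sqrt(14.0) / 3.0)
    res = pearson([1, 2, 3], [1, 2, 4])
    assert res.r == pytest.approx(expected, abs=1e-9)
    assert res.p == pytest.approx(0.121037718, abs=1e-6)


def test_pearson_degenerate_inputs():
    with pytest.raises(StatsInputError, match="'y'"):
        pearson([1, 2, 3], [5, 5, 5], name_x="x", name_y="y")
    with pytest.raises(StatsInputError, match="n >= 3"):
        pearson([1, 2], [1, 2])


def test_pearson_pairwise_complete_and_symmetry():
    x = [1.0, 2.0, np.nan, 4.0, 5.0]
    y = [2.0, 1.0, 3.0, np.nan, 5.0]
    res = pearson(x, y)
    assert res.n == 3
    assert res.r == pytest.approx(pearson(y, x).r, abs=1e-15)
    # invariance under positive affine transforms
    res2 = pearson([3 * v + 2 if np.isfinite(v) else v for v in x], y)
    assert res2.r == pytest.approx(res.r, abs=1e-12)


def test_partial_with_no_controls_reduces_to_pearson():
    rng = np.random.default_rng(1)
    x, y = rng.standard_normal(30), rng.standard_normal(30)
    assert partial_correlation(x, y, []).r == pearson(x, y).r


def _oracle_partial_inverse_corr(x, y, controls):
    """Independent oracle: partial r from the inverse correlation matrix."""
    mat = np.column_stack([x, y] + controls)
    prec = np.linalg.inv(np.corrcoef(mat, rowvar=False))
    return -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])


def test_partial_matches_inverse_matrix_oracle():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n, k = int(rng.integers(10, 60)), int(rng.integers(1, 4))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        controls = [rng.standard_normal(n) for _ in range(k)]
        res = partial_correlation(x, y, controls)
        assert res.r == pytest.approx(
            _oracle_partial_inverse_corr(x, y, controls), abs=1e-9
        )


def test_partial_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "x": rng.standard_normal(40),
            "y": rng.standard_normal(40),
            "c1": rng.standard_normal(40),
            "c2": rng.standard_normal(40),
        }
    )
    res = partial_correlation(df["x"], df["y"], [df["c1"], df["c2"]])
    pg = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    assert res.r == pytest.approx(float(pg["r"].iloc[0]), abs=1e-9)
    assert res.p == pytest.approx(float(pg["p_val"].iloc[0]), abs=1e-9)


def test_partial_removes_confounded_association():
    """y driven by a control, x independent: raw r inflated by chance or
    confounding, partial r near zero."""
    rng = np.random.default_rng(4)
    n = 400
    c = rng.standard_normal(n)
    y = c + 0.1 * rng.standard_normal(n)
    x = 0.8 * c + rng.standard_normal(n)  # x also loads on c -> raw r inflated
    raw = pearson(x, y).r
    part = partial_correlation(x, y, [c]).r
    assert abs(raw) > 0.4
    assert abs(part) < 0.12


def test_partial_converges_to_raw_with_irrelevant_controls():
    rng = np.random.default_rng(5)
    n = 2000
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    controls = [rng.standard_normal(n), rng.standard_normal(n)]
    assert partial_correlation(x, y, controls).r == pytest.approx(
        pearson(x, y).r, abs=0.01
    )


def test_partial_collinear_controls_error():
    rng = np.random.default_rng(6)
    c = rng.standard_normal(30)
    with pytest.raises(StatsInputError, match="collinear"):
        partial_correlation(
            rng.standard_normal(30), rng.standard_normal(30), [c, 2 * c]
        )


def test_partial_needs_enough_cases():
    with pytest.raises(StatsInputError, match="n > k"):
        partial_correlation(
            [1, 2, 3, 4], [1, 2, 3, 5], [[1, 0, 1, 0], [0, 2, 1, 3]]
        )


# --- t-tests ----------------------------------------------------------------


def test_t_test_identical_groups():
    res = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)


def test_t_test_zero_variance_degenerate():
    with pytest.raises(StatsInputError, match="zero variance"):
        independent_t_test([0.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
    with pytest.raises(StatsInputError, match="at least 2"):
        independent_t_test([1.0], [1.0, 2.0])


def test_t_test_pooled_matches_textbook_formula():
    a = [4.0, 5.0, 6.0, 9.0]
    b = [1.0, 2.0, 2.0, 3.0, 4.0]
    res = independent_t_test(a, b, equal_var=True)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    sp2 = (ssa + ssb) / (na + nb - 2)
    t_expected = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    assert res.t == pytest.approx(t_expected, abs=1e-9)
    assert res.df == na + nb - 2
    # Welch (default) gives a different df for unequal variances
    welch = independent_t_test(a, b)
    assert welch.df != res.df


# --- report generation ------------------------------------------------------


def _toy_tables(n=120, rho=0.5, seed=10):
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    scores = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "local_m1": latent + 0.3 * rng.standard_normal(n),
            "global_m1": latent + 0.3 * rng.standard_normal(n),
            "word_count": rng.integers(60, 800, n).astype(float),
        }
    )
    out = rho * latent + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    clinical = pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "panss_negative": 15 + 6 * out,
            "panss_negative_t2": 15 + 6 * (0.7 * out + 0.3 * rng.standard_normal(n)),
            "mini_icf_sum": np.full(n, np.nan),  # all-missing outcome
            "age": rng.normal(40, 10, n),
            "sex": np.where(rng.random(n) < 0.6, "male", "female"),
            "medication": rng.random(n) < 0.85,
        }
    )
    return scores, clinical


def test_validation_report_recovers_known_correlation():
    scores, clinical = _toy_tables()
    bundle = validation_report(scores, clinical)
    row = bundle.correlations.query(
        "variable == 'panss_negative' and score == 'local_m1'"
    )
    # generative r between score and outcome: rho attenuated by score noise
    assert float(row["r"].iloc[0]) == pytest.approx(0.48, abs=0.12)
    assert int(row["n"].iloc[0]) == 120
    # self-correlation cells are exactly 1
    self_row = bundle.correlations.query("variable == 'local_m1' and score == 'local_m1'")
    assert float(self_row["r"].iloc[0]) == 1.0


def test_validation_report_missing_column_and_tables():
    scores, clinical = _toy_tables()
    bundle = validation_report(scores, clinical)
    icf = bundle.correlations.query("variable == 'mini_icf_sum'")
    assert len(icf) == 2  # column present for both scores
    assert icf["r"].isna().all()
    # longitudinal partial correlations control for the T1 outcome
    assert set(bundle.partial_longitudinal["outcome"]) == {"panss_negative_t2"}
    assert (bundle.partial_longitudinal["controls"] == "panss_negative").all()
    # t-tests for both categorical covariates and both scores
    assert set(bundle.t_tests["variable"]) == {"sex", "medication"}
    assert len(bundle.t_tests) == 4
    # control screen includes transcript length
    assert "word_count" in set(bundle.controls_screen["variable"])


def test_validation_report_join_mismatches_reported():
    scores, clinical = _toy_tables(n=20)
    clinical = clinical.iloc[:15]
    scores = pd.concat(
        [scores, pd.DataFrame({"participant_id": ["ONLY"], "local_m1": [0.5],
                               "global_m1": [0.5], "word_count": [100.0]})],
        ignore_index=True,
    )
    bundle = validation_report(scores, clinical)
    assert bundle.join_report["n_joined"] == 15
    assert "ONLY" in bundle.join_report["scores_only"]
    assert len(bundle.join_report["clinical_only"]) == 0


def test_render_report_banner_and_stars():
    scores, clinical = _toy_tables()
    text = render_report(validation_report(scores, clinical))
    assert "descriptive" in text
    assert "multiple testing" in text
    assert "*" in text  # rho=0.5 at n=120 is comfortably starred


def test_read_clinical_table_validates(tmp_path):
    path = tmp_path / "clin.csv"
    path.write_text(
        "participant_id,inpatient_days_0_5y_before\nP1,-3\n", encoding="utf-8"
    )
    with pytest.raises(StatsInputError, match="negative day count"):
        read_clinical_table(path)
    ok = tmp_path / "ok.csv"
    ok.write_text("participant_id,panss_negative\nP1,12\nP2,20\n", encoding="utf-8")
    df = read_clinical_table(ok)
    assert list(df["participant_id"]) == ["P1", "P2"]
    with pytest.raises(StatsInputError, match="range"):
        read_clinical_table(ok, panss_range=(5, 15))
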