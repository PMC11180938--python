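import dataclasses
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

import periconnect as pc


# ---------------------------------------------------------------------------
# one-sample tests against 1


def test_one_sample_symmetric_around_unity():
    r = pc.one_sample_vs_unity([0.9, 1.0, 1.1])
    assert r.estimate == pytest.approx(1.0)
    assert r.statistic == pytest.approx(0.0)
    assert r.p == pytest.approx(1.0)


def test_one_sample_zero_variance_is_degenerate():
    r = pc.one_sample_vs_unity([0.95] * 10)
    assert r.degenerate
    assert r.estimate == pytest.approx(0.95)


def test_one_sample_t_statistic_matches_hand_formula():
    rng = np.random.default_rng(12)
    x = rng.normal(0.975, 0.035, size=20)
    r = pc.one_sample_vs_unity(x)
    expected_t = (x.mean() - 1.0) / (x.std(ddof=1) / math.sqrt(20))
    assert r.method == "t"
    assert r.statistic == pytest.approx(expected_t, rel=1e-12)


def test_one_sample_nonnormal_data_routes_to_signed_rank():
    rng = np.random.default_rng(5)
    x = 1.0 + rng.lognormal(0, 1, size=60)  # heavily skewed: fails Shapiro-Wilk
    r = pc.one_sample_vs_unity(x)
    assert r.method == "wilcoxon"
    assert r.normality_p < 0.05


# ---------------------------------------------------------------------------
# group comparisons


def test_group_compare_exact_shift_with_zero_variance():
    vals = np.array([1.0] * 5 + [1.04] * 5 + [1.0] * 5)
    grp = np.array(["CN"] * 5 + ["MCI"] * 5 + ["AD"] * 5)
    overall, pairwise = pc.group_compare(vals, grp)
    row = pairwise.set_index(["group_a", "group_b"]).loc[("CN", "MCI")]
    assert row["mean_difference"] == pytest.approx(-0.04)


def test_group_compare_null_case_recovers_no_difference():
    rng = np.random.default_rng(0)
    vals = rng.normal(0.95, 0.03, size=300)
    grp = np.array(["AD"] * 100 + ["MCI"] * 100 + ["CN"] * 100)
    overall, pairwise = pc.group_compare(vals, grp)
    assert overall.p > 0.001
    assert np.abs(pairwise["mean_difference"]).max() < 0.02


def test_group_compare_recovers_planted_sv2a_difference():
    """MCI-CN SV2A ratio difference of -0.04 recovered across replicates."""
    diffs = []
    for i in range(100):
        rng = np.random.default_rng(1000 + i)
        cn = rng.normal(0.952, 0.03, size=21)
        mci = rng.normal(0.912, 0.03, size=27)
        ad = rng.normal(0.912, 0.03, size=59)
        vals = np.concatenate([ad, mci, cn])
        grp = np.array(["AD"] * 59 + ["MCI"] * 27 + ["CN"] * 21)
        _, pairwise = pc.group_compare(vals, grp)
        row = pairwise.set_index(["group_a", "group_b"]).loc[("MCI", "CN")]
        diffs.append(row["mean_difference"])
    assert np.mean(diffs) == pytest.approx(-0.04, abs=0.005)


def test_group_with_single_subject_is_dropped():
    vals = np.array([1.0, 1.1, 0.9, 1.05, 0.97])
    grp = np.array(["AD", "AD", "AD", "AD", "CN"])
    with pytest.warns(RuntimeWarning):
        with pytest.raises(ValueError):
            pc.group_compare(vals, grp)


# ---------------------------------------------------------------------------
# adjusted regression


def test_regression_exact_recovery_without_noise():
    model = pc.CognitionModel(residual_sd=0.0)
    cohort = pc.make_cohort(pc.PhantomConfig(seed=6, cognition_model=model))
    res = pc.adjusted_regression(cohort.table, "score", "ratio_abeta")
    assert res.estimate == pytest.approx(-37.8, abs=1e-8)


def test_regression_closed_form_simple_design():
    # 4-point design, no covariates: slope = cov(x, y) / var(x)
    df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "y": [1.0, 3.0, 5.0, 6.0]})
    res = pc.adjusted_regression(df, "y", "x", covariates=())
    x, y = df["x"], df["y"]
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert res.estimate == pytest.approx(slope, rel=1e-12)


def test_regression_collinear_design_is_flagged():
    df = pd.DataFrame({
        "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "age": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0],  # exactly 2x
    })
    res = pc.adjusted_regression(df, "y", "x", covariates=("age",))
    assert res.degenerate


def test_regression_subgroup_restriction():
    cohort = pc.make_cohort(pc.PhantomConfig(seed=8))
    t = cohort.table
    res = pc.adjusted_regression(t, "score", "ratio_abeta", subgroup=t["group"] == "MCI")
    assert res.n == 27


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos, i in enumerate(order):
        j_range = range(rank_pos, m)
        adj[i] = min(min((m / (j + 1)) * p[order[j]] for j in j_range), 1.0)
    return adj


def test_bh_worked_example_and_single_p():
    np.testing.assert_allclose(pc.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(pc.bh_adjust([0.37]), [0.37])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_bh_matches_brute_force_and_statsmodels(pvals):
    p = np.asarray(pvals)
    ours = pc.bh_adjust(p)
    np.testing.assert_allclose(ours, brute_force_bh(p), atol=1e-12)
    sm_adj = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, sm_adj, atol=1e-12)
    assert (ours >= p - 1e-15).all()


# ---------------------------------------------------------------------------
# longitudinal


def test_standardization_anchors_and_worked_example():
    baseline = np.array([16.3, 21.4, 26.5])  # mean 21.4, SD 5.1
    month12 = np.array([19.6, 21.4, 26.5])
    zb, zf, mean_b, sd_b = pc.standardize_longitudinal(baseline, month12)
    assert mean_b == pytest.approx(21.4)
    assert sd_b == pytest.approx(5.1)
    assert zb.mean() == pytest.approx(0.0, abs=1e-12)
    assert zb.std(ddof=1) == pytest.approx(1.0)
    assert zf[0] == pytest.approx((19.6 - 21.4) / 5.1)
    # identical follow-up maps to identical z-scores
    zb2, zf2, *_ = pc.standardize_longitudinal(baseline, baseline)
    np.testing.assert_allclose(zb2, zf2)


def test_standardization_zero_sd_raises():
    with pytest.raises(ValueError):
        pc.standardize_longitudinal(np.ones(5), np.ones(5))


def test_paired_change_identity_and_constant_shift():
    base = np.array([0.97, 0.95, 0.99, 0.96])
    same = pc.paired_change_test(base, base)
    assert same.estimate == 0.0 and same.p == pytest.approx(1.0)
    shifted = pc.paired_change_test(base, base - 0.03)
    assert shifted.degenerate
    assert shifted.estimate == pytest.approx(-0.03)


def test_paired_t_equals_rm_anova_f():
    """Two-timepoint repeated-measures ANOVA reduces to the paired t (F = t^2)."""
    rng = np.random.default_rng(21)
    n = 23
    base = rng.normal(0.976, 0.034, n)
    m12 = base + rng.normal(-0.033, 0.02, n)
    ours = pc.paired_change_test(base, m12)
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "time": np.repeat(["t0", "t1"], n),
        "y": np.concatenate([base, m12]),
    })
    aov = pg.rm_anova(data=long, dv="y", within="time", subject="subject")
    assert aov["F"].iloc[0] == pytest.approx(ours.statistic**2, rel=1e-9)
    assert aov["p_unc"].iloc[0] == pytest.approx(ours.p, rel=1e-9)


def test_slope_comparison_trivial_cases():
    zb = np.array([0.0, 1.0, -1.0, 0.5])
    same = pc.slope_comparison(zb, zb - 0.5, zb, zb - 0.5)
    assert same.estimate == 0.0 and same.p == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    drop = zb - 0.5 + rng.normal(0, 0.01, 4)
    faster = pc.slope_comparison(zb, drop, zb, zb)
    assert faster.estimate < 0  # ratio declining, MMSE flat -> negative d


def test_one_sample_type_one_error_is_calibrated():
    """Null N(1, 0.035^2) ratios: rejection rate near the nominal 5%."""
    rng = np.random.default_rng(99)
    x = rng.normal(1.0, 0.035, size=(2000, 59))
    rejections = sum(pc.one_sample_vs_unity(row).p < 0.05 for row in x)
    assert 0.03 <= rejections / 2000 <= 0.07
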