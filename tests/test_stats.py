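"""Interaction regressions, worked count predictions, correlation and
group tests — each checked against an independent textbook oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import rohscape as rs


def ols_oracle(y, X):
    """Normal equations + classical t-based inference, written independently."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), n - k)
    return beta, se, t, p


def _stack(f0, g0, f1, g1):
    y = np.concatenate([f0, f1])
    g = np.concatenate([g0, g1])
    d = np.concatenate([np.zeros(len(f0)), np.ones(len(f1))])
    return y, np.column_stack([np.ones_like(g), g, d, g * d])


def test_identical_groups_zero_interaction():
    g = np.linspace(0.05, 0.4, 10)
    f = 0.2 + 0.5 * g
    fit = rs.fit_interaction_model(f, g, f, g)
    assert fit.beta[2] == pytest.approx(0.0, abs=1e-12)
    assert fit.beta[3] == pytest.approx(0.0, abs=1e-12)


def test_noiseless_exact_recovery():
    g = np.linspace(0.0, 0.5, 12)
    f0 = 0.1 + 0.8 * g
    f1 = 0.1 + 1.1 * g
    fit = rs.fit_interaction_model(f0, g, f1, g)
    assert fit.beta == pytest.approx([0.1, 0.8, 0.0, 0.3], rel=1e-10, abs=1e-10)


def test_ols_oracle_agreement_random_fixture():
    rng = np.random.default_rng(3)
    g0 = rng.uniform(0, 0.5, 20)
    g1 = rng.uniform(0, 0.5, 25)
    f0 = 0.1 + 0.9 * g0 + rng.normal(0, 0.03, 20)
    f1 = 0.15 + 1.3 * g1 + rng.normal(0, 0.03, 25)
    fit = rs.fit_interaction_model(f0, g0, f1, g1)
    beta, se, t, p = ols_oracle(*_stack(f0, g0, f1, g1))
    assert fit.beta == pytest.approx(beta, abs=1e-10)
    assert fit.se == pytest.approx(se, abs=1e-10)
    assert fit.t == pytest.approx(t, abs=1e-8)
    assert fit.p == pytest.approx(p, abs=1e-10)


def test_missing_values_dropped_and_rank_check():
    g = np.linspace(0.05, 0.4, 10)
    f = 0.2 + 0.5 * g
    f_nan = f.copy()
    f_nan[3] = np.nan
    fit = rs.fit_interaction_model(f_nan, g, f, g)
    assert fit.n == 19 and fit.n_dropped == 1
    with pytest.raises(ValueError, match="rank"):
        rs.fit_interaction_model(f, np.full(10, 0.2), f, np.full(10, 0.2))


def test_pairwise_sizeclass_pairings_and_direction():
    """Three pairings; with built-in slopes decreasing from M to L, the
    L-vs-M interaction comes out negative."""
    g = {c: np.linspace(0.01, 0.3, 15) for c in ("S", "M", "L")}
    f = {
        "S": 0.05 + 1.0 * g["S"],
        "M": 0.05 + 1.2 * g["M"],
        "L": 0.05 + 0.8 * g["L"],
    }
    fits = rs.pairwise_sizeclass_model(f, g)
    assert set(fits) == {("L", "M"), ("L", "S"), ("M", "S")}
    assert fits[("L", "M")].beta[3] == pytest.approx(-0.4, abs=1e-10)
    assert fits[("M", "S")].beta[3] == pytest.approx(0.2, abs=1e-10)
    same = rs.pairwise_sizeclass_model({c: f["M"] for c in f}, {c: g["M"] for c in g})
    assert same[("L", "S")].beta[3] == pytest.approx(0.0, abs=1e-12)


def test_predict_counts_worked_examples():
    pred = rs.predict_counts(1568.76, -57.63, -98.67, 693.63, 0.10)
    assert pred.change_in == 157
    assert pred.change_out == -10
    assert pred.net == 147
    assert pred.baseline == 694


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.floats(-3000, 3000, allow_nan=False),
    st.floats(-3000, 3000, allow_nan=False),
    st.floats(0.01, 0.5, allow_nan=False),
)
def test_predict_counts_rounding_consistency(slope_in, slope_out, dg):
    pred = rs.predict_counts(slope_in, 0.0, slope_out, 0.0, dg)
    rounded = rs.predict_counts(slope_in, 0.0, slope_out, 0.0, dg, net_from_rounded=True)
    assert rounded.net == pred.change_in + pred.change_out
    # the two conventions differ by at most one count
    assert abs(pred.net - rounded.net) <= 1


def test_pearson_exact_line_and_oracle():
    x = np.arange(10, dtype=float)
    r, p = rs.pearson_with_test(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    rng = np.random.default_rng(8)
    a = rng.normal(size=40)
    b = 0.4 * a + rng.normal(size=40)
    r, p = rs.pearson_with_test(a, b)
    # textbook formulas
    r_exp = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
        np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
    )
    t_exp = r_exp * np.sqrt((len(a) - 2) / (1 - r_exp**2))
    p_exp = 2 * sps.t.sf(abs(t_exp), len(a) - 2)
    assert r == pytest.approx(r_exp, abs=1e-12)
    assert p == pytest.approx(p_exp, abs=1e-12)
    assert np.isnan(rs.pearson_with_test(np.ones(5), np.arange(5))[0])


def test_pearson_null_calibration():
    """Independent pairs: r near zero and p roughly uniform over replicates."""
    rng = np.random.default_rng(9)
    rs_, ps = [], []
    for _ in range(200):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        r, p = rs.pearson_with_test(x, y)
        rs_.append(r)
        ps.append(p)
    assert abs(np.mean(rs_)) < 0.03
    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01
    r1000, _ = rs.pearson_with_test(rng.normal(size=1000), rng.normal(size=1000))
    assert abs(r1000) < 0.1


def test_split_low_high_cutoff():
    import pandas as pd

    prof = pd.DataFrame({"sample": list("abc"), "G_R": [0.05, 0.35, 0.20]})
    groups = rs.split_low_high(prof)
    assert groups.set_index("sample")["group"].tolist() == ["low", "high", "high"]


def test_breed_ttest_oracle_and_degenerate():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    t, p = rs.breed_ttest(a, a)
    assert (t, p) == (0.0, 1.0)
    assert rs.breed_ttest([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    rng = np.random.default_rng(10)
    x = rng.normal(0, 1, 12)
    y = rng.normal(1, 2, 17)
    t, p = rs.breed_ttest(x, y)
    # Welch formulas
    v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t_exp = (x.mean() - y.mean()) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
    p_exp = 2 * sps.t.sf(abs(t_exp), df)
    assert t == pytest.approx(t_exp, abs=1e-12)
    assert p == pytest.approx(p_exp, abs=1e-12)


def test_breed_ttest_power_tracks_analytic():
    """Two groups with a 3-unit mean difference (sd 3, n 15/30): empirical
    rejection rate matches noncentral-t power within Monte-Carlo error."""
    rng = np.random.default_rng(12)
    n1, n2, sd, delta, n_rep = 15, 30, 3.0, 3.0, 400
    rej = 0
    for _ in range(n_rep):
        t, p = rs.breed_ttest(rng.normal(0, sd, n1), rng.normal(delta, sd, n2))
        rej += p < 0.05
    se_term = np.sqrt(sd**2 / n1 + sd**2 / n2)
    df = se_term**4 / ((sd**2 / n1) ** 2 / (n1 - 1) + (sd**2 / n2) ** 2 / (n2 - 1))
    nc = delta / se_term
    crit = sps.t.ppf(0.975, df)
    power = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
    mc_se = np.sqrt(power * (1 - power) / n_rep)
    assert rej / n_rep == pytest.approx(power, abs=4 * mc_se + 0.01)
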