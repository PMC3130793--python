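"""Balanced factorial ANOVA, adjusted-df significance, residuals, correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phytocosm.anova import (
    adjusted_df_test,
    balanced_anova,
    pearson_r,
    treatment_residuals,
)


def _frame(y, **factors):
    d = {k: v for k, v in factors.items()}
    d["y"] = y
    return pd.DataFrame(d)


def test_one_way_two_groups_hand_computed():
    data = _frame([1, 2, 3, 4, 5, 6], g=["a"] * 3 + ["b"] * 3)
    tab = balanced_anova(data, "y", ["g"])
    row = tab["g"]
    assert row.df == 1
    assert tab.error_df == 4
    assert row.ss == pytest.approx(13.5)
    assert tab.error_ss == pytest.approx(4.0)
    assert row.f == pytest.approx(13.5)


def test_equal_cell_means_give_zero_f():
    data = _frame(
        [5.0, 7.0] * 4,
        a=["x", "x", "x", "x", "y", "y", "y", "y"],
        b=["u", "u", "v", "v"] * 2,
    )
    tab = balanced_anova(data, "y", ["a", "b"])
    for row in tab.rows:
        assert row.f == pytest.approx(0.0, abs=1e-12)


def test_interaction_df_three_by_six():
    rng = np.random.default_rng(0)
    p = np.repeat(["I", "III", "V"], 18)
    comp = np.tile(np.repeat(list("ABCDEF"), 3), 3)
    data = _frame(rng.normal(size=54), p=p, comp=comp)
    tab = balanced_anova(data, "y", ["p", "comp"])
    assert tab["p*comp"].df == 10
    assert tab.error_df == 36


def test_unbalanced_design_rejected():
    data = _frame([1, 2, 3, 4, 5], g=["a", "a", "a", "b", "b"])
    with pytest.raises(ValueError, match="unbalanced"):
        balanced_anova(data, "y", ["g"])
    missing_cell = _frame(
        [1, 2, 3, 4], a=["x", "x", "y", "y"], b=["u", "v", "u", "u"]
    )
    with pytest.raises(ValueError):
        balanced_anova(missing_cell, "y", ["a", "b"])


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_one_way_f_is_square_of_pooled_t(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=12)
    data = _frame(y, g=["a"] * 6 + ["b"] * 6)
    tab = balanced_anova(data, "y", ["g"])
    t, _ = stats.ttest_ind(y[:6], y[6:])
    assert tab["g"].f == pytest.approx(t**2, rel=1e-9)


@pytest.mark.parametrize("n_factors", [2, 3])
def test_anova_cross_checked_against_statsmodels(n_factors):
    """SS and F of every term agree with an OLS fit (independent route)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(7)
    levels = [("I", "III", "V"), ("lo", "mid", "hi"), tuple("ABCDEF")][:n_factors]
    grids = np.meshgrid(*[np.arange(len(l)) for l in levels], indexing="ij")
    reps = 3
    cols = {}
    for name, lv, g in zip("abc", levels, grids):
        cols[name] = np.repeat([lv[i] for i in g.ravel()], reps)
    n = len(next(iter(cols.values())))
    data = pd.DataFrame(cols)
    data["y"] = rng.normal(size=n) + (data["a"] == "I") * 1.5
    factors = list(cols)
    tab = balanced_anova(data, "y", factors)
    formula = "y ~ " + " * ".join(f"C({f})" for f in factors)
    sm_tab = sm.stats.anova_lm(ols(formula, data=data).fit(), typ=2)
    for row in tab.rows:
        sm_name = ":".join(f"C({f})" for f in row.term.split("*"))
        assert row.ss == pytest.approx(sm_tab.loc[sm_name, "sum_sq"], rel=1e-8)
        assert row.f == pytest.approx(sm_tab.loc[sm_name, "F"], rel=1e-8)
        assert row.df == int(sm_tab.loc[sm_name, "df"])
    assert tab.error_ss == pytest.approx(sm_tab.loc["Residual", "sum_sq"], rel=1e-8)
    assert tab.error_df == int(sm_tab.loc["Residual", "df"])


def test_ss_decomposition_is_complete():
    rng = np.random.default_rng(3)
    data = _frame(
        rng.normal(size=36),
        a=np.repeat(["x", "y", "z"], 12),
        b=np.tile(np.repeat(["u", "v"], 6), 3),
    )
    tab = balanced_anova(data, "y", ["a", "b"])
    assert sum(r.ss for r in tab.rows) + tab.error_ss == pytest.approx(
        tab.total_ss, rel=1e-9
    )
    assert sum(r.df for r in tab.rows) + tab.error_df == tab.n_obs - 1


# ---------------------------------------------------------------------------
# adjusted df
# ---------------------------------------------------------------------------

def test_adjusted_df_critical_value():
    res = adjusted_df_test(5.5, df_num=1, df_err=30)
    assert res.df_adj == pytest.approx(10.0)
    assert res.f_crit == pytest.approx(4.9646, abs=1e-3)
    assert res.significant
    assert not adjusted_df_test(4.9, 1, 30).significant


def test_adjusted_df_below_one_is_untestable():
    with pytest.raises(ValueError):
        adjusted_df_test(100.0, 1, 2)


@settings(deadline=None, max_examples=100)
@given(
    f=st.floats(min_value=0.1, max_value=50),
    df_num=st.integers(1, 10),
    df_err=st.integers(3, 120),
)
def test_adjustment_is_strictly_conservative(f, df_num, df_err):
    """Significance under df/3 implies significance under the full df."""
    adj = adjusted_df_test(f, df_num, df_err, adjustment=3.0)
    full = adjusted_df_test(f, df_num, df_err, adjustment=1.0)
    if adj.significant:
        assert full.significant
    assert adj.f_crit >= full.f_crit


# ---------------------------------------------------------------------------
# residuals and correlation
# ---------------------------------------------------------------------------

def test_treatment_residuals_remove_cell_means():
    data = _frame([10.0, 12.0, 3.0, 5.0], g=["a", "a", "b", "b"])
    res = treatment_residuals(data, "y", ["g"])
    np.testing.assert_allclose(res, [-1.0, 1.0, -1.0, 1.0])
    # residuals sum to zero within each cell; constant shifts cancel
    shifted = data.copy()
    shifted.loc[shifted["g"] == "a", "y"] += 100.0
    np.testing.assert_allclose(
        treatment_residuals(shifted, "y", ["g"]), res, atol=1e-12
    )


def test_singleton_cells_warn_and_zero():
    data = _frame([1.0, 2.0], g=["a", "b"])
    with pytest.warns(UserWarning):
        res = treatment_residuals(data, "y", ["g"])
    np.testing.assert_allclose(res, [0.0, 0.0])


def test_pearson_r_perfect_and_null():
    x = np.arange(10.0)
    res = pearson_r(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    noise = pearson_r(rng.normal(size=2000), rng.normal(size=2000))
    assert abs(noise.r) < 0.06


def test_pearson_r_t_transform_consistency():
    """r = 0.47 with n = 15 corresponds to p ~ 0.077 via the t transform."""
    # build a vector pair with exactly the requested correlation
    n, r = 15, 0.47
    rng = np.random.default_rng(1)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    # orthogonalise then mix to the exact r
    x = (x - x.mean()) / x.std()
    y = y - y.mean()
    y -= x * (x @ y) / (x @ x)
    y /= y.std()
    mixed = r * x + np.sqrt(1 - r**2) * y
    res = pearson_r(x, mixed)
    assert res.r == pytest.approx(r, abs=1e-12)
    assert res.p == pytest.approx(0.077, abs=2e-3)


def test_pearson_r_errors():
    with pytest.raises(ValueError):
        pearson_r([1.0, 2.0], [3.0, 4.0])
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
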