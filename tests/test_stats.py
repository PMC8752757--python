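"""Oracle and property tests for the statistical kernel.

Every test statistic is checked against an independent hand-rolled oracle
(closed form, sum-of-squares decomposition, or exhaustive enumeration) on
small instances.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hgscreen.stats import (
    bh_fdr,
    fisher_exact_2x2,
    hypergeom_tail,
    km_estimator,
    logrank_test,
    one_way_anova,
    pearson_r,
    quantile_normalize,
    student_t,
    tumor_volume,
)

TOL = 1e-9


# ---------------------------------------------------------------------- t-test

def pooled_t_oracle(x, y):
    """Closed-form pooled-variance Student t."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


def test_student_t_matches_closed_form():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = student_t(x, y)
    t, df, p = pooled_t_oracle(x, y)
    assert res.statistic == pytest.approx(-3 * math.sqrt(1.5), abs=TOL)
    assert res.statistic == pytest.approx(t, abs=TOL)
    assert res.df == df == 4
    assert res.p_value == pytest.approx(p, abs=TOL)


def test_student_t_identical_groups_and_symmetry(rng):
    res = student_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_value == 1.0
    x, y = rng.normal(size=8), rng.normal(size=6)
    a = student_t(x, y)
    b = student_t(rng.permutation(x), rng.permutation(y))
    assert a.statistic == pytest.approx(b.statistic, abs=TOL)
    assert a.p_value == pytest.approx(b.p_value, abs=TOL)


def test_student_t_degenerate_variance():
    assert student_t([2, 2, 2], [2, 2]).p_value == 1.0
    with pytest.warns(RuntimeWarning):
        res = student_t([1, 1, 1], [2, 2, 2])
    assert res.p_value == 0.0


def test_welch_differs_from_pooled_on_unequal_variances(rng):
    x = rng.normal(0, 0.2, size=5)
    y = rng.normal(0, 5.0, size=20)
    assert student_t(x, y).p_value != pytest.approx(
        student_t(x, y, welch=True).p_value, abs=1e-12)


# ----------------------------------------------------------------------- ANOVA

def anova_oracle(groups):
    """Between/within sum-of-squares decomposition by hand."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfn = len(groups) - 1
    dfd = len(all_vals) - len(groups)
    f = (ss_between / dfn) / (ss_within / dfd)
    return f, sps.f.sf(f, dfn, dfd)


def test_anova_matches_ss_decomposition():
    groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 5.5], [7.0, 8.0]]
    res = one_way_anova(groups)
    f, p = anova_oracle(groups)
    assert res.statistic == pytest.approx(f, abs=TOL)
    assert res.p_value == pytest.approx(p, abs=TOL)


def test_anova_two_groups_equals_t_squared(rng):
    x, y = rng.normal(size=7), rng.normal(size=9)
    f = one_way_anova([x, y]).statistic
    t = student_t(x, y).statistic
    assert f == pytest.approx(t ** 2, rel=1e-9)


def test_anova_constant_groups_and_singleton_dropping():
    assert one_way_anova([[3, 3], [3, 3, 3]]).p_value == 1.0
    # singleton group dropped; result equals the two remaining groups
    with_singleton = one_way_anova([[1, 2, 3], [9.0], [4, 5, 6]])
    without = one_way_anova([[1, 2, 3], [4, 5, 6]])
    assert with_singleton.statistic == pytest.approx(without.statistic, abs=TOL)
    with pytest.raises(ValueError):
        one_way_anova([[1, 2, 3], [9.0]])


# --------------------------------------------------------------------- Pearson

def test_pearson_matches_definition():
    x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
    y = np.array([0.5, 1.1, 2.0, 3.9, 5.2])
    res = pearson_r(x, y)
    r = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    t = r * math.sqrt((len(x) - 2) / (1 - r ** 2))
    p = 2 * sps.t.sf(abs(t), len(x) - 2)
    assert res.statistic == pytest.approx(r, abs=TOL)
    assert res.p_value == pytest.approx(p, abs=TOL)


def test_pearson_affine_extremes():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_r(x, 2 * x + 1).statistic == pytest.approx(1.0, abs=TOL)
    assert pearson_r(x, -x).statistic == pytest.approx(-1.0, abs=TOL)
    with pytest.raises(ValueError):
        pearson_r(x, np.ones_like(x))


# -------------------------------------------------------------------------- BH

def bh_oracle(p):
    """Step-up BH by hand."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        q[idx] = prev
    return q


def test_bh_hand_examples():
    out = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out.q, [0.04, 0.04, 0.04, 0.04], atol=TOL)
    assert bh_fdr([0.2]).q[0] == pytest.approx(0.2)


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_bh_matches_oracle_and_bounds(p):
    out = bh_fdr(p)
    assert np.allclose(out.q, bh_oracle(p), atol=TOL)
    assert np.all(out.q >= out.raw_p - TOL)
    assert np.all(out.q <= 1.0 + TOL)


def test_bh_monotone_in_raw_p(rng):
    p = rng.uniform(size=12)
    q0 = bh_fdr(p).q
    p2 = p.copy()
    p2[3] = min(1.0, p2[3] + 0.2)
    q1 = bh_fdr(p2).q
    assert np.all(q1 >= q0 - TOL)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ----------------------------------------------------------------- Kaplan-Meier

def test_km_product_limit_by_hand():
    curve = km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
    assert curve(0.5) == pytest.approx(1.0)
    assert curve(1.0) == pytest.approx(2 / 3, abs=TOL)
    assert curve(2.5) == pytest.approx(1 / 3, abs=TOL)
    assert curve(3.0) == pytest.approx(0.0, abs=TOL)


def test_km_no_events_and_duplication_invariance(rng):
    t = rng.exponential(10, size=20)
    all_censored = km_estimator(t, np.zeros(20, int))
    assert np.allclose(all_censored(np.linspace(0, 30, 7)), 1.0)
    e = (rng.random(20) < 0.7).astype(int)
    single = km_estimator(t, e)
    double = km_estimator(np.r_[t, t], np.r_[e, e])
    grid = np.linspace(0, float(t.max()), 13)
    assert np.allclose(single(grid), double(grid), atol=TOL)


def test_km_censoring_reduces_risk_set_without_step():
    # censor at 1.5: S steps only at event times 1 and 3
    curve = km_estimator([1.0, 1.5, 3.0], [1, 0, 1])
    assert curve(1.0) == pytest.approx(2 / 3, abs=TOL)
    assert curve(2.0) == pytest.approx(2 / 3, abs=TOL)  # censoring: no step
    assert curve(3.0) == pytest.approx(0.0, abs=TOL)
    with pytest.raises(ValueError):
        km_estimator([], [])


# --------------------------------------------------------------------- logrank

def logrank_oracle(time, event, group):
    """Per-event-time O-E tabulation with tie-aware hypergeometric variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return chi2, sps.chi2.sf(chi2, 1)


def test_logrank_matches_tabulation_oracle():
    # 6-subject worked example with a tie at t=2
    time = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    event = [1, 1, 1, 0, 1, 1]
    group = [0, 1, 0, 1, 1, 0]
    res = logrank_test(time, event, group)
    chi2, p = logrank_oracle(time, event, group)
    assert res.statistic == pytest.approx(chi2, abs=TOL)
    assert res.p_value == pytest.approx(p, abs=TOL)


def test_logrank_identical_groups_and_label_symmetry(rng):
    t = rng.exponential(5, size=10)
    e = (rng.random(10) < 0.8).astype(int)
    dup = logrank_test(np.r_[t, t], np.r_[e, e], np.r_[np.zeros(10), np.ones(10)])
    assert dup.statistic == pytest.approx(0.0, abs=1e-12)
    assert dup.p_value == pytest.approx(1.0)
    g = (rng.random(10) < 0.5).astype(int)
    g[:2] = [0, 1]
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic, abs=TOL)


def test_logrank_no_events_warns_p1():
    with pytest.warns(RuntimeWarning):
        res = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
    assert res.p_value == 1.0


# ---------------------------------------------------------------------- Fisher

def fisher_oracle(a, b, c, d):
    """Two-sided p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = lambda x: (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)
    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


@pytest.mark.parametrize("table", [(8, 2, 1, 5), (1, 1, 1, 1), (3, 7, 9, 2),
                                   (0, 5, 6, 3), (10, 0, 2, 8)])
def test_fisher_matches_enumeration(table):
    res = fisher_exact_2x2(*table)
    assert res.p_value == pytest.approx(fisher_oracle(*table), abs=TOL)


def test_fisher_transpose_invariance_and_or():
    a = fisher_exact_2x2(8, 2, 1, 5)
    b = fisher_exact_2x2(8, 1, 2, 5)  # transpose
    assert a.p_value == pytest.approx(b.p_value, abs=TOL)
    assert a.effect == pytest.approx((8 * 5) / (2 * 1))
    # Haldane correction on zero cell
    z = fisher_exact_2x2(0, 5, 6, 3)
    assert z.effect == pytest.approx((0.5 * 3.5) / (5.5 * 6.5))
    with pytest.raises(ValueError):
        fisher_exact_2x2(0, 0, 3, 4)


# ----------------------------------------------------------------- hypergeom

def hypergeom_enumeration(overlap, set_size, universe, draws):
    """P(X >= overlap) by exhaustive enumeration of all draw subsets."""
    items = range(universe)
    special = set(range(set_size))
    hits = total = 0
    for combo in itertools.combinations(items, draws):
        total += 1
        if len(special.intersection(combo)) >= overlap:
            hits += 1
    return hits / total


@pytest.mark.parametrize("args", [(4, 4, 10, 5), (0, 4, 10, 5), (2, 3, 8, 4)])
def test_hypergeom_matches_enumeration(args):
    assert hypergeom_tail(*args) == pytest.approx(hypergeom_enumeration(*args), abs=TOL)


def test_hypergeom_monotone_and_validation():
    ps = [hypergeom_tail(k, 4, 10, 5) for k in range(5)]
    assert ps[0] == 1.0
    assert all(ps[i] >= ps[i + 1] for i in range(4))
    with pytest.raises(ValueError):
        hypergeom_tail(5, 4, 10, 5)


# ----------------------------------------------------- quantile normalization

def test_quantile_normalize_rank_mean_by_hand():
    m = pd.DataFrame({"s1": [1.0, 3.0], "s2": [2.0, 4.0]})
    out = quantile_normalize(m)
    assert np.allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])


def test_quantile_normalize_fixed_point_and_idempotence(rng):
    same = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
    assert np.allclose(quantile_normalize(same), same)
    # tie-free input: idempotence and exact distribution equality hold
    m = pd.DataFrame(rng.normal(20, 4, size=(40, 4)))
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    assert np.allclose(once, twice, atol=TOL)
    # equalized column distributions, exactly
    sorted_cols = np.sort(once.to_numpy(), axis=0)
    assert np.allclose(sorted_cols, sorted_cols[:, [0] * 4], atol=TOL)
    # within-column rank order preserved
    for c in m.columns:
        assert (m[c].rank(method="average") == once[c].rank(method="average")).all()


def test_quantile_normalize_ties_get_mean_rank_value():
    m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 9.0]})
    out = quantile_normalize(m)
    # tied pair in column a shares the mean of rank-1 and rank-2 values
    assert out.loc[0, "a"] == pytest.approx(out.loc[1, "a"])
    rank_means = np.sort(m.to_numpy(), axis=0).mean(axis=1)
    assert out.loc[0, "a"] == pytest.approx(rank_means[:2].mean())


def test_quantile_normalize_single_column_warns_identity():
    m = pd.DataFrame({"only": [3.0, 1.0, 2.0]})
    with pytest.warns(RuntimeWarning):
        out = quantile_normalize(m)
    assert np.allclose(out, m)


# ---------------------------------------------------------------- tumor volume

def test_tumor_volume():
    assert tumor_volume(10, 6) == pytest.approx(180.0)
    assert tumor_volume(2, 2) == pytest.approx(4.0)
    assert tumor_volume(7.2, 5.1) == pytest.approx(0.5 * 7.2 * 5.1 ** 2, abs=TOL)
    with pytest.raises(ValueError):
        tumor_volume(5.0, 6.0)
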