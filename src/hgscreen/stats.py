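"""Shared statistical kernel.

Every hypothesis test and matrix transform used by the pipeline lives here,
with a uniform :class:`TestResult` return type, explicit degenerate-input
behaviour, and conservative input validation.  Implementations delegate to
scipy / statsmodels / lifelines where those provide the canonical form of
the test; edge cases (zero variance, zero-event cohorts, single-column
matrices) are resolved here so downstream modules never see a NaN.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "KaplanMeierCurve",
    "student_t",
    "one_way_anova",
    "pearson_r",
    "bh_fdr",
    "km_estimator",
    "logrank_test",
    "fisher_exact_2x2",
    "hypergeom_tail",
    "quantile_normalize",
    "tumor_volume",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``effect`` holds the test-specific effect measure: difference of means
    (t), F (ANOVA), r (Pearson), chi-square omitted (log-rank), odds ratio
    (Fisher).  ``df`` is absent (None) for exact tests.
    """

    statistic: float
    p_value: float
    df: Optional[float] = None
    effect: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class AdjustedPValues:
    raw_p: np.ndarray
    q: np.ndarray


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def student_t(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TestResult:
    """Unpaired two-sample t-test, two-sided.

    Pooled-variance (Student) form by default; Welch form when ``welch``.
    Zero variance in both groups yields statistic 0 / p 1 when the means are
    equal, and p 0 with a warning when they differ.
    """
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    effect = float(np.mean(x) - np.mean(y))
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if effect == 0.0:
            return TestResult(0.0, 1.0, df=float(len(x) + len(y) - 2), effect=0.0)
        warnings.warn("zero variance with unequal means: p set to 0", RuntimeWarning)
        stat = np.inf if effect > 0 else -np.inf
        return TestResult(stat, 0.0, df=float(len(x) + len(y) - 2), effect=effect)
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(float(res.statistic), float(res.pvalue), df=float(res.df), effect=effect)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across ≥ 2 groups; singleton groups are dropped."""
    usable = []
    for i, g in enumerate(groups):
        g = _as_1d(g, f"group {i}")
        if len(g) < 2:
            logger.info("one_way_anova: dropping group %d with %d sample(s)", i, len(g))
            continue
        usable.append(g)
    if len(usable) < 2:
        raise ValueError("fewer than 2 groups with >= 2 samples")
    pooled = np.concatenate(usable)
    dfn = float(len(usable) - 1)
    dfd = float(len(pooled) - len(usable))
    if np.ptp(pooled) == 0.0:
        return TestResult(0.0, 1.0, df=dfn, effect=0.0)
    f, p = sps.f_oneway(*usable)
    return TestResult(float(f), float(p), df=dfn, effect=float(f))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with two-sided p via the t transform."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), float(p), df=float(len(x) - 2), effect=float(r))


def bh_fdr(p: Sequence[float]) -> AdjustedPValues:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    raw = np.asarray(p, dtype=float).ravel()
    if raw.size == 0:
        return AdjustedPValues(raw, raw.copy())
    if np.any(~np.isfinite(raw)) or np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(raw, method="fdr_bh")[1]
    return AdjustedPValues(raw, q)


class KaplanMeierCurve:
    """Right-continuous non-increasing product-limit survival estimate.

    Callable: ``curve(t)`` evaluates S(t); ``curve.table`` holds the step
    times, survival probabilities and numbers at risk.
    """

    def __init__(self, time: Sequence[float], event: Sequence[int]):
        time = _as_1d(time, "time")
        event = np.asarray(event, dtype=int).ravel()
        if time.size == 0:
            raise ValueError("empty survival input")
        if time.size != event.size:
            raise ValueError("time and event must have equal length")
        if np.any(time < 0):
            raise ValueError("negative times")
        kmf = KaplanMeierFitter()
        kmf.fit(time, event_observed=event)
        self._kmf = kmf
        sf = kmf.survival_function_
        ev = kmf.event_table
        self.table = pd.DataFrame(
            {
                "time": sf.index.to_numpy(dtype=float),
                "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                "at_risk": ev["at_risk"].reindex(sf.index).to_numpy(dtype=float),
            }
        )
        self.n = int(time.size)

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = self._kmf.survival_function_at_times(t).to_numpy(dtype=float)
        return out if out.size > 1 else out

    def at_risk(self, t) -> np.ndarray:
        """Number of subjects still at risk just before each requested time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ev = self._kmf.event_table
        entry_times = ev.index.to_numpy(dtype=float)
        removed = ev["removed"].to_numpy(dtype=float)
        return np.array([self.n - removed[entry_times < ti].sum() for ti in t])


def km_estimator(time: Sequence[float], event: Sequence[int]) -> KaplanMeierCurve:
    """Kaplan–Meier product-limit estimator (censoring shrinks the risk set
    without a step)."""
    return KaplanMeierCurve(time, event)


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence[int]
) -> TestResult:
    """Two-sample log-rank test (1-df chi-square, tie-aware hypergeometric
    variance)."""
    time = _as_1d(time, "time")
    event = np.asarray(event, dtype=int).ravel()
    group = np.asarray(group).ravel()
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 groups, got {labels.size}")
    a = group == labels[0]
    if event.sum() == 0:
        warnings.warn("no events in either group: log-rank p set to 1", RuntimeWarning)
        return TestResult(0.0, 1.0, df=1.0)
    res = _ll_logrank(time[a], time[~a], event_observed_A=event[a], event_observed_B=event[~a])
    return TestResult(float(res.test_statistic), float(res.p_value), df=1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Fisher exact test on [[a, b], [c, d]]; two-sided p sums all tables with
    point probability ≤ the observed one.  The odds ratio uses a Haldane 0.5
    continuity correction whenever a cell is zero."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.round(cells)):
        raise ValueError("cells must be non-negative integers")
    a, b, c, d = (int(v) for v in cells)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        oddsr = (a * d) / (b * c)
    return TestResult(float(oddsr), float(min(p, 1.0)), df=None, effect=float(oddsr))


def hypergeom_tail(overlap: int, set_size: int, universe: int, draws: int) -> float:
    """Upper-tail P(X >= overlap) for overlap of a size-``draws`` sample with a
    size-``set_size`` set inside ``universe`` items."""
    for name, v in [("overlap", overlap), ("set_size", set_size),
                    ("universe", universe), ("draws", draws)]:
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if not (overlap <= min(set_size, draws) <= universe) or set_size > universe or draws > universe:
        raise ValueError("inconsistent hypergeometric counts")
    return float(sps.hypergeom.sf(overlap - 1, universe, set_size, draws))


def quantile_normalize(matrix) -> pd.DataFrame:
    """Force every column to share the distribution of across-column rank
    means.  Ties within a column receive the mean of their rank values.
    Accepts a DataFrame or 2-D array; returns a DataFrame."""
    df = pd.DataFrame(matrix).astype(float)
    if df.isna().any().any() or not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("matrix must be finite")
    if (df.to_numpy() < 0).any():
        raise ValueError("matrix must be non-negative")
    if df.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is the identity",
                      RuntimeWarning)
        return df.copy()
    rank_means = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    ranks = df.rank(method="average").to_numpy()  # 1-based, ties averaged
    n = df.shape[0]
    out = np.interp(ranks, np.arange(1, n + 1), rank_means)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def tumor_volume(a: float, b: float) -> float:
    """Ellipsoid xenograft volume 0.5 * a * b**2 (a = long diameter, b = short
    diameter, both mm; result mm^3)."""
    if b <= 0:
        raise ValueError("diameters must be positive")
    if b > a:
        raise ValueError("short diameter b exceeds long diameter a")
    return 0.5 * float(a) * float(b) ** 2
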