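"""Expression cut-point survival analysis.

Splits a cohort into low/high expression groups at candidate quantiles
(by default 30/50/70% high), runs a log-rank test per split, and reports
the most significant split together with every per-fraction result — the
scan is a post-hoc selection and its optimism must stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import KaplanMeierCurve, TestResult, bh_fdr, km_estimator, logrank_test

DEFAULT_FRACTIONS = (0.3, 0.5, 0.7)

SURVIVAL_COLUMNS = ["sample_id", "time", "event", "expr"]


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SURVIVAL_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing column(s): {missing}")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    if cohort["time"].isna().any() or (cohort["time"] < 0).any():
        raise ValueError("times must be present and non-negative")
    if not np.all(np.isfinite(cohort["expr"].to_numpy(dtype=float))):
        raise ValueError("expression values must be finite")
    return cohort


def quantile_split(cohort: pd.DataFrame, high_fraction: float) -> pd.Series:
    """Label the round-half-up(high_fraction * n) highest-expressing samples
    'high' and the rest 'low'.

    Ties are resolved by a stable sort on (expr, sample_id), so the split is
    deterministic under row permutation.  A 425-sample cohort at
    high_fraction 0.3 yields exactly 128 high / 297 low.
    """
    cohort = _validate_cohort(cohort)
    n = len(cohort)
    n_high = int(math.floor(high_fraction * n + 0.5))  # round half up
    if n_high <= 0 or n_high >= n:
        raise ValueError(f"high_fraction {high_fraction} leaves an empty group (n={n})")
    ordered = cohort.sort_values(["expr", "sample_id"], kind="mergesort")
    labels = pd.Series("low", index=ordered["sample_id"], name="group")
    labels.iloc[n - n_high:] = "high"
    return labels.reindex(cohort["sample_id"])


@dataclass
class CutpointScan:
    fractions_tested: Tuple[float, ...]
    per_fraction: pd.DataFrame  # fraction, n_low, n_high, statistic, p, q
    selected_fraction: float

    @property
    def selected(self) -> pd.Series:
        return self.per_fraction.set_index("fraction").loc[self.selected_fraction]


def scan_cutpoints(cohort: pd.DataFrame,
                   fractions: Sequence[float] = DEFAULT_FRACTIONS) -> CutpointScan:
    """Log-rank test at each candidate cut quantile; the selected fraction
    minimizes p (ties to the smallest fraction).  q is BH across the scanned
    fractions — the scan performs len(fractions) tests and reports them all.

    Each fraction is the expression quantile of the cut, i.e. the share of
    samples labeled LOW: fraction 0.7 puts 70% of samples in the low group
    and the top 30% in the high group (128 high / 297 low at n = 425).
    """
    cohort = _validate_cohort(cohort)
    rows = []
    for f in fractions:
        if not 0 < f < 1:
            raise ValueError(f"fraction {f} outside (0, 1)")
        labels = quantile_split(cohort, 1.0 - f)
        grp = (labels == "high").to_numpy().astype(int)
        res = logrank_test(cohort["time"].to_numpy(dtype=float),
                           cohort["event"].to_numpy(dtype=int), grp)
        rows.append((f, int((grp == 0).sum()), int(grp.sum()), res.statistic, res.p_value))
    per = pd.DataFrame(rows, columns=["fraction", "n_low", "n_high", "statistic", "p"])
    per["q"] = bh_fdr(per["p"].to_numpy()).q
    best_p = per["p"].min()
    selected = float(per.loc[per["p"] == best_p, "fraction"].min())
    return CutpointScan(tuple(fractions), per, selected)


def km_curves(cohort: pd.DataFrame, labels: pd.Series,
              at_times: Optional[Sequence[float]] = None
              ) -> Tuple[Dict[str, KaplanMeierCurve], pd.DataFrame]:
    """Per-group Kaplan–Meier curves with a numbers-at-risk table.

    ``at_times`` defaults to 6 evenly spaced points over follow-up.  The
    risk table is a plot-ready long DataFrame (group, time, survival,
    at_risk).
    """
    cohort = _validate_cohort(cohort)
    labels = pd.Series(labels).reindex(cohort["sample_id"])
    if labels.isna().any():
        raise ValueError("labels do not cover every sample")
    curves: Dict[str, KaplanMeierCurve] = {}
    if at_times is None:
        at_times = np.linspace(0.0, float(cohort["time"].max()), 6)
    rows = []
    for g, sub in cohort.groupby(labels.to_numpy()):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        curve = km_estimator(sub["time"].to_numpy(dtype=float),
                             sub["event"].to_numpy(dtype=int))
        curves[str(g)] = curve
        surv = curve(at_times)
        risk = curve.at_risk(at_times)
        for t, s, r in zip(at_times, np.atleast_1d(surv), risk):
            rows.append((str(g), float(t), float(s), int(r)))
    table = pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk"])
    return curves, table
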