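"""Copy-number landscape analysis.

Works on long-format cohorts of discrete GISTIC-style copy-number calls
(amplification +2, gain +1, diploid 0, deletion −1, deep/bi-allelic
deletion −2) with the underlying relative linear copy-number ratio and the
gene's log2 expression per sample.  Provides per-gene category profiles,
expression-by-category ANOVA, neighboring-locus Pearson correlations, and
gene-family amplification / deep-deletion frequency comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import TestResult, bh_fdr, fisher_exact_2x2, one_way_anova, pearson_r

CATEGORY_NAMES = {
    -2: "deep_deletion",
    -1: "deletion",
    0: "diploid",
    1: "gain",
    2: "amplification",
}

CNA_COLUMNS = ["sample_id", "gene", "category", "linear_cn", "expr"]


def _validate(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CNA_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"CNA cohort is missing column(s): {missing}")
    bad = set(cohort["category"].unique()) - set(CATEGORY_NAMES)
    if bad:
        raise ValueError(f"unknown CNA category code(s): {sorted(bad)}")
    if cohort.duplicated(["sample_id", "gene"]).any():
        raise ValueError("more than one record per (sample, gene)")
    if (cohort["linear_cn"] <= 0).any():
        raise ValueError("linear copy-number ratios must be positive")
    return cohort


def _gene(cohort: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = cohort[cohort["gene"] == gene]
    if len(sub) == 0:
        raise ValueError(f"gene {gene!r} has no records")
    return sub


def category_pie(cohort: pd.DataFrame, gene: str) -> Dict[int, float]:
    """Fraction of samples in each CNA category for one gene (sums to 1)."""
    sub = _gene(_validate(cohort), gene)
    frac = sub["category"].value_counts(normalize=True)
    return {int(k): float(v) for k, v in frac.sort_index().items()}


def expression_by_category(cohort: pd.DataFrame, gene: str
                           ) -> Tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA of expression across CNA categories, plus per-category
    n / mean / SD summaries.  Categories with < 2 samples are dropped by the
    ANOVA but still summarized."""
    sub = _gene(_validate(cohort), gene)
    summary = (sub.groupby("category")["expr"]
               .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
               .reset_index())
    summary["category_name"] = summary["category"].map(CATEGORY_NAMES)
    groups = [g["expr"].to_numpy(dtype=float) for _, g in sub.groupby("category")]
    res = one_way_anova(groups)
    return res, summary


def locus_correlation(cohort: pd.DataFrame, gene_a: str, gene_b: str,
                      mode: str = "cn_cn") -> TestResult:
    """Pearson correlation between two loci over shared samples.

    ``mode`` selects the value pair: cn_cn (linear copy number of both),
    cn_expr (copy number of a vs expression of b), expr_expr.
    """
    fields = {"cn_cn": ("linear_cn", "linear_cn"),
              "cn_expr": ("linear_cn", "expr"),
              "expr_expr": ("expr", "expr")}
    if mode not in fields:
        raise ValueError(f"unknown mode {mode!r}")
    fa, fb = fields[mode]
    cohort = _validate(cohort)
    a = _gene(cohort, gene_a).set_index("sample_id")[fa]
    b = _gene(cohort, gene_b).set_index("sample_id")[fb]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared samples")
    return pearson_r(a.loc[shared].to_numpy(dtype=float),
                     b.loc[shared].to_numpy(dtype=float))


@dataclass
class FamilyFrequencyTable:
    """Per-gene amplification / deep-deletion counts across a gene family,
    with BH-adjusted pairwise Fisher tests per event type."""

    frequencies: pd.DataFrame           # gene, n_amp, n_deepdel, n_total
    pairwise: pd.DataFrame              # gene_a, gene_b, event, odds_ratio, p, q
    missing: Tuple[str, ...] = ()


def family_frequency_compare(cohort: pd.DataFrame, family: Sequence[str]
                             ) -> FamilyFrequencyTable:
    """Compare amplification (+2) and bi-allelic deletion (−2) frequencies
    across the members of a gene family (e.g. AKT1/AKT2/AKT3).

    All member pairs are tested per event type with Fisher's exact test on
    event-vs-rest counts; q is BH across pairs within each event type.
    Members absent from the cohort are reported as missing and excluded.
    """
    cohort = _validate(cohort)
    present = [g for g in family if (cohort["gene"] == g).any()]
    missing = tuple(g for g in family if g not in present)
    if len(present) < 2:
        raise ValueError("need at least 2 family members with records")
    rows = []
    for g in present:
        cat = cohort.loc[cohort["gene"] == g, "category"]
        rows.append((g, int((cat == 2).sum()), int((cat == -2).sum()), int(len(cat))))
    freq = pd.DataFrame(rows, columns=["gene", "n_amp", "n_deepdel", "n_total"])
    counts = freq.set_index("gene")
    pair_rows = []
    for event, col in [("amplification", "n_amp"), ("deep_deletion", "n_deepdel")]:
        for ga, gb in combinations(present, 2):
            a = int(counts.loc[ga, col])
            b = int(counts.loc[ga, "n_total"]) - a
            c = int(counts.loc[gb, col])
            d = int(counts.loc[gb, "n_total"]) - c
            res = fisher_exact_2x2(a, b, c, d)
            pair_rows.append((ga, gb, event, res.effect, res.p_value))
    pairwise = pd.DataFrame(pair_rows,
                            columns=["gene_a", "gene_b", "event", "odds_ratio", "p"])
    pairwise["q"] = np.nan
    for event in pairwise["event"].unique():
        mask = pairwise["event"] == event
        pairwise.loc[mask, "q"] = bh_fdr(pairwise.loc[mask, "p"].to_numpy()).q
    return FamilyFrequencyTable(freq, pairwise, missing)
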