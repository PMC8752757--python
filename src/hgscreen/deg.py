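"""Cross-dataset differential-expression consensus screen.

Per-dataset two-group DE on log2 expression matrices, significance ranking,
top-K overlap across cohorts with direction consistency, a sign cross-check
against an external table, and gene-set overlay enrichment on a DEG table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult, bh_fdr, hypergeom_tail

logger = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "log2fc", "stat", "p", "q", "rank"]


@dataclass
class ExpressionDataset:
    """genes × samples log2 expression with a two-group design.

    ``values`` is a DataFrame indexed by gene symbol with sample columns;
    ``group`` maps each sample to 'control' or 'case'.  Duplicate gene rows
    (multiple probes per symbol) are allowed and collapsed at DE time.
    """

    dataset_id: str
    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self):
        self.group = pd.Series(self.group).reindex(self.values.columns)
        if self.group.isna().any():
            missing = list(self.values.columns[self.group.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(self.group) - {"control", "case"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.group == "case").sum() == 0 or (self.group == "control").sum() == 0:
            raise ValueError("both groups must be non-empty")

    @property
    def n_case(self) -> int:
        return int((self.group == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.group == "control").sum())


@dataclass
class ConsensusResult:
    k: int
    candidate_genes: List[str]
    per_dataset_ranks: pd.DataFrame  # genes × dataset_id
    direction: Dict[str, int]


def differential_expression(ds: ExpressionDataset, method: str = "student") -> pd.DataFrame:
    """Per-gene case-vs-control t-test on a log2 matrix.

    Returns a DataFrame with columns gene/log2fc/stat/p/q/rank, ranked by
    ascending p with descending \\|log2fc\\| then symbol as tie-breaks.
    Duplicate symbols collapse to their most significant row.  Genes with
    zero variance in both groups get statistic 0 / p 1 (logged).
    """
    if method not in ("student", "welch"):
        raise ValueError(f"unknown method {method!r}")
    case = ds.values.loc[:, ds.group == "case"].to_numpy(dtype=float)
    ctrl = ds.values.loc[:, ds.group == "control"].to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    import warnings as _warnings
    with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
        # constant rows trip scipy's precision-loss warning; they are
        # re-assigned explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(case, ctrl, axis=1, equal_var=(method == "student"))
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (case.var(axis=1, ddof=1) == 0) & (ctrl.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        logger.info("%s: %d gene(s) with zero variance in both groups",
                    ds.dataset_id, int(degenerate.sum()))
        flat = degenerate & (log2fc == 0)
        stat[flat], p[flat] = 0.0, 1.0
        sep = degenerate & (log2fc != 0)
        stat[sep] = np.sign(log2fc[sep]) * np.inf
        p[sep] = 0.0
    table = pd.DataFrame({
        "gene": ds.values.index.to_numpy(),
        "log2fc": log2fc,
        "stat": stat,
        "p": p,
    })
    # collapse duplicate probes per symbol: keep the most significant
    table = (table
             .sort_values(["p", "log2fc"], key=lambda s: s.abs() if s.name == "log2fc" else s,
                          ascending=[True, False], kind="mergesort")
             .drop_duplicates("gene", keep="first"))
    table["q"] = bh_fdr(table["p"].to_numpy()).q
    table = table.sort_values(
        ["p", "log2fc", "gene"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[DEG_COLUMNS]


def top_k_consensus(tables: Sequence[pd.DataFrame], k: int,
                    dataset_ids: Optional[Sequence[str]] = None) -> ConsensusResult:
    """Intersect the top-``k`` genes of each DEG table, keeping only genes
    whose fold-change sign agrees everywhere; candidates are ordered by their
    worst (maximum) per-dataset rank, best first, ties lexicographic."""
    if len(tables) < 2:
        raise ValueError("need at least 2 DEG tables")
    if k < 1:
        raise ValueError("k must be positive")
    if dataset_ids is None:
        dataset_ids = [f"dataset_{i}" for i in range(len(tables))]
    common = set(tables[0]["gene"])
    for t in tables[1:]:
        common &= set(t["gene"])
    if k > len(common):
        raise ValueError(f"k={k} exceeds the {len(common)} shared gene symbols")
    top_sets, ranks, signs = [], [], []
    for t in tables:
        t = t.set_index("gene")
        top_sets.append(set(t.nsmallest(k, "rank").index))
        ranks.append(t["rank"])
        signs.append(np.sign(t["log2fc"]))
    candidates = set.intersection(*top_sets)
    consistent = sorted(
        g for g in candidates
        if signs[0][g] != 0 and all((s[g] == signs[0][g]) for s in signs[1:])
    )
    order = sorted(consistent, key=lambda g: (max(int(r[g]) for r in ranks), g))
    rank_df = pd.DataFrame(
        {ds: [int(r[g]) for g in order] for ds, r in zip(dataset_ids, ranks)},
        index=pd.Index(order, name="gene"),
    )
    return ConsensusResult(
        k=k,
        candidate_genes=order,
        per_dataset_ranks=rank_df,
        direction={g: int(signs[0][g]) for g in order},
    )


def direction_consistency_check(table: pd.DataFrame, external: Mapping[str, int]) -> pd.DataFrame:
    """Sign cross-check of a DEG table against an external gene → sign map
    (e.g. a hand-converted TCGA/GTEx comparison).

    Returns one row per table gene with columns table_sign/external_sign/
    status where status ∈ {consistent, discordant, unchecked}.
    """
    tab = table.set_index("gene")
    rows = []
    for g in tab.index:
        tsign = int(np.sign(tab.loc[g, "log2fc"]))
        if g not in external:
            rows.append((g, tsign, 0, "unchecked"))
        else:
            esign = int(np.sign(external[g]))
            status = "consistent" if (tsign == esign and tsign != 0) else "discordant"
            rows.append((g, tsign, esign, status))
    return pd.DataFrame(rows, columns=["gene", "table_sign", "external_sign", "status"])


@dataclass
class OverlayResult:
    """Gene-set overlay on a DEG table: hypergeometric enrichment of the set
    among significant genes of the requested direction, plus a one-sided
    rank-sum comparison of set vs non-set t statistics."""

    hypergeom: TestResult
    ranksum: TestResult
    n_set: int
    n_hits: int
    overlap: int
    table: pd.DataFrame = field(repr=False, default=None)


def gene_set_overlay(table: pd.DataFrame, gene_set: Iterable[str],
                     direction: str = "down", q_threshold: float = 0.05) -> OverlayResult:
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    universe = set(table["gene"])
    members = set(gene_set) & universe
    if not members:
        raise ValueError("gene set does not intersect the table's genes")
    tab = table.copy()
    tab["in_set"] = tab["gene"].isin(members)
    sign_ok = tab["log2fc"] < 0 if direction == "down" else tab["log2fc"] > 0
    tab["hit"] = (tab["q"] < q_threshold) & sign_ok
    n = len(tab)
    n_hits = int(tab["hit"].sum())
    overlap = int((tab["hit"] & tab["in_set"]).sum())
    p_hyper = hypergeom_tail(overlap, set_size=len(members), universe=n, draws=n_hits)
    hyper = TestResult(float(overlap), p_hyper, df=None,
                       effect=float(overlap / max(n_hits, 1)))
    in_stat = tab.loc[tab["in_set"], "stat"].to_numpy()
    out_stat = tab.loc[~tab["in_set"], "stat"].to_numpy()
    alt = "less" if direction == "down" else "greater"
    u, p_rs = sps.mannwhitneyu(in_stat, out_stat, alternative=alt)
    ranksum = TestResult(float(u), float(p_rs))
    return OverlayResult(hyper, ranksum, n_set=len(members), n_hits=n_hits,
                         overlap=overlap, table=tab)
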