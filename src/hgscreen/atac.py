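"""ATAC peak × motif enrichment ranking.

Quantile-normalizes peak raw counts, scores each peak sequence for motif
occurrence with a log-odds PWM scanner over JASPAR position frequency
matrices (both strands), and ranks motifs by hypergeometric enrichment of
motif-bearing peaks among the most-increased and most-decreased peaks —
a deliberately simple stand-in for module-based TF activity integration
that keeps the per-motif significance ranking.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .stats import bh_fdr, hypergeom_tail, quantile_normalize

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PositionFrequencyMatrix:
    """Nucleotide count matrix, rows fixed to A, C, G, T."""

    motif_id: str
    name: str
    counts: np.ndarray  # 4 x L

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: expected 4 rows (A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError(f"{self.motif_id}: motif shorter than 4 columns")
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError(f"{self.motif_id}: all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def log_odds(self, pseudocount: float = 0.5,
                 background: Optional[Sequence[float]] = None) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = (self.counts + pseudocount) / (self.counts.sum(axis=0) + 4 * pseudocount)
        return np.log2(probs / bg[:, None])


@dataclass
class PeakSet:
    """BED-style peak intervals (0-based half-open) with optional per-peak
    sequences and a peaks × samples raw count matrix."""

    intervals: pd.DataFrame  # peak_id, chrom, start, end
    sequences: Optional[Dict[str, str]] = None
    counts: Optional[pd.DataFrame] = None

    def __post_init__(self):
        need = ["peak_id", "chrom", "start", "end"]
        missing = [c for c in need if c not in self.intervals.columns]
        if missing:
            raise ValueError(f"peak intervals missing column(s): {missing}")
        if (self.intervals["end"] <= self.intervals["start"]).any():
            bad = self.intervals.loc[self.intervals["end"] <= self.intervals["start"],
                                     "peak_id"].tolist()
            raise ValueError(f"end <= start for peak(s): {bad}")
        if self.sequences is not None:
            self.sequences = {k: v.upper() for k, v in self.sequences.items()}
            for _, row in self.intervals.iterrows():
                seq = self.sequences.get(row["peak_id"])
                if seq is not None and len(seq) != row["end"] - row["start"]:
                    raise ValueError(
                        f"{row['peak_id']}: sequence length {len(seq)} != interval width")


def read_jaspar(path) -> List[PositionFrequencyMatrix]:
    """Read JASPAR-format PFMs; row order is normalized to A,C,G,T whatever
    the file's row labels say."""
    with open(path) as fh:
        text = fh.read()
    parsed = bio_motifs.parse(_io.StringIO(text), "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float)
        out.append(PositionFrequencyMatrix(m.matrix_id or m.name, m.name or "", counts))
    return out


def write_jaspar(pfms: Sequence[PositionFrequencyMatrix], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.name}\n")
            for b, row in zip(BASES, p.counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {vals} ]\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _window_scores(seq: str, weights: np.ndarray) -> np.ndarray:
    """Sum of per-position log-odds for every window; N contributes 0."""
    L = weights.shape[1]
    idx = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    codes = lut[idx]
    w5 = np.vstack([weights, np.zeros(weights.shape[1])])  # row 4 = N
    if len(seq) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return w5[windows, np.arange(L)].sum(axis=1)


def pwm_scan(seq: str, pfm: PositionFrequencyMatrix, pseudocount: float = 0.5,
             background: Optional[Sequence[float]] = None,
             threshold_frac: float = 0.8) -> List[tuple]:
    """Log-odds scan of both strands.

    Returns (position, strand, score) tuples for windows scoring at least
    ``threshold_frac`` of the maximum attainable score; positions are
    forward-strand window starts.  N bases score as background (odds 0).
    """
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    W = pfm.log_odds(pseudocount, background)
    max_score = W.max(axis=0).sum()
    threshold = threshold_frac * max_score
    hits: List[tuple] = []
    fwd = _window_scores(seq, W)
    for pos in np.nonzero(fwd >= threshold)[0]:
        hits.append((int(pos), "+", float(fwd[pos])))
    rev = _window_scores(reverse_complement(seq), W)
    L = pfm.length
    for pos in np.nonzero(rev >= threshold)[0]:
        hits.append((len(seq) - L - int(pos), "-", float(rev[pos])))
    return sorted(hits)


def peak_motif_matrix(peaks: PeakSet, pfms: Sequence[PositionFrequencyMatrix],
                      **scan_kwargs) -> pd.DataFrame:
    """Binary peaks × motifs occurrence matrix (1 iff ≥ 1 PWM hit)."""
    if peaks.sequences is None:
        raise ValueError("peaks carry no sequences")
    peak_ids = peaks.intervals["peak_id"].tolist()
    missing = [p for p in peak_ids if p not in peaks.sequences]
    if missing:
        raise ValueError(f"peak(s) without sequence: {missing}")
    data = {
        pfm.motif_id: [
            1 if pwm_scan(peaks.sequences[p], pfm, **scan_kwargs) else 0
            for p in peak_ids
        ]
        for pfm in pfms
    }
    return pd.DataFrame(data, index=pd.Index(peak_ids, name="peak_id"))


def differential_peaks(counts: pd.DataFrame, condition: pd.Series,
                       case_label: str = "case",
                       control_label: str = "control") -> pd.Series:
    """Per-peak accessibility change: quantile-normalize raw counts, then
    mean log2(normalized + 1) difference, case − control."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    condition = pd.Series(condition).reindex(counts.columns)
    if condition.isna().any():
        raise ValueError("every sample column needs a condition label")
    for lab in (case_label, control_label):
        if (condition == lab).sum() < 1:
            raise ValueError(f"no samples labeled {lab!r}")
    norm = np.log2(quantile_normalize(counts) + 1.0)
    score = (norm.loc[:, (condition == case_label).to_numpy()].mean(axis=1)
             - norm.loc[:, (condition == control_label).to_numpy()].mean(axis=1))
    return score.rename("score")


def module_map_enrichment(pm: pd.DataFrame, peak_scores: pd.Series,
                          top_frac: float = 0.05) -> pd.DataFrame:
    """Rank motifs by enrichment among the most differential peaks.

    For each motif: hypergeometric upper-tail p of its occurrence among the
    ``top_frac`` highest-scoring peaks (up) and among the lowest-scoring
    (down); BH across motifs within each direction; signed_score is
    −log10(best q), negative when down-enrichment dominates.  Output sorted
    by descending \\|signed_score\\| with motif_id as tie-break.
    """
    scores = pd.Series(peak_scores).reindex(pm.index)
    if scores.isna().any():
        raise ValueError("peak scores do not cover the peak × motif matrix rows")
    n = len(pm)
    n_top = int(round(top_frac * n))
    if n_top < 10:
        raise ValueError(
            f"top_frac {top_frac} of {n} peaks keeps only {n_top} (< 10); "
            "provide more peaks or a larger fraction")
    order = scores.sort_values(kind="mergesort")
    bottom_ids = set(order.index[:n_top])
    top_ids = set(order.index[-n_top:])
    rows = []
    for motif_id in pm.columns:
        occ = pm[motif_id].astype(bool)
        total = int(occ.sum())
        k_up = int(occ.loc[occ.index.isin(top_ids)].sum())
        k_down = int(occ.loc[occ.index.isin(bottom_ids)].sum())
        p_up = hypergeom_tail(k_up, set_size=total, universe=n, draws=n_top)
        p_down = hypergeom_tail(k_down, set_size=total, universe=n, draws=n_top)
        rows.append((motif_id, total, p_up, p_down))
    res = pd.DataFrame(rows, columns=["motif_id", "occurrence_count", "p_up", "p_down"])
    res["q_up"] = bh_fdr(res["p_up"].to_numpy()).q
    res["q_down"] = bh_fdr(res["p_down"].to_numpy()).q
    down_wins = res["q_down"] < res["q_up"]
    q_best = np.where(down_wins, res["q_down"], res["q_up"])
    res["enrichment_p"] = np.where(down_wins, res["p_down"], res["p_up"])
    res["q"] = q_best
    sign = np.where(down_wins, -1.0, 1.0)
    res["signed_score"] = sign * (-np.log10(np.maximum(q_best, 1e-300)))
    res = res.sort_values(["q", "motif_id"], kind="mergesort").reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res
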