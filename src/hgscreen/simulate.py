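"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its :class:`GeneratorSpec` (the seed
lives inside the spec), and each returns a machine-readable ground-truth
object alongside the data so recovery tests can score the analysis against
what was planted.  Defaults encode the study conditions the analyses are
built for: two-cohort microarray-style screens, a TCGA-scale survival
cohort, a deletion-dominant copy-number locus neighborhood, a uniform-
background proteome with planted substrate sites, and small-replicate
ATAC-style peak count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atac import PeakSet, PositionFrequencyMatrix
from .deg import ExpressionDataset
from .motif import AMINO_ACIDS, ConsensusMotif, PhosphoSiteWindow


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 1.0 / 60.0   # events per month
    hazard_ratio: float = 3.0
    threshold_quantile: float = 0.7
    censor_rate: float = 0.3


@dataclass(frozen=True)
class CnaSpec:
    neighbor_rho: float = 0.9
    # deletion-dominant profile of a 14q32-like tumor-suppressor locus
    category_probs: Tuple[float, ...] = (0.05, 0.384, 0.40, 0.13, 0.036)
    log2_sd: float = 0.4       # SD of the latent log2 copy-ratio
    expr_slope: float = 0.5    # log2 expression units per CNA category
    expr_sd: float = 0.3


@dataclass(frozen=True)
class MotifSpec:
    n_proteins: int = 50
    protein_length: int = 400
    n_planted: int = 20
    ms_confirmed_frac: float = 0.5


@dataclass(frozen=True)
class PeakSpec:
    n_peaks: int = 300
    peak_length: int = 100
    planted_motif_frac: float = 0.1
    fold_change: float = 0.25  # applied to motif-bearing peaks in the case group
    n_samples_per_group: int = 3
    base_mean: float = 100.0


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs for the synthetic cohorts, with the defaults the test suite
    and worked examples use."""

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_group: int = 10
    n_shared_de: int = 50
    n_specific_de: int = 25
    effect_size: float = 2.0   # log2 units
    noise_sd: float = 0.5
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    cna: CnaSpec = field(default_factory=CnaSpec)
    motif: MotifSpec = field(default_factory=MotifSpec)
    peaks: PeakSpec = field(default_factory=PeakSpec)

    def __post_init__(self):
        if self.n_shared_de + 2 * self.n_specific_de > self.n_genes:
            raise ValueError("more DE genes than genes")
        if not 0 < self.survival.threshold_quantile < 1:
            raise ValueError("threshold_quantile must lie in (0, 1)")
        if not 0 <= self.cna.neighbor_rho <= 1:
            raise ValueError("neighbor_rho must lie in [0, 1]")
        if abs(sum(self.cna.category_probs) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)


def _gene_names(n: int) -> List[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def make_expression_pair(spec: GeneratorSpec,
                         n_case: Optional[Tuple[int, int]] = None
                         ) -> Tuple[ExpressionDataset, ExpressionDataset, pd.DataFrame]:
    """Two log2 expression datasets sharing ``n_shared_de`` true DE genes
    (same sign in both) plus ``n_specific_de`` private decoys each, with
    independent Gaussian noise.

    ``n_case`` optionally overrides the case-group size per dataset (the
    control size stays ``n_samples_per_group``), mirroring asymmetric
    normal-vs-tumor cohorts.  The truth table lists every planted gene with
    its sign and whether it is shared.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    baseline = rng.normal(7.0, 1.0, size=spec.n_genes)
    signs = rng.choice([-1.0, 1.0], size=spec.n_shared_de + 2 * spec.n_specific_de)
    shared = list(range(spec.n_shared_de))
    spec_a = list(range(spec.n_shared_de, spec.n_shared_de + spec.n_specific_de))
    spec_b = list(range(spec.n_shared_de + spec.n_specific_de,
                        spec.n_shared_de + 2 * spec.n_specific_de))
    if n_case is None:
        n_case = (spec.n_samples_per_group, spec.n_samples_per_group)
    datasets = []
    for ds_idx, (ds_id, private) in enumerate([("sim_A", spec_a), ("sim_B", spec_b)]):
        n_ctrl, n_cs = spec.n_samples_per_group, n_case[ds_idx]
        effect = np.zeros(spec.n_genes)
        for gi in shared + private:
            effect[gi] = signs[gi] * spec.effect_size
        mat = np.empty((spec.n_genes, n_ctrl + n_cs))
        mat[:, :n_ctrl] = baseline[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_genes, n_ctrl))
        mat[:, n_ctrl:] = (baseline + effect)[:, None] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_genes, n_cs))
        samples = [f"{ds_id}_ctrl{i}" for i in range(n_ctrl)] + \
                  [f"{ds_id}_case{i}" for i in range(n_cs)]
        values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
        group = pd.Series(["control"] * n_ctrl + ["case"] * n_cs, index=samples)
        datasets.append(ExpressionDataset(ds_id, values, group))
    truth_rows = [(genes[gi], int(signs[gi]), True, "both") for gi in shared]
    truth_rows += [(genes[gi], int(signs[gi]), False, "sim_A") for gi in spec_a]
    truth_rows += [(genes[gi], int(signs[gi]), False, "sim_B") for gi in spec_b]
    truth = pd.DataFrame(truth_rows, columns=["gene", "sign", "shared", "dataset"])
    return datasets[0], datasets[1], truth


def make_survival_cohort(spec: GeneratorSpec, n: int = 400
                         ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Step-hazard survival cohort: exponential event times with hazard
    multiplied by ``hazard_ratio`` for samples whose expression lies above
    the ``threshold_quantile``; each subject is independently censored with
    probability ``censor_rate`` at a uniform fraction of its event time."""
    sv = spec.survival
    rng = np.random.default_rng(spec.seed)
    expr = rng.normal(0.0, 1.0, size=n)
    cut = np.quantile(expr, sv.threshold_quantile)
    high = expr > cut
    hazard = sv.baseline_hazard * np.where(high, sv.hazard_ratio, 1.0)
    time = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < sv.censor_rate
    time = np.where(censored, time * rng.random(n), time)
    cohort = pd.DataFrame({
        "sample_id": [f"P{i:04d}" for i in range(n)],
        "time": time,
        "event": (~censored).astype(int),
        "expr": expr,
    })
    truth = {"threshold_quantile": sv.threshold_quantile,
             "hazard_ratio": sv.hazard_ratio,
             "high_is_risk": 1.0}
    return cohort, truth


def make_cna_cohort(spec: GeneratorSpec,
                    genes: Sequence[str] = ("MARK3", "HSP90AA1", "AKT1"),
                    n: int = 489,
                    category_probs: Optional[Dict[str, Sequence[float]]] = None
                    ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Long-format CNA cohort for a locus neighborhood.

    A latent per-sample Gaussian copy-number state is shared across loci
    with correlation ``neighbor_rho**|i-j|`` (decaying with locus distance).
    Per locus, category cutpoints are the Gaussian quantiles of its
    cumulative ``category_probs``, applied to the latent log2 copy ratio
    (``log2_sd`` × state), so category fractions match the probs by
    construction; linear_cn = 2**log2_ratio; expression is
    ``expr_slope`` × category + Gaussian noise.
    """
    cs = spec.cna
    rng = np.random.default_rng(spec.seed)
    k = len(genes)
    cov = np.array([[cs.neighbor_rho ** abs(i - j) for j in range(k)] for i in range(k)])
    z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    rows = []
    for j, gene in enumerate(genes):
        probs = np.asarray((category_probs or {}).get(gene, cs.category_probs), float)
        cuts = sps.norm.ppf(np.cumsum(probs)[:-1])
        zj = z[:, j]
        cat = np.searchsorted(cuts, zj) - 2  # categories -2..+2
        log2r = cs.log2_sd * zj
        expr = cs.expr_slope * cat + rng.normal(0.0, cs.expr_sd, size=n)
        for i in range(n):
            rows.append((f"P{i:04d}", gene, int(cat[i]),
                         float(2.0 ** log2r[i]), float(expr[i])))
    cohort = pd.DataFrame(rows, columns=["sample_id", "gene", "category",
                                         "linear_cn", "expr"])
    truth = {"neighbor_rho": cs.neighbor_rho, "expr_slope": cs.expr_slope}
    return cohort, truth


def _realize_motif(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """One concrete amino-acid string satisfying the motif."""
    out = []
    for pos in motif.positions:
        if pos.is_wildcard:
            out.append(rng.choice(list(AMINO_ACIDS)))
        else:
            out.append(rng.choice(list(pos.residues)))
    return "".join(out)


def make_proteome(spec: GeneratorSpec, motif: ConsensusMotif
                  ) -> Tuple[Dict[str, str], pd.DataFrame, List[Tuple[str, int]]]:
    """Uniform-background random proteome with ``n_planted`` exact motif
    realizations inserted at recorded positions; a ``ms_confirmed_frac``
    subset of planted sites is marked mass-spec confirmed."""
    ms = spec.motif
    if ms.protein_length <= motif.width:
        raise ValueError("proteins must be longer than the motif")
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AMINO_ACIDS))
    proteome = {
        f"PROT{i:03d}": "".join(rng.choice(aas, size=ms.protein_length))
        for i in range(ms.n_proteins)
    }
    ids = list(proteome)
    slots = [(pid, start) for pid in ids
             for start in range(0, ms.protein_length - motif.width, motif.width + 2)]
    chosen = rng.choice(len(slots), size=ms.n_planted, replace=False)
    planted = []
    for idx in sorted(chosen):
        pid, start = slots[idx]
        word = _realize_motif(motif, rng)
        seq = proteome[pid]
        proteome[pid] = seq[:start] + word + seq[start + motif.width:]
        planted.append((pid, start + motif.phospho_index + 1))  # 1-based site
    confirmed_mask = rng.random(len(planted)) < ms.ms_confirmed_frac
    ms_confirmed = [site for site, c in zip(planted, confirmed_mask) if c]
    truth = pd.DataFrame(planted, columns=["protein_id", "position"])
    truth["ms_confirmed"] = confirmed_mask
    return proteome, truth, ms_confirmed


def make_peakset(spec: GeneratorSpec, pfm: PositionFrequencyMatrix
                 ) -> Tuple[PeakSet, pd.Series, pd.DataFrame]:
    """Random peak sequences with the PFM consensus embedded in a
    ``planted_motif_frac`` subset; raw counts are Poisson around a lognormal
    per-peak mean, with ``fold_change`` applied to motif-bearing peaks in
    the case samples.  Returns (peaks, condition labels, truth)."""
    ps = spec.peaks
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    peak_ids = [f"peak{i:04d}" for i in range(ps.n_peaks)]
    n_planted = int(round(ps.planted_motif_frac * ps.n_peaks))
    planted = set(rng.choice(ps.n_peaks, size=n_planted, replace=False).tolist())
    consensus = pfm.consensus()
    seqs = {}
    for i, pid in enumerate(peak_ids):
        s = "".join(rng.choice(bases, size=ps.peak_length))
        if i in planted:
            start = int(rng.integers(0, ps.peak_length - pfm.length + 1))
            s = s[:start] + consensus + s[start + pfm.length:]
        seqs[pid] = s
    intervals = pd.DataFrame({
        "peak_id": peak_ids,
        "chrom": "chr1",
        "start": np.arange(ps.n_peaks) * 1000,
        "end": np.arange(ps.n_peaks) * 1000 + ps.peak_length,
    })
    samples = [f"ctrl{i}" for i in range(ps.n_samples_per_group)] + \
              [f"case{i}" for i in range(ps.n_samples_per_group)]
    condition = pd.Series(["control"] * ps.n_samples_per_group +
                          ["case"] * ps.n_samples_per_group, index=samples)
    base = rng.lognormal(np.log(ps.base_mean), 0.4, size=ps.n_peaks)
    mean = np.tile(base[:, None], (1, len(samples)))
    for i in range(ps.n_peaks):
        if i in planted:
            mean[i, ps.n_samples_per_group:] *= ps.fold_change
    counts = pd.DataFrame(rng.poisson(mean).astype(float),
                          index=pd.Index(peak_ids, name="peak_id"), columns=samples)
    peaks = PeakSet(intervals, sequences=seqs, counts=counts)
    truth = pd.DataFrame({"peak_id": peak_ids,
                          "motif_planted": [i in planted for i in range(ps.n_peaks)],
                          "fold_change": [ps.fold_change if i in planted else 1.0
                                          for i in range(ps.n_peaks)]})
    return peaks, condition, truth


# ---------------------------------------------------------------------------
# Engineered substrate fixture

# Four aligned ±5 windows emulating the sequence contexts of known substrate
# phosphosites (CDC25C-, HDAC7-, KSR1- and PKP2-like).  Column offsets -5, -3,
# 0 and +2 are invariant (L, R, S, P), +1 and +5 carry three residues each,
# and the remaining columns are fully degenerate.
SUBSTRATE_WINDOWS = (
    ("CDC25C_like", 216, "LYRSPSAPENI"),
    ("HDAC7_like", 155, "LKRTESVPHDL"),
    ("KSR1_like", 392, "LSRNHSMPTTV"),
    ("PKP2_like", 82, "LTRQDSAPKGI"),
)


def substrate_windows() -> List[PhosphoSiteWindow]:
    """The four engineered substrate phosphosite windows the consensus-motif
    example is built from (synthetic sequence contexts, not database ones)."""
    return [PhosphoSiteWindow(pid, pos, w[5], w) for pid, pos, w in SUBSTRATE_WINDOWS]


def example_pfm() -> PositionFrequencyMatrix:
    """A small AP-1-like (TGACTCA) position frequency matrix used by the
    peak-enrichment examples and tests (synthetic counts)."""
    consensus = "TGACTCA"
    counts = np.full((4, len(consensus)), 2.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 14.0
    return PositionFrequencyMatrix("SYN0001", "AP1_like_synthetic", counts)
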