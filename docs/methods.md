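# Methods

This note documents the statistical procedures, the synthetic-data models
behind the test suite, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Statistical kernel

All hypothesis tests route through `hgscreen.stats`, backed by
scipy/statsmodels/lifelines where those provide the canonical form, with
degenerate inputs resolved explicitly:

- **Two-group comparison** defaults to the pooled-variance Student t
  (two-sided); Welch is an explicit option. Zero variance in both groups
  gives statistic 0 / p 1 when means agree and p 0 with a warning when
  they differ. The DE screen exposes both forms; the moderated-t used by
  microarray pipelines such as limma is deliberately out of scope, so
  rankings on very small cohorts will differ from an empirical-Bayes
  analysis.
- **One-way ANOVA** drops categories with fewer than two samples (copy-
  number categories such as +2 are often near-empty) and logs the fact;
  fewer than two usable groups is an error.
- **Fisher's exact test** uses the conventional two-sided definition (sum
  of tables with point probability ≤ observed). The odds ratio applies a
  Haldane 0.5 continuity correction only when a cell is zero. The exact
  test is conservative at small counts: its null rejection rate
  approaches the nominal 5% only as the margins grow, which is why the
  calibration experiments use group sizes of several hundred.
- **Log-rank** uses the tie-aware hypergeometric variance (survival data
  have tied times); a cohort with no events at all returns p 1 with a
  warning.
- **BH FDR** is used wherever multiplicity arises; no source analysis
  names its adjustment, and BH is the field default.
- **Quantile normalization** maps each column onto the across-column rank
  means; within-column ties receive the mean of their rank values.
  Consequences worth knowing: with ties present the operation is not
  exactly idempotent (the tie-averaged values feed back into the target
  distribution), and rescaling one column changes the target slightly
  even though ranks are untouched. The suite therefore asserts exact
  idempotence on tie-free data and rank/extreme-set stability under
  single-sample rescaling.

## DEG consensus screen

Per-gene ranking is by ascending p with descending |log2 fold change| and
then symbol as deterministic tie-breaks. Duplicate gene symbols (multiple
probes) collapse to the most significant row before ranking. The top-*k*
sets are taken overall, not per direction, with sign consistency enforced
at intersection time; candidates are ordered by their worst per-dataset
rank. Rationale: the screen this mirrors reported exclusively
down-regulated candidates, and the overall-rank rule reproduces that
behaviour without assuming a per-direction split; whether the original
ranking was by p, adjusted p, or fold change is not recoverable, and p is
the most common GEO2R ordering.

The gene-set overlay reports two complementary statistics: a
hypergeometric upper-tail p for set membership among FDR-significant genes
of the requested direction (degenerate to p = 1 when nothing passes FDR),
and a one-sided Mann–Whitney p comparing set vs non-set t statistics,
which stays calibrated on null tables and is the quantity used for null
calibration.

The external direction-consistency check is a pure sign comparison
against a user-supplied gene → sign table (e.g. hand-converted TCGA/GTEx
output); no network access anywhere.

## Survival cut-point scan

`quantile_split(cohort, high_fraction)` labels the round-half-up
(high_fraction · n) highest-expressing samples high, ties broken by a
stable sort on (expr, sample_id). Round-half-up reproduces the reference
cohort arithmetic: n = 425 at high fraction 0.3 → 128/297.

`scan_cutpoints` parametrizes by the **cut quantile** (share of samples
labeled low): fractions {0.3, 0.5, 0.7} with 0.7 meaning 70% low / 30%
high. The selected fraction minimizes the log-rank p, ties to the smallest
fraction. Two honesty measures are built in: every per-fraction result is
always emitted (no silent selection), and q values BH-adjusted across the
scanned fractions accompany the raw p. The scan's selection optimism is a
documented property — under a flat hazard the minimum of three correlated
log-rank tests rejects at roughly 10–15% at α = 0.05, and the suite
asserts that this exceeds the nominal rate rather than pretending the
selected p is calibrated. Whether a fixed genome-wide fraction or per-gene
selection is appropriate is left to the caller: `scan_cutpoints` is
per-gene selection; passing a single fraction fixes the rule.

## CNA landscape

Discrete GISTIC-style categories are inputs, not derived: real exports
carry the caller's thresholds, and re-deriving them is out of scope.
"Bi-allelic deletion" is identified with category −2. Family comparisons
test each member pair per event type (amplification, deep deletion) with
Fisher's exact test on event-vs-rest counts, BH across pairs within event
type.

## Substrate motif analysis

Windows are ±5 residues (the width implied by an 11-symbol pattern),
1-based positions, gap-padded at termini; the consensus rule is: one
distinct residue per column → fixed, 2–3 distinct → bracketed class, more
→ wildcard, gaps never counted. Class members are ordered by descending
frequency with ties broken by first appearance in the input windows;
motif equality is defined on residue sets, so inference is
permutation-invariant up to rendering order. `x` denotes exactly one
arbitrary residue — a fixed-spacing wildcard, not a deletable position —
because the pattern aligns the phosphoacceptor at a fixed offset and the
14-3-3 comparison presumes fixed spacing.

Scanning anchors the motif's phospho position on each candidate S (or
S/T); non-wildcard positions falling outside the sequence fail
(conservative terminal behaviour). The 14-3-3 pattern `R[ST]xSxP` carries
no `*`; annotation anchors its phosphoserine — the last fixed S, the 4th
symbol, offsets −3..+2 — on the candidate site, the mode-1 convention.

The four bundled substrate windows are engineered synthetic sequence
contexts (named only *-like*), constructed so that the documented
consensus rule reproduces the target pattern exactly; they are fixture
data, not database extracts.

## ATAC peak × motif enrichment

PWM scoring: counts + 0.5 pseudocount per cell, uniform background, log2
odds summed over the window, both strands, hit at ≥ 80% of the maximum
attainable score; N bases contribute 0 (background odds). All thresholds
configurable. The per-peak differential score is the mean log2(quantile-
normalized count + 1) difference (case − control) — a deliberate choice
over a per-peak test because replicate counts in such designs are small
and the downstream statistic is rank-based.

Motif ranking is a declared simplification of module-based TF activity
integration: per motif, hypergeometric upper-tail enrichment of
motif-bearing peaks among the top and bottom `top_frac` (default 5%) of
peaks by differential score, BH across motifs within direction, signed
score −log10(best q) with negative sign when down-enrichment dominates.
The full module-learning machinery of the original approach is out of
scope; only the per-motif significance ranking it was used for is
reproduced.

## Synthetic-data generators

All generators are pure functions of a `GeneratorSpec` (seed included) and
emit machine-readable ground truth. Defaults are the study conditions the
suite tests against:

- **Expression pair**: 2,000 genes, 10 control vs 10 case per cohort, 50
  shared + 25 cohort-specific true DE genes at |Δ| = 2 log2 units, noise
  σ = 0.5 — Gaussian on the log2 scale, matching log2-fitted microarray
  inputs. Group sizes are symmetric by default (the asymmetric 10 vs 53 /
  10 vs 185 structure of real normal-vs-tumor cohorts is available via an
  override); no batch or probe effects are modeled, so passing recovery
  tests demonstrate algorithmic correctness, not robustness to array
  artefacts.
- **Survival**: exponential event times at baseline hazard 1/60 per month,
  hazard × 3 for samples above the 70th expression percentile, 30%
  independent uniform censoring. The step (threshold) hazard is exactly
  the structure the cut-point scan is designed to detect, making recovery
  a sharp test; a proportional-in-expression hazard would blur the
  selected fraction. The elevated-hazard side (high expression) is an
  arbitrary sign choice the analysis is agnostic to.
- **CNA**: latent per-sample Gaussian state shared across loci with
  correlation ρ^|i−j| (default ρ = 0.9, decaying with locus distance);
  per-locus category cutpoints are the Gaussian quantiles of the
  cumulative category probabilities (default deletion-dominant:
  5/38.4/40/13/3.6%), applied to the latent log2 copy ratio (σ = 0.4), so
  category fractions match the probabilities by construction; linear copy
  ratio = 2^log2-ratio; expression = 0.5 × category + N(0, 0.3). The
  quantile cutpoints are a synthetic convention — real GISTIC thresholds
  are unknown and no claim is made about them. Because the linear ratio
  is lognormal, its Pearson correlation is mildly attenuated relative to
  the latent ρ (about 0.896 for ρ = 0.9 at σ = 0.4), well inside the
  sampling CI at the tested n.
- **Proteome**: uniform background over 20 residues (real proteomes are
  not uniform; chance-match expectations use the uniform model only), 50
  proteins × 400 residues, 20 planted exact motif realizations at
  recorded non-overlapping slots, half marked mass-spec confirmed.
- **Peaks**: 300 peaks × 100 bp, consensus embedded in 10%, Poisson counts
  around lognormal per-peak means, fold change 0.25 applied to
  motif-bearing peaks in the 3 case samples (vs 3 controls).

## Problem sizes and calibration experiments

Recovery and calibration use 200 replicates (100 for the peak-enrichment
recovery), cohorts of n = 400 (survival), n = 489 (CNA, the reference
cohort size), and 2,000-gene expression matrices — sizes at which every
check is decisive while the full suite and the acceptance script each
complete within about a minute.

## Known limitations

- The t-based DE ranking is not the moderated-t of limma; on very small
  cohorts the two can order borderline genes differently.
- Fisher-exact calibration statements hold only at the large margins
  noted above.
- The selected cut-point p is optimistic by construction; callers needing
  calibrated genome-wide claims must adjust for the selection, which the
  emitted per-fraction table makes possible.
- The peak-enrichment ranking is a simplification; exact reproduction of
  rankings produced by module-learning tools is not claimed.
- Probe annotation, batch correction, peak calling, and read alignment
  are out of scope: tables of the documented shapes are the interface.
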