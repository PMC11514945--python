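# Methods

This note records the model, the defaults, the numerical conventions,
and the open design choices made in `devostate`, so results can be
interpreted and reproduced without reading the code.

## Signature construction

A *cell state* is a (tissue, cell type, developmental stage) triple,
with stage restricted to `fetal` or `adult`; keeping the two stages as
separate states — even for the "same" cell type — is the core modelling
commitment: it lets adult programs act as negative controls when fetal
signal is quantified in a bulk sample.

Pipeline and defaults (all exposed as parameters):

| step | default | rationale |
| --- | --- | --- |
| cell QC | total UMI ≥ 500 | removes low-complexity droplets |
| normalization | CPM (columns sum to 10^6) | removes library-size variation |
| state QC | ≥ 20 high-quality cells | avoids sparse, noisy signature columns |
| mega-cell replicates | 10 per state, each averaging ⌊n/2⌋ cells drawn without replacement | turns single cells into pseudo-replicates for a rank test |
| DGE test | one-vs-rest Mann–Whitney U, alternative "greater" | robust to the heavy-tailed CPM scale |
| adjustment | Benjamini–Hochberg per state across genes, α = 0.01 | "adjusted p" made concrete |
| ranking | top 200 by log2FC among passing genes | caps signature size per state |
| pooling | mean CPM per state over *all* its cells | the final matrix is not limited to the sampled halves |

Conventions the recipe leaves open, fixed here:

- A mega cell is the **arithmetic mean of per-cell CPM vectors**, not
  the CPM of pooled counts; this makes replicates library-size
  invariant.
- `log2FC = log2((mean focal CPM + 1) / (mean rest CPM + 1))`; the
  pseudocount avoids division by zero on the CPM scale.
- The one-vs-rest pool spans all other states of the tissue jointly,
  fetal and adult together, consistent with one signature matrix per
  tissue.
- Exclusion lists (cell cycle, ribosome biogenesis, apoptosis,
  mitochondrial — supplied as GMT, since GO-derived gene counts are
  ontology-version-dependent) are applied **before** the top-200
  truncation, so each state refills its quota from eligible genes.
- Ties in the log2FC ranking break by ascending adjusted p, then gene
  id; the Mann–Whitney null is exact when both groups have ≤ 12
  replicates and the tie-corrected normal approximation with continuity
  correction otherwise.
- Per-(state, replicate) random draws are seeded through a splittable
  counter keyed on a hash of the state name, so adding or removing a
  state never perturbs the other states' samples.
- Gene identifiers are opaque, case-sensitive strings; cross-species
  work goes through an explicit one-to-one ortholog map, and genes
  without a one-to-one partner are dropped (and logged).

## Deconvolution and the fetalness index

A bulk TPM profile `m` over the signature genes is modelled as a
non-negative combination of signature columns. The default solver is
the published CIBERSORT core: both `m` and the signature matrix are
z-scored (globally, not per gene), a linear ν-SVR is fit for
ν ∈ {0.25, 0.5, 0.75} with C = 1, the ν with the lowest RMSE between
fitted and observed mixture is kept, negative coefficients are set to
zero and the rest renormalized to sum to one. No quantile normalization
is applied (the RNA-seq guidance for the referenced tool disables it).
An NNLS solver (raw values, same renormalization) is provided as a
transparent, exactly verifiable alternative. Fractions below 1e-8 after
renormalization are snapped to zero and the row renormalized.
Per-sample diagnostics (RMSE, Pearson r of the reconstruction, chosen
ν) are always reported; no sample is auto-rejected, and no p-value
gating is applied to fractions.

Because the z-scoring (ν-SVR) and renormalization (both solvers) absorb
any positive scaling of the mixture, fractions are scale-invariant;
only *relative* fractions are reported.

The fetalness index of a sample is exactly the sum of its fractions
over fetal-stage states — a number in [0, 1] interpreted as the
aggregate strength of fetal cell programs, i.e. a tissue-aware stemness
surrogate. It is a statement about transcriptional similarity, not a
literal cell-count estimate.

ν-SVR behaves slightly differently from NNLS at the extremes: on a
noiseless vertex mixture (one state only) NNLS recovers the vertex to
machine precision while the ν-SVR's ε-tube and ridge penalty spread
~1e-3 of mass onto correlated columns. Under multiplicative noise the
ranking reverses — the SVR's loss makes it measurably more robust than
NNLS (see the acceptance quantities) — which is why ν-SVR is the
default.

## Embedding and fetal-neighbor enrichment

The co-clustering preprocessing is the standard single-cell chain:
CP10K per cell, optional averaging within (cell type × replicate),
log1p, dispersion-based HVG selection, regression of total count and
mitochondrial fraction, per-gene scaling with upper clipping at 10, PCA
(50 components by default), seeded UMAP (neighbors 15, min_dist 0.1,
Euclidean). Choices the recipe leaves open:

- dispersion normalization z-scores log-dispersion within 20
  **equal-frequency** bins of log1p mean expression; thresholds
  (mean ∈ (0.0125, 3), normalized dispersion > 0.5) are interpreted on
  the log1p scale, as is conventional for those values;
- scaling uses the population (ddof = 0) standard deviation and clips
  only the upper tail; genes constant after regression are set to zero
  rather than erroring;
- mitochondrial genes are recognized by a configurable prefix list
  (default `MT-`) or an explicit gene set.

Fetal-neighbor enrichment: the fetal centroid is the mean of the fetal
samples' coordinates in the first 10 PCs; fetal samples are excluded
from the neighbor pool; for each k the k nearest non-fetal samples by
Euclidean distance are taken (ties at the boundary break by sample id
for determinism) and each class's captured fraction
|class ∩ subset| / |class| is reported. The per-class-capture reading
(rather than within-subset composition) is used because it makes every
class's curve rise to 1 at k = pool size and keeps classes comparable
regardless of their abundance.

## Mutual-information enrichment

Genes are ranked by Spearman correlation (average ranks on ties;
constant genes dropped) with the fetalness index across samples, sorted
ascending, and cut into 15 contiguous bins of equal size (remainder to
the last bins, so sizes differ by at most one; bin 1 = most negative).
For a gene set, the plug-in mutual information between the bin variable
and membership is reported in bits. Significance comes from a
permutation null — gene-to-bin assignment shuffled with membership
fixed, realized by drawing per-bin member counts from a multivariate
hypergeometric distribution, which is the same null computed faster —
with the add-one estimator `p = (1 + #{MI_null ≥ MI_obs}) / (1 + n_perm)`
and 10,000 permutations by default. FDR across sets is
Benjamini–Hochberg.

MI is non-negative, so direction is reconstructed separately: the
reported per-bin profile is `log2((observed + 0.5)/(expected + 0.5))`,
and the sign is the sign of the Spearman correlation between bin index
and the per-bin membership **rate** (members / bin size). The rate, not
the smoothed profile, carries the sign because bins that differ only in
size would otherwise acquire a spurious ordering among equally empty
bins — with a set perfectly concentrated in the top bin, the smoothed
profile of the 14 empty bins varies microscopically with bin size and a
profile-based Spearman can return the wrong sign. A flat membership
yields sign 0. Everything downstream of the per-gene correlation uses
ranks only, so the analysis is invariant to strictly monotone
transforms of the index. No iterative conditional-MI pruning of
redundant sets is performed.

## Clinical statistics

- **Cox:** partial likelihood with Efron tie handling (lifelines); the
  index is standardized to unit SD before fitting so hazard ratios are
  comparable across cohorts; the index enters continuously (the median
  split exists separately for Kaplan–Meier display); stage enters
  multivariate models as an ordinal integer I=1..IV=4. At least 10
  events are required.
- **Median split:** `low` strictly below the median, `high` at or
  above; with odd n the extra member lands in `high`.
- **Marker shift:** Pearson r of each marker with the index versus the
  all-other-genes baseline distribution, compared by a two-sided
  Mann–Whitney U test; direction is the sign of the median difference.
- **Dependency:** essential means CERES strictly below −0.5; genes with
  correlation exactly 0 are excluded from the sign groups; the odds
  ratio is the cross-product ratio and p is two-sided Fisher exact; a
  zero marginal is reported as degenerate with an undefined OR.
- **Drug response:** Spearman per drug over overlapping cell lines
  (≥ 5 by default); for ≤ 8 lines the two-sided p comes from full
  enumeration of rank permutations instead of the t approximation; BH
  across drugs.

## Synthetic data

The generators define the conditions under which the pipeline is
validated:

- **Reference:** negative-binomial UMI counts
  (Var = μ + 0.4 μ²; per-gene baseline means log-normal around 2) for
  8 states (4 fetal, 4 adult) × 200 cells × 2,000 genes, with 25
  disjoint marker genes per state whose mean is multiplied by 8 in
  their own state. NB overdispersion is the standard model for UMI
  counts; the marker fold change is large enough that a 10-vs-70
  replicate rank test should recover every marker, making "100%
  planted-marker recovery" a meaningful pass/fail criterion.
- **Mixtures:** Dirichlet(1) fractions over the empirical state mean
  profiles, optional per-gene multiplicative log-normal noise
  (σ = 0.2 for the robustness benchmark), renormalized to TPM.
- **Survival:** exponential event times with rate
  `h0 · exp(β · fetalness)`; independent exponential censoring whose
  rate is solved numerically so the expected censored fraction matches
  the target (30% by default).
- **Enrichment:** a Uniform(0,1) index, one 50-gene set linearly
  coupled to it (coupling 2, noise SD 1, 100 samples, 1,500 genes) and
  19 random decoy sets.

What these fixtures do **not** emulate: gene-length and GC bias,
dropout structure beyond NB sampling, batch effects between the
signature platform and the bulk platform, correlated gene modules,
doublets, or realistic cohort-level clinical confounding. Passing the
synthetic benchmarks therefore demonstrates the correctness and
calibration of the algorithms, not field performance on any particular
real cohort.

## Problem sizes and tolerances

The validation suite and `scripts/acceptance.py` use: 200 mixtures per
benchmark; 1,000 random gene sets × 999 permutations for the
permutation-null calibration; 500 simulated cohorts of n = 500 for the
Cox type-I and coverage checks; Monte-Carlo rates are judged against
99% binomial intervals. CPM columns are exact to 1e-9 relative, TPM
rows to 1e-6; noiseless NNLS recovery is checked at 1e-3 (measured:
~1e-15) and ν-SVR mean error at 0.02 (measured: ~1e-5). These sizes
make the whole suite run in a few minutes on one CPU while leaving the
Monte-Carlo error well below every tolerance they are checked against.

## Known limitations

- The deconvolution assumes the signature spans the bulk's constituent
  programs; unmodelled cell types project onto their transcriptionally
  nearest states.
- Relative fractions are similarity coordinates, not cell counts; no
  absolute-abundance mode is provided.
- No batch correction between signature and bulk platforms.
- The Cox module warns rather than tests for proportional-hazards
  violations; competing risks are out of scope.
- UMAP layouts are seed-reproducible but not comparable across
  umap-learn versions.
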