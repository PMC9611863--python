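# Methods

`tissuescreen` implements a screening-and-validation pipeline for
tissue-specific gene expression, built around the case of testis-specific
C2H2 zinc-finger genes: screen several public expression databases for genes
expressed predominantly in one tissue, keep only cross-database consensus
calls, validate candidates by qPCR in a tumor/normal cohort, and examine the
transcriptional consistency of the final gene set by correlation-distance
clustering.  This note documents the model behind each stage, the defaults
and why, the synthetic-data model used for testing, and known limitations.

## The specificity screen

Input is a genes × tissues matrix of median TPM (one matrix per database;
GCT 1.2 or TSV).  A gene is called specific to a target tissue when

* its TPM in the target tissue is at least `tpm_min` (default **5 TPM**), and
* that TPM is at least `fold_min` (default **3**) times its TPM in *every*
  other tissue.

The fold condition is evaluated through the **inverted ratio**

```
r = max over other tissues of (TPM_other / TPM_target)
```

and the rule `r ≤ inv_ratio_max` with `inv_ratio_max = 1/fold_min` by
default.  The inversion matters for genes silent outside the target tissue:
`TPM_target / 0` is undefined, while the inverted ratio is simply 0 and the
gene passes — which is exactly the desired behaviour for the most strictly
tissue-restricted genes.  Both boundaries are inclusive ("at least 5 TPM",
"at least 3-fold").

`inv_ratio_max` defaults to `1/3 ≈ 0.333`, not a rounded 0.3.  The two are
not equivalent at the margin: a gene at 34.6 TPM with a 11.3-TPM maximum
elsewhere has r ≈ 0.327, which passes a 3-fold rule but fails a 0.3 cutoff,
and such borderline genes are among the consensus set this pipeline is
designed to reproduce.  A stricter cap remains available via
`ScreenConfig(inv_ratio_max=0.3)`.

Tissues are matrix columns as-is; sub-tissues (e.g. brain regions) are not
aggregated, because the rule quantifies over *every other column*.  Genes
are identified by their primary (Ensembl-style) ID; symbols are display
only.  Missing values are not permitted inside a panel; the readers resolve
upstream NA by dropping the gene with a warning (default) or imputing 0,
chosen explicitly by a reader flag.

The per-gene reduction used throughout reporting is the triple
(target TPM, max of others, median of others); the median of an even count
of tissues is the mean of the central pair, which is why half-values such as
4.25 appear in summaries.

## Cross-database consensus

Per-database screens are combined by gene ID:

1. **Venn partition** — every gene is assigned to the exact subset of
   databases that called it specific; all `2^D − 1` regions are materialised
   and the all-databases region is the consensus core.  Genes absent from a
   database cannot be core members and are logged as `missing_in:<db>`.
2. **Consensus fold filter** — a core gene is kept when its weakest
   cross-database fold, `min over databases of (target / max_other)`
   (treating `x/0` as +∞), *strictly exceeds* `min_fold` (default **1.5**).
   Note the asymmetry, which mirrors the two rules' origins: the 3-fold
   screen is inclusive (≥), the 1.5-fold consensus filter is strict (>).
3. **Report table** — one row per gene, one `T (M/m)` cell per database,
   with input-preserving decimal formatting and an exact parser for
   round-tripping.

## qPCR relative quantification

Replicate Cq values (technical triplicates) are averaged on the Cq scale;
a replicate spread above 0.5 cycles is flagged but not fatal.  A target's
relative level in a sample is

```
level = E^(mean(Cq_ref) − Cq_target),   E = 2 by default
```

i.e. the target abundance `E^−Cq` divided by the **geometric mean** of the
reference-gene abundances (the geometric mean on the abundance scale is the
arithmetic mean on the Cq scale).  The default reference pair is 18S rRNA
and GAPDH.  Amplification efficiency is fixed at 2 (100%) with a per-gene
hook; no efficiency calibration data is modelled.  Because normalization
subtracts the mean reference Cq within each sample, any sample-wide shift
(loading, global efficiency) cancels exactly — a property the tests assert.
Samples missing a reference gene are skipped with a log entry.  No
inter-plate calibration is applied; samples are assumed co-run.

## Cohort statistics

Groups of relative levels are compared two-sided with rank tests:

* **Mann–Whitney U** for independent groups.  Exact null distribution when
  the combined sample size is ≤ 12 and the pooled values are tie-free;
  otherwise the normal approximation with midrank tie correction and
  continuity correction (delegated to `scipy.stats.mannwhitneyu`).
* **Wilcoxon signed-rank** for patient-paired samples.  Zero differences
  are discarded; if all are zero the comparison is degenerate (p = 1,
  flagged).  For ≤ 12 informative pairs the p-value is computed in-package
  by full enumeration of the `2^n` sign patterns over midranks of |d| —
  this is the *conditional* exact test and remains exact under tied
  absolute differences, where generic tie-free tables do not.  Larger
  cohorts use the normal approximation with continuity correction.  The
  reported statistic is `min(W+, W−)`, so uniformly positive differences
  give W = 0.

Effect size is the ratio of group medians ("normal/tumor ratio"); a zero
denominator median yields a flagged +∞ sentinel.  The headline grouping
pools healthy controls with tumor-adjacent normal tissue ("normal"),
configurable to controls only; comparisons run overall and within germ /
non-germ histology strata, plus a paired comparison over patients with both
states.  Strata with fewer than 2 samples per side are skipped with a log
entry.  No multiple-testing correction is applied — the design is a
small-panel confirmation, not a genome-wide scan.  α defaults to 0.05 and
names the reporting threshold only.

## Co-expression clustering

Given a genes × samples matrix, gene pairs are scored by midrank Spearman
correlation (≥ 3 samples required; constant genes get ρ = 0 plus a flag
rather than NA, keeping the matrix complete).  The distance is

```
d = 1 − |ρ|
```

which is deliberately sign-blind: strong anti-correlation is as much
evidence of coordinated regulation as strong positive correlation, so
`d(ρ) = d(−ρ)` and ρ = ±1 both give d = 0.

Clustering is agglomerative **complete linkage**, implemented in-package
with a deterministic smallest-index tie-break so dendrograms are
reproducible across platforms; merges are stored in scipy linkage-matrix
layout (cross-checked against `scipy.cluster.hierarchy.linkage` in the
tests).  Tree fidelity is measured by the cophenetic correlation (Pearson
correlation of original vs cophenetic distances; 1.0 on ultrametric input;
degenerate all-equal inputs are flagged).  The number of clusters is chosen
by **mean silhouette width on the precomputed distance** over k = 2..10,
ties broken to the smallest k.  A single transparent index was preferred to
a 30-index ensemble vote: it is reproducible, and the question it answers
("is the block structure 2- or 3-way?") does not need an ensemble.
Dendrograms export to Newick with branch lengths equal to merge-height
differences.

## Synthetic data model

All tests run offline against generators with planted ground truth.

**Expression panels.**  Background TPM is i.i.d. log-normal per tissue
(natural-log mean 0.5, sd 1.0 by default — median ≈ 1.6 TPM with the heavy
right tail typical of expression data).  A base matrix shared by all
pseudo-databases is jittered per database by `exp(N(0, cross_db_noise_sd))`
(default 0.25).  `n_specific` planted genes get target-tissue TPM
`max(5, specific_fold × max of their other tissues)` (default fold 10).
Both planted elevation *and* background non-specificity are enforced
post-jitter by bounded rejection: a background gene that would reach 5 TPM
at ≥ `background_max_fold` (default 3) over every other tissue is redrawn.
This makes recovery tests sharp — the screen must return *exactly* the
planted set — instead of probabilistic: with a free log-normal background a
false positive occurs at a rate of roughly 10⁻⁴ per gene, which is real
biology (borderline genes do flip between database versions) but would make
an exact-recovery contract unsatisfiable.  The free background remains
available (`background_max_fold=None`) and is used to measure the
false-positive rate itself.

**qPCR cohorts.**  Default shape mirrors the studied cohort: 2 healthy
controls, 7 germ + 4 non-germ adjacent normals, 27 germ + 4 non-germ
tumors, 6 + 3 patient pairs.  Reference genes sit at a base Cq (default 17)
plus a per-sample N(0, 1) loading shift shared by all genes in the sample;
a target with true relative level L sits at `base + shift − log2(L)`;
planted suppression shifts germ-tumor Cq up by `log2(fold)` cycles; all
replicates get N(0, `cq_noise_sd`) noise (default 0.1 cycles, typical
technical-replicate scatter).

**Correlated blocks.**  Each block shares a latent per-sample factor z;
gene values are `ρ·z + noise_sd·sqrt(1 − ρ²)·ε`, so realized within-block
correlation rises with ρ and equals 1 exactly at zero noise.  An optional
fraction of each block is sign-flipped to plant anti-correlated members
that a sign-blind distance must still group correctly.

What the generators do **not** emulate: between-tissue correlation
structure in background expression, database-specific tissue coverage
(every pseudo-database has the same columns), gene-length or library-size
artifacts in TPM, qPCR efficiency differences between genes, and outlier
samples.  Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not robustness to every
artifact of real public expression data.

## Problem sizes and numerical choices

The default test and acceptance workloads use 100-gene × 20-tissue panels
(4 databases), 100-seed recovery sweeps, 2000 simulated null cohorts for
test calibration, 8-point matrices for linkage-oracle comparison and
26-gene × 100-sample matrices for clustering recovery — sizes chosen so
the full suite completes in well under a minute while keeping Monte-Carlo
bands tight.  Exact-test switchover is at combined n = 12 (enumeration is
cheap there and removes approximation error exactly where groups are
smallest).  Floating-point comparisons in panel I/O preserve input decimals
up to 10 places; correlation symmetry is enforced to 1e−12 and the
diagonal set exactly to 1.

## Known limitations

* The screen operates on whatever columns the panel ships; if a database
  lacks a tissue where a gene is active, the gene can be falsely called
  specific — the cross-database consensus exists precisely to dampen this,
  and it is why databases with few tissues inflate single-database calls.
* The qPCR model assumes 100% amplification efficiency for all genes unless
  per-gene efficiencies are supplied.
* Silhouette-based k selection assumes compact, separated clusters; for
  chained or nested structure the 2–3 range it reports should be read as a
  diagnostic, not truth.
* The Mann–Whitney normal approximation is conservative at very small n
  with α = 0.05 (measured type-I error ≈ 0.03–0.04 at n = 8 vs 8).
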