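# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pitmeth`, and what the synthetic cohorts do and do not establish
about real methylation-array data.

## Data model

The substrate is the beta value β = M/(M+U) of a CpG on an Illumina
EPIC-like array, in [0,1], with a companion detection p-value per
probe and sample. Probes come in two chemistry designs: type I probes span
nearly the full [0,1] range, while type II probes are compressed toward
0.5 — the distortion BMIQ corrects. Copy number is inferred from total
intensities (M+U), which scale with the local DNA copy number of the
tumour fraction of the specimen.

## Synthetic cohorts

The generator (`pitmeth.simulate`) emulates the statistical structure the
analysis relies on, at desk scale:

- **Genome**: 4 chromosomes × 50 Mb, centromere at 40% of length
  (`mini_genome`), giving distinct p/q arms while keeping runtimes in
  seconds. Arm definitions are emitted as 0-based half-open BED; manifest
  positions are 1-based (array convention) and converted at load.
- **Betas**: each probe is assigned an unmethylated / hemimethylated /
  methylated state (probabilities 0.45/0.10/0.45 — arrays are strongly
  bimodal). State means are (0.05, 0.5, 0.95) for type I and
  (0.15, 0.5, 0.85) for type II, reproducing the type II compression.
  Noise is Beta(μ·s, (1−μ)·s) with dispersion s = 50 by default: bounded
  support matching beta values, standard deviation ≈ 0.07 at μ = 0.5.
  The dispersion is pragmatic — no noise model for the real cohort exists
  to calibrate against.
- **Planted differential methylation**: the default design plants 100 DMP
  probes at |Δβ| = 0.3 in a 30-vs-12 contrast (20 APT + 10 PC vs 12
  benign). The shift direction is chosen away from the nearer [0,1]
  boundary (hypomethylation when the baseline mean is ≥ 0.5), so the
  planted effect size is realizable after clamping; the signed value is
  recorded in the truth object.
- **Batch effects** are additive shifts on logit(β), which keeps [0,1]
  support; slides are assigned round-robin across the sample list so batch
  is not confounded with group.
- **Copy number**: per-probe integer copy number (gain CN = 3,
  loss CN = 1) over planted arms or whole chromosomes, with carriers drawn
  per group at the designed prevalence. Intensities are a per-probe
  log-normal baseline multiplied by the purity-mixed ratio
  purity·CN/2 + (1 − purity) — so the expected log2 ratio of a clonal
  single-copy gain at purity 1 is log2(1.5) ≈ 0.585 — with log-normal
  measurement noise (SD 0.1 in log2 units). Chromothripsis-like events
  tile one chromosome with n alternating gain/loss segments (default 12).
- **Detection failures** occur at rate 5×10⁻⁴ per probe and sample,
  removing ≈ 2% of probes under the any-sample rule at a 42-sample cohort
  — comparable to routine array QC attrition.

What the simulation does **not** model: bisulfite-conversion chemistry,
two-channel fluorescence, probe cross-hybridisation, cell-type
heterogeneity, correlated CpG blocks (probes are independent given their
state), or copy-number effects on beta values. Passing recovery tests
therefore demonstrates that the *analysis machinery* is correct and
calibrated under its own assumptions, not that those assumptions capture
every property of FFPE tumour arrays.

## Preprocessing

- **Filter order**: SNP overlap → sex chromosome → detection p > 0.01,
  each probe tallied once under the first rule that removes it, so the
  report always reconciles. The detection rule removes a probe that fails
  in *any* sample — the strictest reading, consistent with keeping only
  CpGs shared and measurable across all specimens. Filtering is
  idempotent.
- **BMIQ**: per sample, a three-component beta mixture is fit by EM
  separately to each design type (moment-matching M-step, means
  initialised at 0.1/0.5/0.9, tolerance 1e-4 on log-likelihood, ≤ 100
  iterations). Type II probes are classified by maximum responsibility;
  the classification is then converted to value intervals (U = below the
  largest U-classified value, M = above the smallest M-classified value)
  so the final piecewise map — beta quantile matching on U and M, a linear
  dilation between the mapped boundaries for H — is globally monotone.
  Any degenerate fit (empty state, overlapping or inverted boundaries)
  falls back to the identity for that sample with a logged warning.
  Type I probes are returned bit-identical.
- **SVD screen**: singular vectors of the row-centred matrix; categorical
  covariates tested by Kruskal–Wallis on the component scores, continuous
  ones by the Pearson correlation test; constant covariates are skipped.
- **Batch correction** is the standard parametric empirical-Bayes
  location/scale model on logit(β) (clamped to [1e-3, 1−1e-3]): per-probe
  standardisation retaining the protected group term, normal prior on the
  batch location and inverse-gamma on the batch scale with hyperparameters
  by method of moments, posterior point estimates by the usual fixed-point
  iteration. The implementation agrees with Bioconductor `sva::ComBat` to
  ≈ 1e-6 on a shared fixture (asserted by test via Rscript). Protecting
  the biological group is an explicit, logged choice; a batch perfectly
  confounded with the protected group is an error.

## Differential methylation

Two-group contrasts on beta values (not M-values). Per probe:
Δβ = mean(A) − mean(B), pooled variance s² with d = n_A + n_B − 2 degrees
of freedom, shrunk toward a common prior s̃² = (d₀s₀² + d·s²)/(d₀ + d)
where (d₀, s₀²) are fit across probes by method of moments on log s²
(scaled-F model, trigamma inversion by Newton); t = Δβ/(s̃·√(1/n_A+1/n_B))
against Student t with d₀ + d degrees of freedom. With shrinkage off this
reduces exactly to the pooled two-sample t-test (asserted to 1e-10).
Significance uses the dual rule p ≤ 1.3×10⁻⁷ **and** |Δβ| ≥ 0.2, both
inclusive; 1.3×10⁻⁷ is 0.05/384,629, the Bonferroni genome-wide level for
the canonical post-QC EPIC probe pool. Contrasts are unadjusted for
covariates (batch effects are handled upstream). Zero-variance probes get
finite t through the prior (s₀ > 0).

## Clustering

"Most variable" means highest across-sample variance, ties broken by
manifest order via a stable sort. Sample distance is d = 1 − r (Pearson),
not 1 − |r| and not halved — the most common convention; anticorrelated
profiles are maximally distant (d = 2). Complete linkage guarantees
monotone merge heights; the dendrogram exports to Newick with branch
lengths from merge-height differences. PCA is the SVD of the probe-centred
matrix; separation against labels is the adjusted Rand index of a k-cluster
cut.

## Copy number

- **Log ratios**: per probe, log2(sample / median of ≥3 reference
  samples); the benign group is the default reference panel. Probes with
  zero reference median are dropped with a warning.
- **Binning**: fixed non-overlapping bins (default 500 kb on the
  mini-genome), bin value = median of member probes, empty bins missing
  and excluded from segmentation.
- **Segmentation** is circular binary segmentation: the candidate change
  is the interior arc [i, j) maximising the two-sample t statistic against
  the rest of the chromosome (an edge split is the degenerate arc), and it
  is accepted when its permutation p-value over 200 seeded shuffles is
  below 0.01; recursion continues inside the three resulting pieces until
  no acceptance or a piece falls below `min_bins` = 5. The arc form was
  chosen over a plain single-breakpoint split because a balanced gain/loss
  oscillation has equal flank means — a single-split statistic cannot even
  start on a chromothripsis chromosome. The permutation loop terminates
  early once the rejection count is settled (decision unchanged). For
  chromosomes longer than 300 bins the candidate grid is strided;
  recursion restores full resolution inside accepted pieces.
- **Arm calls**: a segment is gained at mean ≥ +0.1 and lost at ≤ −0.1
  log2 units (configurable stand-ins; the thresholds used by the original
  classifier workflow are not published). Per arm, the fraction of arm
  *basepairs* covered by gained (lost) segments decides the state at the
  50% cutoff — basepairs rather than bins, for robustness to uneven probe
  density. An exact tie is resolved toward the state with larger
  |mean|·length and logged; uncovered arms are balanced with a warning.
- **Cumulative profiles** report per-group gain/loss percentages per arm;
  an event is *frequent* only strictly above 50%.
- **Jaccard clustering** uses plain d = 1 − |A∩B|/|A∪B| on the factorized
  (arm, state) features; the square-root dialect is a monotone transform
  and yields the identical complete-linkage topology (asserted by test).
  Two event-free samples are at distance 0 by convention.
- **Oscillation flag**: ≥ 10 gain↔loss switches along one chromosome
  (balanced segments between unlike flanks count as a single switch). The
  threshold is an operational screen, configurable — chromothripsis has no
  consensus array-level definition. Detecting a 12-segment oscillation on
  a 50 Mb chromosome needs several bins per segment with decisive
  permutation margins; the desk-scale fixtures use 100 kb bins
  (≈ 40 bins per oscillation segment) for this analysis.

## GSEA

CpGs without a gene symbol are dropped; per gene the CpG with maximal |Δβ|
is kept (ties → smaller genomic position); genes are ranked by signed Δβ,
most positive first, score ties broken lexicographically. "Ranked by beta
values" is read as the contrast Δβ — the differential quantity of the
volcano analysis — an interpretation, recorded as such. The enrichment
score is the classic weighted (exponent 1) KS running sum; the null is
gene permutation (random same-size draws from the ranked universe), the
standard choice for preranked input. NES = ES / mean |null ES| of the
matching sign; the nominal p is the matching-sign tail count with the +1
convention and no lower-bound clamp, so it reaches the 1/(n_perm+1) scale;
BH adjustment runs across all tested sets and FDR ≤ 0.05 flags enrichment.
Sets are filtered to 15–500 members after intersection. Note the
attainable p floor at 1000 permutations is ≈ 2/1000, so collections of
more than ~25 sets cannot push a single set's BH-adjusted p below 0.05 on
permutation grounds alone; the desk-scale fixtures use 15-set collections.

## Pipeline

Stages run in the fixed order filter → intersect → normalize → SVD screen
→ batch-correct → {cluster, PCA, DMP} → GSEA, with the CNV branch off the
intensity matrix. All published parameter values are the configuration
defaults (top 5000 CpGs; p ≤ 1.3×10⁻⁷; |Δβ| ≥ 0.2; 50% arm cutoff; >50%
frequency; 1000 permutations; set sizes 15/500; FDR 0.05; detection
p 0.01) and are audited by a frozen-table test. The configuration is YAML
with unknown keys rejected; a first-surgery cohort filter is applied
before analysis when set. Each run writes a manifest with the software
version, configuration hash, seed, and per-output SHA-256 checksums;
identical configuration and seed reproduce identical checksums.

## Problem sizes

The test and acceptance fixtures use 4–20 k probes, 12–60 samples, 10–20
replicate cohorts, and 100–1000 permutations — large enough for the
planted-recovery margins above to be decisive, small enough that the whole
suite runs in a few minutes on one CPU.

## Known limitations

- BMIQ falls back to identity (with a warning) on degenerate mixture fits
  rather than attempting repair.
- Segmentation assumes exchangeable bins under the null; heavy-tailed bin
  noise would inflate the permutation threshold.
- No DMR calling, no cell-type deconvolution, no focal-event calling, no
  allele-specific copy number, and no ploidy re-centering: arm-level
  states are relative to the cohort reference panel.
- The GSEA p floor is permutation-limited (no analytic tail refinement).
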