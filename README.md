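# pitmeth

Genome-wide DNA-methylation and copy-number analysis for separating
**aggressive and metastatic pituitary neuroendocrine tumours (APT/PC)**
from benign ones, re-built as a tested, desk-scale Python pipeline.

Pituitary tumours that are refractory to standard therapy (APT) or that
metastasise (PC) are hard to recognise histologically. On Illumina
EPIC-style methylation arrays they show two robust genome-wide signatures:
widespread CpG hypermethylation relative to benign tumours, and heavily
disrupted copy-number profiles dominated by chromosome-arm gains and
losses, occasionally with chromothripsis-like gain/loss oscillation.
`pitmeth` implements the full analysis chain behind those observations and
ships a synthetic EPIC-like cohort generator with known ground truth, so
every stage is verifiable without access to patient data.

## What the pipeline computes

Starting from a beta-value matrix β ∈ [0,1] (probes × samples) with
detection p-values, a total-intensity matrix, a sample sheet, and a probe
manifest:

1. **Probe QC** — drop probes overlapping SNPs, on sex chromosomes, or with
   detection p > 0.01 in any sample; restrict to CpGs shared across inputs.
2. **BMIQ normalization** — per sample, fit a three-state
   (unmethylated/hemimethylated/methylated) beta mixture separately to
   type I and type II probes and map the type II U/M states onto the
   type I components by beta quantile matching, with a linear dilation of
   the middle state.
3. **Covariate screen and batch correction** — SVD components tested
   against slide, array, sex, and age; parametric empirical-Bayes
   (ComBat-style) location/scale adjustment on logit(β) with the tumour
   group protected. Verified against Bioconductor `sva` to ~1e-6.
4. **Unsupervised structure** — top-5000 most-variable CpGs,
   complete-linkage clustering on Pearson distance d = 1 − r, 3-component
   PCA, and an adjusted-Rand separation score against labels.
5. **Differential methylation** — per-CpG moderated t statistics
   (empirical-Bayes variance shrinkage across probes); a CpG is a DMP when
   p ≤ 1.3×10⁻⁷ (the Bonferroni genome-wide level 0.05/384,629) **and**
   |Δβ| ≥ 0.2.
6. **Copy number from intensities** — per-probe log2 ratios against a
   reference panel median, genomic binning, circular binary segmentation
   with a permutation stop rule, arm calls at a ≥50%-of-arm cutoff,
   cumulative group profiles (frequent = >50% of specimens), per-sample
   altered-arm burdens, Jaccard-distance clustering of the factorized
   gain/loss matrix, and a gain↔loss oscillation flag.
7. **Preranked GSEA** — CpGs collapsed to one signed Δβ per gene (max
   |Δβ|), ranked most-positive first, tested with the weighted
   Kolmogorov–Smirnov enrichment score against GMT collections
   (1000 gene permutations, set sizes 15–500, BH FDR ≤ 0.05).

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Generate a synthetic cohort (12 benign, 20 APT, 10 PC; 100 planted DMPs at
|Δβ| = 0.3; a chr1p gain planted in 60% of APT and a chr2 loss in 60% of
PC), then run three stages:

```sh
pitmeth simulate --out demo --n-probes 8000 --seed 3
pitmeth dmp      --in demo --out demo/dmp.csv
pitmeth cluster  --in demo --out demo/clust --top-k 5000
pitmeth cnv      --in demo --out demo/cnv --seed 3
```

which prints

```
wrote synthetic cohort (42 samples, 8000 probes) to demo
{"total": 100, "hyper": 41, "hypo": 59}
variance explained (%): 12.9, 2.6, 2.6
 group  median  min  max  n
   APT     1.0    0    1 20
    PC     1.0    0    1 10
benign     0.0    0    0 12
```

Reading the output: the DMP stage recovers the 100 planted differentially
methylated CpGs (41 hyper-, 59 hypomethylated in APT/PC — the planted
direction depends on each probe's baseline state); PC1 carries the planted
group signature (12.9% of variance against a ~2.6% noise floor); and the
arm-burden table shows the planted copy-number asymmetry — carriers in the
APT and PC groups have one altered arm, benign tumours none. The full
pipeline (`pitmeth run --config ...`) adds normalization, batch
correction, GSEA, Jaccard clustering, and a run manifest with per-output
checksums.

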