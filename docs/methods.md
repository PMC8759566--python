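# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices and the known limitations of `mirmet`.

## Problem setting

Bulk small-RNA sequencing of metastases is a mixture measurement: a liver
metastasis sample contains tumour cells *and* hepatocytes, immune cells and
blood. A miRNA that is simply abundant in the host organ (Mir-122 in liver)
will appear "up-regulated" in metastasis-vs-primary comparisons for purely
compositional reasons. The pipeline therefore couples a standard
negative-binomial differential-expression engine with a normal-tissue
background correction, and every stage is validated on synthetic data with
planted ground truth.

Tissue labels used throughout: pCRC (primary colorectal cancer), nCR (normal
colorectum), mLi/nLi (liver metastasis and adjacent normal liver), mLu/nLu
(lung equivalents), PM (peritoneal metastasis, which has no adjacent-normal
tissue).

## Read-level quality control

Reads pass four filters in a fixed order:

1. **Quality**: discard when fewer than half of the bases have Phred > 20
   (a read with exactly 50% high-quality bases is kept — every gate in this
   pipeline uses the strict comparison as printed).
2. **Adapter trimming**: the suffix starting at the leftmost position where a
   prefix of the 3' adapter aligns with ≥ 6 bases and ≤ 10% mismatches is
   removed; quality strings are trimmed in lockstep.
3. **Length**: discard below 18 nt (evaluated after trimming).
4. **Complexity**: discard when a single 1–3-nt motif, tandemly repeated,
   covers ≥ 80% of the read. "Repetitive element" has no standard
   quantitative definition in small-RNA QC tools; this tandem-coverage proxy
   was chosen because it is deterministic and exactly testable. The motif
   length bound and coverage threshold are configurable.

Retained reads are classified against the mature reference by 5'-anchored
comparison allowing ≤ 1 mismatch and ≤ 2 nt of 3' length difference — a
deliberate simplification of full isomiR handling (5' ends of mature miRNAs
are processed precisely; 3' ends are ragged). Sample gates: fail when
< 25% of retained reads fall in the 20–25 nt band, when > 75% of input reads
were discarded, or when < 10% of retained reads classify as miRNA. The
length- and miRNA-fraction gates denominate over retained reads, the discard
fraction over input reads, matching the natural reading of "reads were
discarded" vs "reads were identified". A study is excluded when more than
half its samples fail, or when any sample's contaminant-clade fraction among
classified miRNA reads exceeds 10% (configurable; "significant
contamination" has no published numeric threshold).

## Annotation merging and counting

Mature miRNA genes with near-identical sequences cross-map, so annotations
are merged before counting: two annotations are linked when their sequences
are identical, when one is a 5' sub/superstring of the other with ≤ 2 nt of
3' difference, or when they are within Hamming distance 1 at equal length;
groups are the connected components (union-find) of this relation. Each
clause is switchable, because the upstream tools that motivate the merge do
not publish their exact criterion. Reads matching two or more merged groups
under the classification tolerance are counted as ambiguous and dropped —
merging is the designed mechanism for cross-mapping, so residual ambiguity
is surfaced rather than fractionally assigned. RPM normalizes by
miRNA-assigned reads (reads per million mapped miRNA reads), the standard
small-RNA convention.

## Differential expression

Counts are modelled as y_ij ~ NB(mu_ij, alpha_i) with variance
mu + alpha·mu², log link, mu_ij = s_j · exp(b0 + b1·x_j), where x_j
indicates the case group and s_j is the median-of-ratios size factor
(computed over genes with all-positive counts, rescaled to geometric mean 1).

- **Dispersion**: per-gene method-of-moments on normalized counts within
  groups, alpha_i = (pooled excess variance)/mu_i², floored at 1e-8; a trend
  alpha_tr(mu) = a0 + a1/mu is fitted by trimmed non-negative least squares
  (10% trim, two passes); final dispersions blend genewise and trend on the
  log scale with weight 0.5. This replaces the Cox-Reid-adjusted shrinkage
  of heavier DE engines with a simpler estimator whose calibration is
  verified directly by simulation (type-I error 3–7% at nominal 5%,
  Kolmogorov–Smirnov vs uniform < 0.05, at n = 20 vs 20 and alpha = 0.1).
- **Wald test**: IRLS per gene (vectorized across genes; 2×2 normal
  equations in closed form), dispersion fixed, convergence at max |step|
  < 1e-8 within 100 iterations, Newton steps clipped to ±5 on the natural
  scale. SE from the Fisher information; z = LFC/SE; p = 2(1 − Φ(|z|)).
  Non-converged genes (typically all-zero in one group) are flagged, get
  NaN p-values and are excluded from the BH denominator, as are genes with
  all-zero counts in both groups.
- **LFC shrinkage**: posterior mean under a zero-centred normal prior,
  LFC' = LFC·σ²/(σ² + SE²), with σ² = max(mean(LFC²) − mean(SE²), 0.0625)
  estimated from the contrast. This is the simplest empirical-Bayes
  normal-prior shrinkage; it matches the qualitative contract (high-variance
  estimates pulled hard, precise ones barely moved) without adopting any
  particular heavier prior.
- **Relevance filter**: FDR < 0.05, |LFC| > 0.58 (≈ 1.5-fold) and mean
  expression > 100 RPM in at least one compared tissue — all strict. The
  filter applies to the shrunken LFC (the quantity reported); a config flag
  switches to the MLE.
- **VST**: closed-form variance-stabilizing transform implied by the fitted
  trend, vst(n) = log2((1 + a1 + 2·a0·n + 2·√(a0·n·(1 + a1 + a0·n)))/(4·a0)),
  monotone and asymptotically log2(n) + const; falls back to log2(n+1) with
  a warning when a0 ≤ 0.

## Background correction

Per metastatic site, a signed background set is built from two contrasts —
nSite vs nCR and nSite vs pCRC — oriented so that positive always means
"higher at the site's organ than in colorectal tissue". A miRNA enters the
set (with its sign) when it passes the full relevance filter in either
contrast; requiring the full filter, not just FDR, keeps one relevance
standard across the pipeline. A site call whose sign matches a background
entry is suppressed; opposite signs never suppress. PM, lacking adjacent
normal tissue, uses the signed union of the liver and lung sets. The
combination rule across the two contrasts (union by default) and the
alternatives (single-contrast, intersection) are config-exposed because the
choice is genuinely open; union is the conservative default for a filter
whose purpose is to avoid false metastasis calls.

## Cell-type-specific miRNAs

A curated marker list (shipped as an editable TSV; the packaged file is a
synthetic stand-in labelled as such) is filtered to miRNAs with per-tissue
mean RPM > 100 in at least one tissue. Heatmap input is the per-tissue mean
of per-miRNA z-scores of RPM across samples (z across samples, not across
tissue means — the per-sample variant retains within-tissue spread and the
tissue means are recoverable from it). PCA is computed on VST values with
features centred and scaled (correlation PCA, matching a correlation-circle
reading of loadings; covariance PCA available by flag); loadings are
orthonormal, components ordered by eigenvalue, and each loading vector's
largest-magnitude entry is made positive for sign stability. Group
comparisons use Welch's two-sided t-test with Satterthwaite degrees of
freedom, implemented directly from the formulas and cross-checked against an
independent implementation to 1e-10.

## Gene-set enrichment

S_miRNA = −log10(FDR)·sign(LFC) per miRNA (FDR floored at 1e-300; the
post-background-correction FDR is used, with a flag for raw p);
S_mRNA(g) = Σ S_miRNA over the gene's predicted regulators, duplicates
counted once, untargeted genes scoring an informative 0. Gene sets are
scored by logistic regression of membership on S_mRNA over the universe
(interaction-map genes ∪ collection members), fitted by Newton/IRLS with
likelihood-guarded step-halving (tolerance 1e-8); under quasi-separation the
slope then diverges monotonically in the correct direction and the set is
flagged with p = NA rather than oscillating. BH correction is applied within
each collection.

The published description of the background correction feeding this analysis
("reducing LFC towards 0 and increasing FDR toward 1, depending on the
magnitude of the normal background") fixes limits but not a formula. The
implemented interpolation — r = min(1, |LFC_bg|/|LFC|), LFC' = LFC·(1−r),
FDR' = FDR + r·(1−FDR), applied only for significant same-sign backgrounds —
satisfies the monotonicity constraints, reaches the null exactly when the
background matches the foreground, and is the identity when background is
absent or insignificant. It is config-replaceable.

## qPCR

dCq = mean(target replicates) − mean(reference replicates) per sample
(replicates are technical and unpaired across assays, so they are averaged
before differencing); lower dCq = higher expression. Groups are compared by
Welch's two-sided t-test. dCq is exactly invariant to per-sample plate
shifts.

## Synthetic-data generator

The generator emulates the study conditions and is the source of every test
input:

- **Counts**: seven tissues at the study's post-QC dataset counts
  (pCRC 120, nCR 25, mLi 35, nLi 20, mLu 28, nLu 10, PM 30); six cell-type
  expression programs (epithelial, hepatocyte, pneumocyte, lymphocyte,
  myeloid, erythroid); per-sample cell-type proportions drawn from
  Dirichlet(concentration × tissue mean) with concentration 50 by default —
  within-tissue composition variance is not published, so the concentration
  is a free parameter chosen to give visible but not overwhelming
  heterogeneity; baseline abundances lognormal over ~4 decades around
  400 RPM; 30 marker miRNAs expressed ~300-fold above their off-target level;
  per-miRNA NB dispersions lognormal around 0.15 (typical for bulk
  miRNA-seq); library sizes uniform on [1e6, 5e6]. Metastasis effects are
  log2 multipliers applied at the site; background effects apply at the site
  *and* its adjacent normal, which is exactly the compositional artefact the
  filter must remove. Liver/lung normals are parenchyma-dominated and the
  corresponding metastases carry a ~25% host-organ admixture.
- **Reads**: category counts follow largest-remainder rounding and sum
  exactly; miRNA reads are a mature sequence ± ≤ 2 nt of 3'
  truncation/extension plus adapter at high quality; low-quality reads have
  60% of bases at Phred ≤ 20; short reads have 10–17 nt inserts;
  low-complexity reads are mono-/di-nucleotide repeats; "other RNA" reads
  come from a fixed fragment panel that doubles as the QC's other-RNA
  reference. References are generated with ≥ 3 mismatches over the first
  18 bases pairwise, which guarantees a read with the allowed 3' variation
  and 1 mismatch can never match two references.
- **Interactions/sets**: each miRNA receives a fixed number of uniform
  random targets; miRNAs planted as up-regulated target genes of planted
  "suppressed" sets with 8-fold higher probability.
- **qPCR**: per-sample RNA-input offsets cancel in dCq; the target assay
  carries N(0, sd) biological noise plus the planted group difference; two
  technical replicates per assay with N(0, 0.15) noise.

What the generator does **not** emulate — isomiR biology beyond 3'
raggedness, sequencing-error substitution profiles, batch effects between
studies, GC/length biases, correlated dispersion structure — bounds what
passing tests show about real data: they validate the statistical machinery
and the filtering logic, not robustness to every real-world artefact.

## Problem sizes used in validation

The validation suite and the acceptance script use: 10,000-read QC samples
over 20 seeded configurations; 2,000-gene null matrices at n = 20 vs 20 and
alpha = 0.1 (10 seeds) for calibration; planted effects ±1/±1.5 at
200/1000 RPM, n = 15/group, alpha = 0.05 (the recovery-benchmark dispersion)
over 10 seeds; the full seven-tissue design with 10 metastasis-only,
10 background-only and 10 dual effects per organ site over 20 seeds for the
background filter; 1,000-gene universes with 50 sets for enrichment recovery
(20 seeds) and a 1,000-permutation logistic null. These sizes give stable
rates while keeping a full validation run in minutes on one core.

## Known limitations

- The DE engine omits Cox-Reid dispersion adjustment, outlier replacement
  and independent filtering; with very small groups (n < 5) its type-I
  control degrades faster than heavier implementations.
- The annotation-merge relation is a calibrated stand-in; reproducing a
  specific published group count on a real reference may require adjusting
  its clauses.
- The background filter is set logic, not deconvolution: it suppresses
  genuine metastasis effects that coincide in direction with a host-organ
  background (the "dual" case), by design.
- UMAP coordinates depend on the library version; only label-separation
  statistics, never exact coordinates, are treated as meaningful.
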