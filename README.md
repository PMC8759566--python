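# mirmet

Identification of metastasis-associated miRNAs from bulk small-RNA
sequencing of colorectal cancer and its metastases.

Bulk sequencing of a metastasis measures a cell mixture: tumour cells plus
the host organ's parenchyma, immune cells and blood. Differential-expression
analysis of liver metastases (mLi) against primary tumours (pCRC) therefore
reports two very different kinds of signal — genuine metastasis-associated
regulation, and host-tissue miRNAs (hepatocyte Mir-122, erythrocyte Mir-451,
…) carried along by composition. `mirmet` implements the full analysis chain
that separates them, for researchers analysing small-RNA-seq of primary
tumours, metastases and adjacent normal tissues:

- **Read QC** — quality / adapter / length / complexity filters with
  sample-level exclusion gates (< 25% of reads in the 20–25 nt miRNA band,
  > 75% discarded, < 10% miRNA) and study-level gates (> 50% failed samples,
  clade-level contamination).
- **Quantification** — merging of near-identical mature annotations
  (union-find over a sequence-similarity relation), tolerant read counting,
  RPM normalization.
- **Differential expression** — negative-binomial Wald test
  (y ~ NB(mu, alpha), var = mu + alpha·mu², log link, median-of-ratios size
  factors, method-of-moments dispersions shrunk to a trend a0 + a1/mu),
  Benjamini–Hochberg FDR, empirical-Bayes LFC shrinkage, and the
  physiological-relevance filter FDR < 0.05, |log2FC| > 0.58, > 100 RPM.
- **Background correction** — signed sets of miRNAs differentially expressed
  between each metastatic site's normal organ and colorectal tissue; site
  calls in the same direction as their organ background are suppressed;
  peritoneal metastases use the union of the liver and lung backgrounds.
- **Cell-type analysis** — marker-miRNA z-score matrices, correlation PCA
  with loadings, Welch t-tests on VST means.
- **Gene-set enrichment** — S_miRNA = −log10(FDR)·sign(log2FC), per-gene
  S_mRNA sums over predicted targeting, logistic regression of set
  membership on S_mRNA.
- **qPCR validation** — dCq against a reference miRNA and Welch comparison.
- **Synthetic data** — a seeded generator producing FASTQ read populations,
  count matrices with planted metastasis/background effects, interaction
  maps, gene sets and Cq tables, each with a truth record, so the entire
  pipeline is testable without any external download.

See `docs/methods.md` for the models, default parameters and their
rationale.

## Worked example

Simulate a study-scale cohort (268 samples across seven tissues, 220
miRNAs) with 10 metastasis-only, 10 background-only and 10 dual
(metastasis + background) effects planted at the liver site, then run the
mLi-vs-pCRC contrast and the background filter:

```python
from mirmet import synthetic_data as sd
from mirmet import diffexp, background as bg

design, _ = sd.background_validation_design(seed=0)
cm, truth = sd.simulate_counts(design)

de_mli = diffexp.de_analysis(cm, "mLi", "pCRC")
bset = bg.build_background_set(
    diffexp.de_analysis(cm, "nLi", "nCR"),
    diffexp.de_analysis(cm, "nLi", "pCRC"), site="mLi")
calls = bg.apply_background_filter(de_mli, bset, "mLi")

print("relevant before background:", int(calls.relevant_before_bg.sum()))
print("suppressed by background:  ",
      int((calls.relevant_before_bg & calls.suppressed_by_background).sum()))
print("final calls:               ", int(calls.final_call.sum()))
```

```
relevant before background: 37
suppressed by background:   27
final calls:                10
```

Thirty-seven miRNAs pass the relevance filter in the raw contrast, but 27 of
them move in the same direction as the liver background (planted
background-only and dual effects, plus hepatocyte markers riding on the
host-organ admixture) and are suppressed. The 10 final calls are exactly the
10 planted metastasis-only miRNAs. The top of the table:

```
          mean_rpm_case  mean_rpm_control  LFC_mle  LFC_shrunk     SE  fdr
Mir-7_5p        250.685           619.746   -1.309      -1.294  0.078  0.0
Mir-1_5p        765.950           313.295    1.280       1.265  0.078  0.0
Mir-9_5p       2923.668          1237.755    1.227       1.214  0.076  0.0
```

Each row reports the mean RPM in the two tissues, the maximum-likelihood and
shrunken log2 fold changes with the Wald standard error, and the BH FDR —
the planted |log2FC| of 1.2 is recovered within a few hundredths.

A command-line interface mirrors the library
(`mirmet simulate|qc|de|background|celltype|gsea|qpcr|report`); run
`mirmet --help` for the options.

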