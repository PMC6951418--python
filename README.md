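# elincnet

Classify intergenic long non-coding RNAs (lincRNAs) into
**enhancer-associated (elincRNAs)** and **canonical, promoter-like
lincRNAs** from chromatin signatures.

Enhancer-associated lincRNAs are transcribed from regions bearing
enhancer-like chromatin — high H3K4me1 and low H3K4me3 at the transcription
start site (TSS) — while canonical lincRNAs carry promoter-like marks (the
reverse). `elincnet` implements the full computational pipeline for telling
the two apart:

1. **High-confidence labeling.** For each expressed lincRNA (FPKM ≥ 0.5)
   with at least one H3K4 mark signal ≥ 10, the H3K4me1/H3K4me3 read-count
   ratio in the ±500 bp TSS window is compared against an empirical null
   built by independently permuting the two count vectors across
   transcripts (10,000 rounds). Transcripts ranking strictly above the 95th
   null percentile are labeled elincRNAs, strictly below the 5th canonical.
2. **Feature extraction.** For the TSS window and the gene body
   (TSS+500 bp → TTS), per-assay statistics in [0, 1]: base-coverage
   fraction for histone marks, transcription factors, CpG islands and
   repeats; mean β for DNA methylation.
3. **Regularized regression.** A linear model
   y = β₀ + Σⱼ βⱼ xⱼ with responses y = ±1 is fit by minimizing the
   penalized residual sum of squares

   RSS/(2n) + λ Σⱼ [ ½(1−α) βⱼ² + α |βⱼ| ]

   using cyclical coordinate descent with soft-thresholding (α = 1 lasso,
   α = 0 ridge, elastic net in between). λ is chosen on a log-spaced,
   warm-started path by 10-fold cross-validated MSE; α by comparing the
   best CV error over a grid. A transcript with score > 0 is called an
   elincRNA, < 0 canonical; |βⱼ| is the feature's contribution rate.
4. **Evaluation and validation.** Stratified 10-fold CV with pooled
   out-of-fold scores (accuracy, trapezoid ROC AUC, step-interpolated PR
   AUC); independent test labels from transcripts covering more than half
   of an annotated enhancer or promoter; and a chromatin-state
   randomization test with length-matched random placements and add-one
   empirical p-values.

A synthetic-data generator produces toy genomes with this exact planted
structure so the whole pipeline runs and is tested at desk scale without
any downloads.

## Worked example

The bundled fitted model (a lasso over TSS/gene-body epigenetic features of
mouse embryonic stem cell lincRNAs) is

y = 2.0860 + 5.79·TSS_DNAme + 3.16·TSS_H3K4me1 + 0.53·Body_DNAme
  + 0.46·Body_H3K122ac − 5.17·Body_H3K36me3 − 4.13·TSS_H3K9ac
  − 0.87·TSS_H3K4me3

```python
>>> import pandas as pd
>>> from elincnet import PUBLISHED_MODEL, score, classify
>>> x = pd.Series({"TSS_DNAme": 0.6, "TSS_H3K4me1": 0.7, "Body_DNAme": 0.5,
...                "Body_H3K122ac": 0.3, "Body_H3K36me3": 0.1,
...                "TSS_H3K9ac": 0.2, "TSS_H3K4me3": 0.1})
>>> round(score(PUBLISHED_MODEL, x), 4), classify(PUBLISHED_MODEL, x)
(6.745, 'elinc')
```

A methylated, H3K4me1-rich TSS pushes the score far above zero (elincRNA);
flipping the profile to promoter-like marks gives −3.24 (canonical).

The command-line pipeline on synthetic data:

```sh
$ elincnet simulate --seed 11 --n-per-class 60 --outdir simdata
wrote 120 transcripts and tracks to simdata
$ elincnet label --indir simdata --out labels.tsv --nperm 2000 --seed 12
labels: {'unlabeled': 96, 'canonical': 13, 'elinc': 11}
$ elincnet features --indir simdata --out features.tsv
features: 120 transcripts x 22 columns
$ elincnet train --features features.tsv --labels labels.tsv \
    --out model.json --alpha auto --folds 5 --seed 13
alpha=0.25 lambda=0.02809 nonzero=18/22
$ elincnet evaluate --features features.tsv --labels labels.tsv \
    --out metrics.tsv --alpha 1.0 --folds 5 --seed 14
accuracy=1.000 auc_roc=1.000 auc_pr=1.000
```

The permutation labeler finds the ratio extremes (11 elinc, 13 canonical of
120), the trained model separates the planted classes perfectly, and
`elincnet predict` then scores every remaining transcript. `elincnet run
--config <file>` chains all stages from a flat key=value config and writes
a manifest with the config hash and seed for reproducibility.

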