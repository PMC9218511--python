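# toxgnet

Toxicity-category prediction from partial-correlation gene networks of
chemically exposed pluripotent stem cells.

## The problem

Chemical hazard assessment traditionally relies on animal studies or on
cancer-derived cell lines, both of which translate poorly to normal human
physiology. An alternative is to expose undifferentiated human pluripotent
stem cells — which express an unusually broad slice of the transcriptome,
including the transcription factors that sit upstream of toxicity-response
pathways — to graded doses of a chemical and read the perturbation off the
transcriptome. `toxgnet` implements the full computational side of such an
assay for a panel of 24 reference chemicals annotated in six toxicity
categories (neurotoxin NT, hepatotoxin HT, cardiotoxin CT, glomerular
nephrotoxin GT, tubular nephrotoxin TT, non-genotoxic carcinogen NGC; a
chemical may be positive in several).

## The method

1. **Dose setting.** ATP-assay viability at 10 serial three-fold dilutions
   is fit with a three-parameter log-logistic curve
   f(x) = d / (1 + exp(b (ln x − ln e))); the inhibitory concentration
   IC_p = e (q/(1−q))^{1/b}, q = p/100, sets the maximum exposure dose
   between IC0.1 and IC50, then diluted two-fold (1/1 … 1/16) plus vehicle.
2. **Expression.** RNA-seq counts over a transcription-factor gene panel
   are filtered (CPM cutoff from min.count = 30 at the median library
   size), normalized to log2 counts per million, batch-corrected with a
   per-gene linear model, and summarized per (chemical, dose) condition as
   the log2 fold change (LFC) against the matched same-solvent vehicle.
   Moderated t-statistics (empirical-Bayes shrunken variances,
   Benjamini–Hochberg FDR) call differentially expressed genes.
3. **Feature genes and networks.** A PCA of the 120-condition LFC panel
   yields 20 feature genes (the two most positive and two most negative
   loadings of the top five PCs). For each chemical, the covariance of its
   five dose-level LFC vectors over those genes feeds an L1 graphical lasso
   along a 1000-point penalty path; the precision matrix Θ minimizing the
   BIC (EBIC with γ = 0) is selected and converted to the 190 partial
   correlations ρ_ij = −Θ_ij/√(Θ_ii Θ_jj) — one fixed-order edge vector per
   chemical.
4. **Classification.** Each category is a binary SVM task over the
   24 × 190 edge matrix, evaluated by leave-one-out cross-validation: per
   fold the features are ranked by a two-sided Welch t-test on the training
   chemicals only, the top k are kept (k swept 1..190), features are
   standardized by training statistics, and a kernel/hyperparameter grid
   (linear, polynomial, RBF) is searched. The maximum accuracy
   100·(TP+TN)/(TP+TN+FP+FN) over the grid and the AUC of that
   configuration are reported.
5. **Transfer to iPS cells.** Edge vectors from a second, unlabeled cell
   line (qPCR ΔΔCT profiles of the same 20 genes) are predicted
   transductively: train on the labeled ES-cell instances, pool the
   standardization statistics over both domains, and score each chemical's
   iPS instance (or concatenate both domains into 380 features under plain
   LOOCV).
6. **Significance.** Every headline accuracy is compared against ten
   replicates of the identical sweep on uniform-random features by a
   one-sided one-sample t-test, t = (actual − mean)/(SD/√10) on 9 degrees
   of freedom.

A `synthetic_data` generator (`toxgnet.simulate`) reproduces the whole
study design — 24 chemicals × 6 doses × 2 replicates × 2 timepoints = 576
samples — with category-structured gene-network ground truth, so every
stage is testable without any download.

## Worked example

```python
import numpy as np
from toxgnet import classify, feature_net, pipeline, simulate
from toxgnet.io import load_label_table, positive_mask

labels = load_label_table()                       # packaged 24-chemical table
truth = simulate.make_truth(seed=7, timepoints=(24,))
sheet = simulate.gen_design(timepoints=(24,))     # 24 x 6 x 2 design, 288 samples
counts = simulate.gen_counts(sheet, truth, n_genes=300, seed=8)

lfc = pipeline.counts_to_lfc(counts, sheet, timepoint=24)
panel = feature_net.pca_select_genes(lfc)         # 20 feature genes
_, edges = pipeline.lfc_to_edge_features(lfc, panel=panel,
                                         nlambda=100, tol=1e-3, max_iter=50)

y = positive_mask(labels, "NT").to_numpy().astype(int)
run = classify.loocv_sweep(edges, y, kernels="reduced", category="NT")
base = classify.random_baseline(y, n_features=190, n_rep=10, seed=0,
                                kernels="reduced")
sig = classify.significance_test(run.max_accuracy, base.max_accuracies)
```

printed for this seed:

```
panel: ['PG07', 'PG08', 'G0116', 'G0071'] ... (20 genes)
edge features: (24, 190)
NT: max accuracy 95.8%  AUC 0.98  kernel linear(C=1)  k=14
random baseline: mean 85.4%  SD 10.62
one-sided t-test: t=3.10 (df=9)  p=0.0064
```

The neurotoxin task is recovered from the planted network signal at 95.8%
LOOCV accuracy (AUC 0.98) — significantly above the 85.4% that the
identical sweep extracts from pure noise (selection optimism over the
kernel/k grid), p < 0.01 on the 9-df baseline t-test.

The same steps are available from the shell via the `toxgnet` entry point
(`toxgnet simulate`, `doses`, `preprocess`, `select-genes`, `networks`,
`predict`, `transfer`, `report`); every subcommand echoes its full
configuration to standard error.

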