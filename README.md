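# tcrspec

Supervised prediction of the antigen specificity of single T cells from
TCR CDR3 sequences and cell-level covariates.

## The problem

Droplet-based single-cell immune profiling measures, for every captured
T cell, the reconstructed CDR3 loops of the TCR α- and β-chains, per-cell
mRNA and surface-protein UMI counts, and the UMI counts of barcoded
peptide-MHC multimers ("dextramers") from a panel of antigens. Those
pMHC counts reveal which antigen, if any, the cell's TCR binds — turning
one experiment into a large supervised training set for TCR-specificity
prediction. `tcrspec` provides the full modeling stack for this setting:

- **Data preparation** faithful to screen semantics: UMI-count
  binarization into binding events (count > 10 **and** ≥ 5 × the highest
  negative-control count; the largest passing count wins), doublet
  exclusion via multi-allele chains, clonotype collapsing and
  down-sampling, antigen-frequency filtering, shuffled-negative
  construction for database-style (IEDB/VDJdb-like) pair sets, and
  clonotype-aware train/validation/test splits that prevent sequence
  leakage.
- **Models**: a *categorical antigen model* p(y | s, c) = softmax(f(s, c))
  over the antigen panel plus a non-binding class, and an
  *antigen-embedding pair model* p(bind | s_TCR, s_antigen) for
  database-style pairs. Sequences enter as one-hot, BLOSUM50, or a
  learned 1×1-convolution embedding of BLOSUM50 channels; the
  sequence-embedding stack can be a bidirectional GRU/LSTM,
  self-attention, plain or inception-style convolutions, a NetTCR-style
  multi-kernel max-pooling block, or a linear pass-through; covariates
  (donor one-hot, total-count size factor, log1p negative-control and
  surface-protein counts) join at the final dense block.
- **Count regression**: multi- or single-task models of the raw pMHC
  counts with exponentiated outputs trained on mean squared logarithmic
  error, scored by R² on log(1+x) counts.
- **Training protocol**: Adam, validation-plateau learning-rate decay,
  early stopping with best-in-terminal-window checkpoint selection,
  seeded clonotype-fraction or leave-one-donor-out cross-validation, and
  Welch / Wilcoxon model-comparison tests.
- **A synthetic-screen generator** that plants per-antigen CDR3β motifs
  with known ground truth and emulates clonotype structure, donor
  effects, log-normal size factors, negative-binomial counts and cell
  doublets — so every stage above is testable without any downloads.

The neural models run on a small, self-contained numpy autograd engine
(float64, fully deterministic, no framework dependency).

## Worked example

Simulate a screen of 1,000 clonotypes (4 antigens, 4 donors, 5%
doublets), prepare it, train a convolutional categorical model with a
donor covariate, and evaluate on held-out clonotypes:

```bash
tcrspec simulate -c sim.yaml -o sim --seed 0
# wrote 1745 cells to sim/screen_binarized_matrix.csv
tcrspec prepare --matrix sim/screen_binarized_matrix.csv \
    --clonotypes sim/screen_clonotypes.csv -o prep --min-clonotypes 50 --seed 0
# kept 1658/1745 cells, 4 antigens
tcrspec train --prepared prep --model-config model.yaml -o zoo/conv_donor --seed 0
# trained 16 epochs; selected epoch 16
tcrspec evaluate --model-dir zoo/conv_donor --prepared prep -o report.json
```

`report.json` then holds the test-set metrics on the 418 held-out-clonotype
cells:

```json
{
  "auc_roc": 0.9975,
  "auc_macro": 0.9965,
  "auc_per_antigen": {"antigen_0": 0.9966, "antigen_1": 1.0,
                      "antigen_2": 0.9998, "antigen_3": 0.9998},
  "f1": 0.9689, "fnr": 0.0311, "fpr": 0.0078, "n_test": 418
}
```

`auc_roc` is the micro-averaged one-vs-rest AUC over the panel plus the
non-binding class; the planted motifs are almost perfectly recovered.
F1/FNR/FPR are computed at the argmax prediction. Imputation then
labels cells from sequence (and optionally zeroed covariates):

```bash
tcrspec impute --model-dir zoo/conv_donor \
    --matrix prep/prepared_binarized_matrix.csv -o imputed.tsv
# imputed 1658 cells (full covariates)
```

The configs used above (`sim.yaml`, `model.yaml`) are plain YAML, e.g.

```yaml
# model.yaml
model:
  chain_mode: trb
  head: categorical
  seq_layer: {kind: conv, width: 16}
  embedding: {mode: learned}
  covariate_set: [donor]
train:
  max_epochs: 25
  batch_size: 128
```

The same workflow is available as a library (`tcrspec.simulate_screen`,
`tcrspec.run_cross_validation`, …); see `docs/methods.md` for the model
and generator details.

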