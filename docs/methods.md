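# Methods

This note documents the models, the data-preparation semantics, the
synthetic-screen generator, and the numerical and design choices behind
`tcrspec`.

## Binarization of pMHC counts

A cell is called a binder of an antigen iff that antigen's dextramer UMI
count is (i) strictly larger than 10 and (ii) at least five times the
highest UMI count across the cell's negative-control dextramers. When
several antigens pass, the one with the largest count is the single
binder; ties among equal passing counts break to the lowest panel index
(a convention — ties are vanishingly rare in real counts). The "larger
than 10" threshold is strict and the "five times" threshold is
inclusive, and both boundaries are covered by tests against a per-cell
brute-force oracle.

## Data preparation

Processing order for single-cell screens: (i) doublet removal, (ii)
clonotype assignment and down-sampling, (iii) antigen selection, and —
only for single-antigen binary tasks — (iv) majority-class
down-sampling.

- **Doublets.** Any cell with more than one reconstructed allele for
  either chain is excluded; a droplet holding two cells would otherwise
  pair one cell's TCR with the other's binding read-out.
- **Clonotypes.** A clonotype file, when supplied, is authoritative;
  otherwise cells are assigned by exact (CDR3α, CDR3β) string identity,
  and database records by exact CDR3β identity. Clonotypes are capped
  at 10 cells (databases: 1 observation) to stop large clones from
  dominating.
- **Antigen selection.** Antigens need at least 100 unique binder
  clonotypes (configurable). Cells bound to a dropped antigen are
  *removed*, not relabeled as non-binders: the non-binding class must
  mean "no dextramer passed thresholds", not "bound an excluded
  antigen".
- **Negative pairs** for database-style data are uniform seeded draws,
  without replacement, from the unobserved (TCR, antigen) combinations
  over the positive TCR pool — the in-silico-shuffling construction.
  Train and test negatives are generated separately from their
  respective positives.
- **Splits** operate on clonotypes, never cells: 25% of clonotypes form
  the test set (exactly `round(0.25 n)`), and 10% of the remainder the
  validation set. Leave-one-donor-out folds hold out every cell of one
  donor and are used for models without a donor covariate. Splits are
  functions of (cells, seed) only, so all model configurations compared
  under one seed see identical folds.
- **Covariates.** Design-matrix blocks in fixed order: donor one-hot;
  total mRNA count divided by the *training-set* mean total count (the
  size factor; freezing the mean on the training part avoids leakage);
  log(x+1)-transformed negative-control counts; log(x+1)-transformed
  surface-protein counts. A zero covariate vector is legal at inference
  (imputation without covariates).

## Models

All models share three blocks.

**Amino-acid embedding.** Sequences are padded to fixed lengths (40 per
CDR3 chain, 80 for concatenated α+β, 25 for antigen peptides); PAD
positions encode to all-zero channel vectors in every mode, which keeps
all layer families shape-compatible without masking; masks are still
carried for diagnostics. Channels are one-hot indicators or raw BLOSUM50
rows restricted to the 20 standard residues (raw integer scores, no
rescaling — an optional min–max flag exists but defaults off; the
bundled matrix is parsed from NCBI flat format). The default *learned*
embedding is a trainable 1×1 convolution (position-wise affine map,
20 → 5 channels) on the BLOSUM50 encoding, shared across every sequence
input of a model. Non-standard residue codes are rejected by default
(surfacing data errors early) with an opt-in mapping to zero vectors.

**Sequence-embedding stack.** One of: bidirectional GRU or LSTM
(position-wise states; a bidirectional layer emits forward-scan states
followed by backward-scan states, doubling the positional axis),
multi-head self-attention (default 1 block, 4 heads, key dim =
width/4, deliberately without positional encodings so the network sees
no built-in sequence order), plain convolutions (odd kernels,
same-padding), inception-style parallel convolutions (kernels {1,3,5},
channel-concatenated), a NetTCR-style block (parallel sigmoid
convolutions, kernels {1,3,5,7,9}, 16 filters each, global max-pool per
filter), a linear pass-through, or no sequence input at all
(covariates-only). A residual connection spans every layer; when widths
differ the skip path is a learned linear projection, and when a
bidirectional layer doubles the positional length the skip input is
repeated along positions first. Latent reduction: recurrent stacks
concatenate the final state of each scan direction (2 × width,
length-independent); convolutional/attention/linear stacks flatten
positions × channels (well defined at fixed padded lengths); the
NetTCR block max-pools each filter over positions.

**Heads.** The latent vector and the covariate vector are concatenated
and passed through optional ReLU dense layers into: a softmax over
n_antigens + 1 classes (categorical), a single sigmoid node (binary,
also used by pair models), or exponentiated outputs (counts; strictly
positive by construction). Pair models embed TCR (40) and antigen (25)
either in separate stacks whose latents concatenate, or as one appended
65-position sequence in a single stack. Multi-task count models share
the whole trunk across an n_antigens-wide output; single-task builders
create one independent 1-output model per antigen.

Nonlinearities are ReLU in dense/convolutional blocks and the standard
tanh/sigmoid gates in recurrent cells. Initialization is a seeded
Glorot-style uniform fan-based scheme; parameters materialize lazily in
a fixed forward order, so a seed fully determines them. Optional
dropout on the dense block defaults to 0. Exact layer depths and widths
are configuration, not claims: defaults are depth 1, width 16.

The models run on a small reverse-mode autograd engine over float64
numpy arrays written for this package: deterministic, dependency-free,
and fast enough for screen-scale linear/convolutional models (recurrent
and attention stacks are supported and tested, but train more slowly
and are sized accordingly in examples).

## Optimization and evaluation

Training minimizes cross-entropy (classification) or mean squared
logarithmic error on exponentiated outputs (counts; computed in the
stable softplus form log(1+e^a)) with Adam on seeded minibatches, with
an optional steps-per-epoch cap. When the validation loss fails to
improve for `patience` epochs the learning rate is multiplied by
`lr_reduce_factor`; after 2 × patience non-improving epochs training
stops (or at `max_epochs`). The returned parameters are the checkpoint
with the lowest validation loss within the terminal window of
`window_n` epochs, kept in a ring buffer of per-epoch snapshots. The
2 × patience stopping rule is this package's concrete rendering of
"stop when the validation loss no longer decreases"; the window
selection is asserted by tests directly from the history.

Classification metrics: AUC ROC (micro-averaged one-vs-rest for the
categorical head; macro and per-antigen values are reported alongside
since either aggregation is defensible), F1, and false-negative /
false-positive rates at threshold 0.5 (binary) or argmax (categorical;
rates aggregate one-vs-rest over classes). A single-class test set
makes AUC undefined and is reported as missing, never as 0. Count
models are scored with R² on log(1+x)-transformed counts over all
cells × antigens. Model comparisons: Welch's unequal-variance t-test
between two cross-validation sets of one configuration (p = 1 by
convention when both variances are zero with equal means), and the
Wilcoxon rank-sum test across sets of models varying in
hyper-parameters (exact null distribution for groups ≤ 10, normal
approximation above).

## The synthetic-screen generator

The generator encodes the premise that specificity behaves as a
fixed-position sequence-motif problem: each antigen has a 3–6-residue
motif written into the CDR3β of every truly binding clonotype at a
fixed offset (default 3; a random-position mode exists), with a
per-position mutation probability. Around this it emulates:

- clonotype structure — CDR3 backbones uniform over residues (lengths
  12–18 by default, optional C…F flanks off), clone sizes geometric
  (p = 0.5, optionally capped) or fixed; all cells of a clone share
  sequences and ground truth;
- donor effects — donors act on label priors and surface-count means
  only, never on motif content, so covariate-benefit experiments have a
  clean causal path;
- counts — a per-cell log-normal size factor s (σ = 0.5) scales all
  modalities; the bound antigen's pMHC counts are negative-binomial
  with mean 100 s (dispersion 10), all other antigens and the negative
  controls with mean 1 s; surface counts use donor-specific means;
  total mRNA is proportional to s. A binding mean of zero is the
  degenerate null-signal case and leaves the bound antigen at
  background level;
- doublets — a seeded fraction of cells acquires a second clonotype's
  chains plus counts drawn for that clone's label, and is flagged in
  the ground truth.

The negative-binomial/log-normal choices mirror standard single-cell
count behavior; they are configurable and are a structural emulation
only. The generator does not attempt realistic V(D)J recombination,
transcriptomes, or HLA restriction, so passing tests demonstrate that
the pipeline and models behave correctly under the assumed generative
structure — not that they reach any particular accuracy on real screens.

### Experiment conditions used by the acceptance checks

- *Motif recovery*: 2,000 clonotypes, 4 antigens + non-binding, uniform
  priors, mutation rate 0.05, clone size ≤ 3 — an easily learnable
  sequence signal for both convolutional and linear models.
- *Donor-covariate benefit*: the regime where donor identity carries
  real information that sequence cannot — label priors put weight 0.9
  on a donor-favored antigen (non-binding mass 0.3) and the motif
  mutation rate is 0.7 so the sequence channel is informative but far
  from saturating. With weak mutation the sequence model alone is
  near-perfect and no covariate can help; the high mutation rate is
  what makes this an actual test of covariate integration.
- *Covariates-only null*: uniform priors (covariates carry no label
  information), mutation 0.05; the covariates-only model must sit at
  chance while sequence models learn.
- *Count recovery*: 10,000 cells, 8 antigens, 100:1 binding-to-
  background ratio, log-normal size factors. Removing the size-factor
  covariate is evaluated as donor+counts vs donor-only: negative-
  control and surface covariates themselves encode the size factor, so
  dropping the explicit size factor from the full model changes little
  — an expected redundancy, not a defect.

Problem sizes throughout (cells, epochs, widths) are chosen so the full
suite runs in minutes on one CPU core; they are the package's default
demonstration scale, and everything scales up by configuration.

## Known limitations

- Recurrent and attention stacks backpropagate through explicit
  per-position loops; they are an order of magnitude slower than the
  convolutional/linear families at equal batch size.
- The categorical model assumes exactly one binding event per cell (the
  binarization's largest-count rule); genuinely multi-specific cells
  are not modeled.
- Donor is a categorical proxy for HLA genotype; no HLA inference is
  attempted, and prediction for unseen donors with donor-covariate
  models requires zeroed covariates.
- BLOSUM rows are restricted to the 20 standard residues; ambiguity
  codes (B, Z, X, *) are rejected or zeroed, never scored.
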