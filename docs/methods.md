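# Methods

`tcnss` predicts per-residue protein secondary structure — eight DSSP
states (H, G, I, E, B, T, S, C) or the three-state reduction (H, E, C) —
from amino-acid sequence alone, and evaluates predictions with the field's
standard metrics.  This note records the model, the design choices made
where the design was genuinely open, the synthetic data the package is
tested on, and the known limits of what those tests show.

## Model

**Featurization.**  Each residue is a row of D = 21 + 7 + E numbers:

* one-hot over the 20 canonical amino acids in alphabetical order plus a
  21st column for `X` (unknown);
* physicochemical properties: a 4-class polarity one-hot (nonpolar /
  polar-uncharged / positive / negative), integer net charge at pH 7
  (His is classed positive but carries charge 0; its side-chain pKa ≈ 6),
  residue mass min–max scaled to [0, 1] over the 20 canonical residues, and
  Kyte–Doolittle hydropathy scaled the same way.  The table ships as
  `tcnss/data/physchem.csv`; `X` gets the all-zero property vector;
* a skip-gram embedding (default E = 16) trained with negative sampling on
  overlapping k-mer tokens of the training sequences (default k = 1,
  context window 5, 5 negatives, 20 epochs, seeded).  Out-of-vocabulary
  tokens and any k-mer containing `X` map to the zero vector, keeping
  unknowns uninformative.  Embeddings are trained on discrete tokens and
  *concatenated* with the other blocks (a word2vec-style objective needs
  discrete tokens, so it cannot consume the continuous blocks as input).

A sliding-window segmenter (odd width, default 19, zero-padded at the
edges) is available for local-feature augmentation; by default whole
sequences flow through the model.

**Trunk: improved multiscale bidirectional TCN.**  The trunk is built from
dilated causal convolutions — output position t sees inputs at
t, t−d, t−2d, … only — arranged in residual blocks of three
conv→ReLU→dropout stages plus a skip path (identity when widths match,
1×1 projection otherwise; the block output is branch + skip with no outer
activation, so a zeroed branch passes the input through exactly).  One
block per dilation scale runs in parallel (default scales 1, 9, 81, 729,
6561; kernel 3), outputs are concatenated over channels and fused by a 1×1
convolution.  Two such stacks with independent parameters process the
sequence forward and backward (the backward stack sees the
position-reversed sequence and its output is re-reversed); the branches
are merged by elementwise addition, then 1×1 convolution, a dense layer
with ReLU, and batch normalization.  With kernel 3 and three layers per
block, the largest scale's receptive field spans 3·(3−1)·6561 ≈ 39k
positions, far beyond any protein chain.  ReLU is used inside the trunk;
softmax appears only in the classifier head, where a normalization over
classes is meaningful.

**Head: BiLSTM with multi-head self-attention.**  Three stacked
bidirectional LSTM layers (standard gates: input/forget/output sigmoid
gates, tanh candidate cell, h_t = tanh(c_t)·o_t; forward and backward
outputs concatenated per position) with dropout after layers 1 and 2.
Scaled dot-product self-attention (Q = K = V = the BiLSTM states, 3 heads,
per-head width ⌊model width / heads⌋, heads concatenated and projected)
runs over the BiLSTM output; the BiLSTM and attention outputs are
concatenated, fused by a 1×1 convolution and classified by a dense layer
with softmax.  Padding positions of a batch are excluded from attention
(masked keys), from batch-norm statistics and from every loss and metric.

**Knowledge distillation.**  Training minimizes

    L = (1 − α) · CE(student, labels) + α · ρ² · KL(σ(Z_T/ρ) ‖ σ(Z_S/ρ))

with temperature ρ (default 2.0) and blend weight α (default 0.2, the
value the source sensitivity analysis settles on; scales likewise default
to the full [1, 9, 81, 729, 6561] list).  KL uses the teacher as the
reference distribution, the standard distillation direction.  The ρ²
factor keeps the soft-gradient magnitude roughly temperature-invariant; it
is the classic convention and can be disabled
(`scale_kd_by_rho_sq: false`).  The teacher is abstracted as cached
per-residue logits in a JSON-lines file whose header declares the class
order, so any teacher (e.g. a large protein language model run elsewhere)
can be plugged in without being loaded here.  With α = 0, or when a record
has no teacher logits, the code path is bit-identical to hard-label
training.

## Metrics

* **SOV99** decomposes both label strings into maximal same-state runs.
  For each state, every overlapping (observed, predicted) pair contributes
  `(minov + δ)/maxov · len(s1)` where minov is the overlap, maxov the
  combined extent, and the boundary allowance
  δ = min(maxov − minov, minov, ⌊len(s1)/2⌋, ⌊len(s2)/2⌋) — a prediction
  may misplace a boundary by up to half the shorter segment without
  penalty.  The normalizer sums len(s1) once per overlapping pair plus the
  lengths of observed segments with no overlapping prediction.  (A printed
  form of the normalizer that sums over the paired set twice is
  inconsistent with the definition of the unmatched set and with the
  original SOV99 reference; the unmatched-set reading is implemented.)
  An observed segment overlapping several predicted segments contributes
  once per pair to both numerator and normalizer.  Dataset-level SOV99 is
  the chain-length-weighted mean of per-chain scores.
* **Q3/Q8 accuracy** is the percentage of residues whose predicted state
  matches the observed one.
* **MiAUC** pools all (position, class) one-vs-rest score/indicator pairs
  and integrates a single ROC curve by the trapezoidal rule (equivalently:
  the probability that a random positive outscores a random negative, ties
  counting one half).  It is computed via scikit-learn's `roc_auc_score`;
  the test suite checks it against an exhaustive pairwise-comparison
  implementation.

## Synthetic data

Real benchmark sets (CB513, TS115, CASP) require downloads and a GPU-scale
teacher, so the package ships a generator that emulates their structure:
labels follow a semi-Markov chain (geometric dwell per state, default mean
segment length 5 — matching typical helix/strand run lengths — then a
uniform off-diagonal transition), and residues are emitted per position
from state-dependent distributions: a mixture of a state-preferred residue
set (helix formers A/E/L/M/Q/K/R/H, strand formers V/I/Y/C/W/F/T,
coil/turn formers G/N/P/S/D) with the uniform background, controlled by a
sharpness parameter (default 0.7).  Two presets pin the study conditions:

* **easy**: each state deterministically emits a single residue
  (A→H, V→E, G→C), 20 chains of length 40 — the labels are a lookup
  function of the sequence, so a converged model must approach 100% train
  accuracy; used for overfit/convergence checks.
* **hard**: sharpness 0.5, 100 chains of length 30–40 (30 train / 10
  validation / 60 test) — residues only weakly determine states, models
  overfit the small training set, and regularization has headroom to
  matter; used for the distillation comparison.

The **oracle teacher** produces logits with a margin (default 4.0 in the
experiments) at the true class plus Gaussian noise (preset sd 0.5).  What
the generator does *not* emulate: real sequence–structure statistics
(amphipathic periodicity, sheet pairing, chain-length distributions) and a
teacher with input-conditional knowledge.  Tests passing on this corpus
show the machinery is correct and trainable, not that the model reaches
any particular accuracy on real proteins.

### What the distillation comparison can and cannot show

Because the oracle teacher's logits are derived from the true labels, they
carry no information about the input→label mapping beyond the hard labels
already in the loss; the soft term reduces to label smoothing (toward
confidence σ(margin/ρ) ≈ 0.71) plus target noise.  In paired runs on the
hard preset (identical initialization, data order and dropout draws; 100
epochs; best-validation checkpoint restored) the distilled student wins
about half the comparisons, with a mean paired test-accuracy difference
statistically indistinguishable from zero.  A systematic benefit of the
kind reported for large pretrained teachers on small real datasets
requires a teacher whose outputs encode input-conditional structure, which
a label-derived oracle cannot supply.  The comparison is kept in the
test suite, and this limitation is documented rather than hidden.

## Numerical and design choices

* All tensor math runs on a small reverse-mode autodiff engine over
  float64 numpy arrays written for this package (no deep-learning
  framework is required at runtime).  Gradients are verified against
  central differences in the test suite; the BiLSTM against a hand-
  unrolled gate recursion to 1e-10.
* Weight initialization: fan-in-scaled uniform, seeded from the config;
  evaluation mode is fully deterministic (dropout off, batch-norm running
  statistics frozen), so repeated predictions and repeated end-to-end runs
  are byte-identical.
* Optimizer: Adam (lr 1e-3 default), padded mini-batches (default 8
  chains) with masks; best-validation checkpointing with optional early
  stop (patience) and an optional train-accuracy stopping target.  These
  training knobs are artifact choices; the source material does not state
  them.
* Dataset splitting operates on whole chains (never residues), so no
  sequence leaks across the train/test boundary; default 7:3, seeded.
* Eight-to-three state reduction: H,G,I→H, E,B→E, C,S,T→C (the convention
  consistent with the three-state accuracy definition; a stray statement
  merging the helical states into E is treated as a typo).
* Defaults for unstated architecture widths are config-exposed (TCN width
  64, LSTM hidden 64/direction, attention width 128).  Tests, examples and
  the acceptance script use a narrower desk-scale configuration
  (`workflow.desk_scale_config`: channels 12, trunk width 24, LSTM 16/dir,
  attention width 24) so that full training runs complete in seconds to a
  few minutes on a single CPU core; this changes capacity, not
  architecture.
* Degenerate inputs: empty sequences are rejected; a length-1 sequence
  flows through every stage (attention over one position is the identity);
  SOV99 of an empty observed segment set is defined as 0 with a warning.

## Limitations

* No PSSM/HMM profile features and no pretrained-language-model input
  features; the teacher is consumed only as cached logits.
* CPU-only, desk-scale: the default widths train comfortably, but the
  package is not engineered for GPU-scale corpora.
* Reproduction of published benchmark accuracies on CB513/TS115/PDB-scale
  data is out of scope: it requires the real datasets and a genuine
  large-model teacher.
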