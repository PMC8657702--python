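# Methods

## Problem setting

Proteochemometric (PCM) modeling predicts whether a compound binds a
protein from a joint numeric representation of both. Unlike single- or
multi-task QSAR, a PCM model conditions on a protein descriptor, so one
model covers many targets and can in principle generalize to unseen ones.
This package provides the full pipeline — data I/O, descriptor backends,
split generation, the classifier pair, metrics and comparison statistics —
plus a simulator that makes every stage testable without external data.

## Models

Both variants are three-hidden-layer feedforward networks trained with
binary cross-entropy.

* **Full model.** Input [x_c ‖ x_p]; hidden layers (default 2048/1024/512,
  ReLU, inverted dropout 0.25) and a single sigmoid unit. Hidden units mix
  the two channels, so arbitrary compound–protein interaction features can
  form.
* **No-Interaction-Terms baseline.** Two towers of the same depth at half
  width (configurable); the compound tower sees only x_c, the protein tower
  only x_p. Each tower is trained as an independent single-channel
  predictor of the label; the model prediction is the arithmetic mean of
  the two tower probabilities. Averaging on the probability scale makes the
  2×2 interaction contrast identically zero, which is the property the
  baseline exists for: any full-vs-baseline gap is attributable to learned
  interaction terms. Training the towers independently (rather than through
  a joint loss on the averaged probability) was chosen because calibrated
  marginal towers compose to the exact additive decision boundary
  (σ(g)+σ(h) > 1 ⇔ g > −h), and it measured no worse in practice.

Optimization: Adam (lr 10⁻³, default moments), batch 256, max 300 epochs.
After each epoch the validation loss is evaluated with dropout off. The
learning rate halves after `lr_halving_patience` (5) epochs without a
validation improvement larger than `min_delta` (10⁻⁴), training stops after
`early_stop_patience` (10) such epochs, and the weights with the strictly
lowest validation loss are restored, so the model's reported validation
loss equals the minimum of its training log. Validation loss (not MCC) is
the plateau criterion because it is smooth and threshold-free. Everything
is plain numpy and a pure function of the config seed; two runs with the
same config, data and machine produce bit-identical weights.

The "comparable capacity" half-width rule and the layer widths themselves
are declared defaults, not tuned values; the parameter count depends on the
input descriptor dimensions.

## Splits

* `random` — measurements permuted and cut to (train, valid, test)
  fractions, default (0.7, 0.1, 0.2), sizes within one record of the
  request.
* `lcco` — compounds clustered by k-means (default k = 10) on
  unit-normalized descriptor vectors (Euclidean on the unit sphere is
  monotone in cosine distance); all measurements of one cluster form the
  test set; iterating the held-out cluster yields k folds.
* `lpo` — proteins shuffled once and dealt into n near-equal groups; all
  measurements of a group form the test set.

Validation records are always carved from the training side, never from
held-out clusters or proteins, so early stopping cannot exploit test-like
matter. `nn_distance_diagnostic` reports the mean over test compounds of
1 − max cosine similarity to any train compound (ties broken by lowest
train index); zero vectors are an error because cosine distance is
undefined for them.

## Metrics

* **MCC** from the confusion matrix at probability threshold 0.5
  (configurable). When a marginal is zero the score is reported as 0 with a
  log message.
* **BEDROC** (Truchon–Bailey closed form), default α = 20: rank i of N
  carries weight e^(−αi/N); the sum over actives is normalized to RIE and
  affinely mapped to [0, 1]. α = 20 is the unique standard value at which
  the top 8 % of ranks carries ≈ 80 % of the total weight
  (1 − e^(−0.08α) = 0.798). Tied scores share the mean weight of their tied
  block, making the score invariant to input order among ties.
* **Top-decile overlap**: per protein with ≥ 100 measured compounds
  (default), the fraction of the ⌈0.1·n⌉ truly most active compounds that
  also appear among the ⌈0.1·n⌉ highest-predicted; smaller panels are
  omitted because a decile of a small panel is discreteness-dominated.
* **Wilcoxon signed-rank** over paired fold metrics: zero differences
  dropped; exact null for n ≤ 25 with tie-free ranks, otherwise the normal
  approximation with continuity correction (via scipy behind the module
  interface; an exhaustive 2ⁿ enumeration oracle checks it in the tests).

Aggregation keeps full precision; display rounding is half-away-from-zero
at 3 decimals (MCC/BEDROC), 1 (percent improvement) and 0 (averaged
percent). Recomputing a published improvement grid from printed 3-decimal
inputs reproduces 13 of its 18 one-decimal cells; the six random-split
cells disagree by exactly 0.1 in five cases, indicating the originals were
computed from unrounded values. The discrepancy is documented, not patched.

## Simulator

`SimulationConfig` defaults: 2000 compounds × 50 proteins, 10 clusters,
descriptor dims (64, 32), density 0.1 (10 000 measured pairs), label flip
noise 0.1 — sized for minutes-scale CPU training.

* **Compound space** is hierarchical: cluster centers drawn uniformly on
  the unit sphere; per cluster, 20 series centers at Gaussian spread 0.15;
  compounds at spread 0.04 around a random series center. Clusters model
  chemotypes; series model congeneric analog sets.
* **Proteins** are unit-normalized Gaussian vectors.
* **Latent logit** b₀ + s_c·bias_c + s_p·bias_p + γ·u with
  bias_e = x_eᵀw_e/|x_e| (fixed random projections, unit variance — so the
  additive part is genuinely learnable from the embeddings, including for
  held-out entities) and u = x_cᵀMx_p/(|x_c||x_p|) (fixed random M, unit
  variance). Normalizing by the vector norms rather than by √(d_c·d_p)
  stabilizes the interaction variance exactly, for any descriptor scale.
  Labels are the logit sign with a `label_noise` fraction flipped;
  `truth_metrics` reports the MCC of the noiseless-sign classifier against
  the noisy labels — the Bayes ceiling, ≈ 1 − 2ρ at flip fraction ρ with
  balanced classes. Bias scales default to 1; γ defaults to 0.
* **Measurement sampling** mimics public bioactivity data: per-protein
  counts follow a Zipf skew (exponent 0.5), series are dealt exclusively to
  proteins in proportion to size, and each protein draws 90 % of its
  measurements from its own series and 10 % uniformly
  (`chemistry_bias = 0.9`). This protein-specific chemistry is what makes
  leave-protein-out splits indirectly hold out compound space. At the
  default density (≈ 5 measurements per compound) nearly every test
  compound is still seen in training, so the nearest-neighbor ordering
  LCCO > LPO > random is exercised at a realistic sparsity
  (density 0.03, ≈ 1.9 measurements per compound) in the tests.

What the simulator does **not** model: real chemistry (no SMILES or
sequences behind the vectors), assay noise structure, activity-value
distributions beyond the latent logit, or the descriptor-specific
geometry of CDDD/MolBERT/UniRep/SeqVec/ESM embeddings. Passing tests
demonstrate pipeline correctness and the bias/interaction decomposition
logic, not absolute performance on ChEMBL-scale data.

## Known limitations and observed behavior

* At the default simulator scale, the full model retains a small but
  seed-consistent MCC edge (~0.03–0.1) over the no-interaction baseline
  even at γ = 0, where the Bayes-optimal predictor is additive and both
  architectures can express the optimal decision boundary. The gap is a
  finite-sample estimation effect, not a training artifact: ideal logistic
  towers composed by averaging show the same consistent deficit against a
  joint logistic fit, because each tower learns from marginally much
  noisier targets. It vanishes with more data but is detected by a paired
  Wilcoxon test at any consistent magnitude; the corresponding
  indistinguishability test is therefore expected to fail at this scale
  and is roughly 2.5× smaller than the γ = 5 interaction effect it is
  contrasted with.
* Interaction-recovery experiments use three-layer nets at (64, 32, 16)
  with max 60 epochs — the package's desk-scale defaults for the simulated
  descriptor dims; the paper-scale widths remain the model default.
* Duplicate (compound, protein) measurements keep the highest activity
  (deterministic, conservative toward activity); the default binarization
  threshold of 6.5 log-activity units is a convention flag, not a claim.
* The handcrafted descriptors (1024-bit radius-2 hashed circular
  fingerprint; amino-acid composition + mean/std of the five Sandberg
  z-scales, dim 30) are a re-derivation of the classic handcrafted
  families, not a byte-level reproduction of any specific prior feature
  set; 'X' residues are skipped in aggregation to avoid imputation bias.
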