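# pcmkit

Proteochemometric (PCM) modeling toolkit for protein–ligand binding
classification with pluggable compound and protein descriptors, honest
train/test splits, early-enrichment metrics, and a baseline that makes the
value of interaction modeling measurable.

## Who this is for

Computational chemists and ML practitioners benchmarking molecular and
protein representations (learned embeddings such as CDDD, MolBERT, UniRep,
SeqVec, ESM — consumed as precomputed vector tables — or the built-in
handcrafted baselines) on bioactivity data, and anyone who wants to know
whether their PCM model actually learns compound–protein *interactions* or
merely per-entity propensities.

## The core ideas

**Model.** A PCM classifier maps a pair (x_c, x_p) of compound and protein
descriptor vectors to P(active). The *full* model feeds the concatenation
[x_c ‖ x_p] through three fully connected ReLU layers to a sigmoid output.
The *No-Interaction-Terms* baseline keeps the two channels separate — a
compound-only tower and a protein-only tower, each a three-layer network
with its own sigmoid — and predicts the arithmetic mean of the two tower
probabilities:

    p̂(c, p) = ½ · [σ(f_c(x_c)) + σ(f_p(x_p))]

By construction the baseline satisfies, for any compounds c₁, c₂ and
proteins p₁, p₂,

    p̂(c₁,p₁) + p̂(c₂,p₂) = p̂(c₁,p₂) + p̂(c₂,p₁)

i.e. its 2×2 prediction tables have zero interaction contrast: it can at
best recover compound and protein bias. The full-vs-baseline gap therefore
isolates the interaction signal. Training uses binary cross-entropy with
Adam, learning-rate halving on validation plateau, early stopping after a
patience of epochs (default 10), and best-validation weight restoration.

**Splits.** Random splits over measurements; leave-compound-cluster-out
(LCCO, k-means on unit-normalized compound descriptors, one cluster held
out per fold); leave-protein-out (LPO, protein groups held out). The mean
nearest-neighbor cosine distance from test to train compounds
(`splits.nn_distance_diagnostic`) quantifies how much chemistry a split
actually holds out.

**Metrics.** MCC (threshold 0.5) and the Truchon–Bailey BEDROC early
enrichment score with α = 20, at which the top 8 % of the ranked list
carries 1 − e^(−0.08·20) ≈ 80 % of the total exponential rank weight.
Per-protein top-decile overlap and Wilcoxon signed-rank comparisons over
folds complete the analysis layer.

**Simulator.** `pcmkit.synthetic` generates clustered compound embeddings
(clusters → congeneric series → compounds), protein embeddings, and labels
from a latent logit b₀ + s_c·bias_c + s_p·bias_p + γ·(x_cᵀ M x_p)/(|x_c||x_p|)
with flip noise — an additive part both model variants can learn and a
bilinear interaction that is invisible to the baseline by construction, so
γ dials exactly the signal the full model should recover.

## Worked example

```bash
cat > run.yaml <<'YAML'
seed: 7
simulation:
  n_compounds: 800
  n_proteins: 25
  n_clusters: 5
  compound_dim: 32
  protein_dim: 16
  density: 0.25
  interaction_strength: 3.0
split: {regime: lcco, k: 5, valid_fraction: 0.1}
model:
  hidden_sizes: [64, 32, 16]
  max_epochs: 60
  early_stop_patience: 8
  variants: [full, no_interaction]
YAML
pcm run --config run.yaml --out demo/
```

This simulates 5 000 measurements with a strong interaction term, holds out
each of the 5 compound clusters in turn, trains both model variants per
fold, and prints one row per (fold, variant):

```
regime  fold        variant       mcc   bedroc  n_test
  lcco     0           full  0.239396 0.803163    1033
  lcco     0 no_interaction  0.248358 0.739442    1033
  lcco     1           full  0.141050 0.725199     968
  lcco     1 no_interaction  0.053693 0.677590     968
  ...
```

and a comparison report (`demo/report.txt`):

```
Full vs No-Interaction-Terms percent improvement:
regime     full  no_interaction  pct_improvement
  lcco 0.215574        0.095333            126.1

Wilcoxon signed-rank contrasts (significance 0.05):
regime            contrast  n_pairs  statistic  p_value
  lcco full>no_interaction        5       14.0   0.0625
```

Read: averaged over the five LCCO folds the full model more than doubles
the baseline MCC (0.216 vs 0.095) because the simulated labels carry a
bilinear compound–protein interaction the dual-tower baseline structurally
cannot express; with only five folds the one-sided Wilcoxon test bottoms
out at p = 1/16. With `interaction_strength: 0` the two variants converge.

Real data enters through the same formats: an activity CSV/TSV
(compound_id, protein_id, activity, label — column names remappable),
embedding tables (`id,dim_0..dim_{d-1}`), FASTA for the handcrafted protein
descriptor and SMILES lists for the hashed circular fingerprint. See
`pcm simulate / split / train / evaluate / report --help`.

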