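"""Synthetic proteochemometric datasets with a known bias/interaction decomposition.

The generator draws clustered compound embeddings (Gaussian blobs around
random unit-sphere centers), unit-normalized Gaussian protein embeddings,
and labels from a latent logit

    logit(c, p) = b0 + s_c * bias_c + s_p * bias_p + gamma * u(c, p)

where bias_c = x_c' w_c / |x_c| and bias_p = x_p' w_p / |x_p| are
unit-variance per-entity propensities read off the embeddings through fixed
random projections (so an additive model can genuinely recover them, also
for held-out entities), and u(c, p) = x_c' M x_p / (|x_c| |x_p|) is a
unit-variance bilinear
compound-protein interaction with a fixed random mixing matrix M. The
interaction term is exactly the component a No-Interaction-Terms model is
structurally unable to express, so gamma cleanly dials how much a full PCM
model can gain over the additive baseline. The label is the sign of the
logit with a configurable fraction of labels flipped.

Compound space is hierarchical: clusters (chemotypes) contain congeneric
series, and compounds scatter tightly around their series center. Measured
pairs are sampled without replacement from the compound x protein grid with
two realism features of public bioactivity data: per-protein measurement
counts follow a Zipf-like skew (a few heavily assayed targets, many sparse
ones), and each protein concentrates most of its measurements on its own
exclusive set of series (the chemical matter developed against that
target), with a uniform spillover fraction. This is what makes holding out
a protein also indirectly hold out chemistry, so that at realistic sparsity
the mean nearest-neighbor distance ordering LCCO > LPO > random emerges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ActivityRecord, ActivityTable, EmbeddingTable
from .metrics import ConfusionCounts, mcc


@dataclass
class SimulationConfig:
    n_compounds: int = 2000
    n_proteins: int = 50
    n_clusters: int = 10
    compound_dim: int = 64
    protein_dim: int = 32
    cluster_spread: float = 0.15
    bias_scale_compound: float = 1.0
    bias_scale_protein: float = 1.0
    interaction_strength: float = 0.0  # gamma
    intercept: float = 0.0
    density: float = 0.1
    label_noise: float = 0.1
    n_series_per_cluster: int = 20
    series_spread: float = 0.04
    chemistry_bias: float = 0.9  # probability mass on a protein's own series
    protein_size_skew: float = 0.5  # Zipf exponent of per-protein counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compound_dim < 2 or self.protein_dim < 2:
            raise ValueError("descriptor dims must be >= 2")
        if not 2 <= self.n_clusters <= self.n_compounds:
            raise ValueError("need 2 <= n_clusters <= n_compounds")
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.interaction_strength < 0 or self.bias_scale_compound < 0 or self.bias_scale_protein < 0:
            raise ValueError("strengths must be non-negative")
        if not 0 < self.chemistry_bias < 1:
            raise ValueError("chemistry_bias must be in (0, 1)")
        if self.n_series_per_cluster < 1:
            raise ValueError("need at least one series per cluster")
        if self.n_clusters * self.n_series_per_cluster < self.n_proteins:
            raise ValueError("need at least one series per protein")
        if self.protein_size_skew < 0:
            raise ValueError("protein_size_skew must be non-negative")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    activity: ActivityTable
    compound_embeddings: EmbeddingTable
    protein_embeddings: EmbeddingTable
    cluster_of: dict[str, int]
    # ground truth, row-aligned with activity.records
    latent_logit: np.ndarray = field(repr=False, default=None)
    true_label: np.ndarray = field(repr=False, default=None)
    compound_bias: np.ndarray = field(repr=False, default=None)
    protein_bias: np.ndarray = field(repr=False, default=None)


def _protein_sizes(config: SimulationConfig, n_pairs: int) -> np.ndarray:
    """Zipf-skewed per-protein measurement counts summing to ``n_pairs``."""
    ranks = np.arange(1, config.n_proteins + 1, dtype=float)
    w = ranks ** (-config.protein_size_skew)
    w /= w.sum()
    lo, hi = min(2, config.n_compounds), config.n_compounds
    sizes = np.clip(np.round(w * n_pairs).astype(int), lo, hi)
    diff = n_pairs - sizes.sum()
    i = 1
    while diff:
        step = int(np.sign(diff))
        if lo <= sizes[i % len(sizes)] + step <= hi:
            sizes[i % len(sizes)] += step
            diff -= step
        i += 1
    return sizes


def _sample_pairs(
    config: SimulationConfig,
    rng: np.random.Generator,
    comp_series: np.ndarray,
    n_series: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample measured (compound, protein) pairs without replacement.

    Series are dealt out exclusively to proteins in proportion to protein
    size; each protein puts ``chemistry_bias`` of its sampling mass on its
    own series' compounds and spreads the rest uniformly.
    """
    nc, npr = config.n_compounds, config.n_proteins
    n_pairs = int(round(config.density * nc * npr))
    sizes = _protein_sizes(config, n_pairs)

    perm = rng.permutation(n_series)
    alloc = np.maximum(np.round(sizes / sizes.sum() * n_series).astype(int), 1)
    while alloc.sum() > n_series:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_series:
        alloc[np.argmin(alloc)] += 1
    bounds = np.concatenate([[0], np.cumsum(alloc)])

    comp_rows, prot_rows = [], []
    for p in range(npr):
        own = perm[bounds[p] : bounds[p + 1]]
        in_own = np.isin(comp_series, own)
        n_own = int(in_own.sum())
        if 0 < n_own < nc:
            w = np.where(
                in_own,
                config.chemistry_bias / n_own,
                (1 - config.chemistry_bias) / (nc - n_own),
            )
        else:
            w = np.full(nc, 1.0 / nc)
        w /= w.sum()
        chosen = rng.choice(nc, size=sizes[p], replace=False, p=w)
        comp_rows.append(chosen)
        prot_rows.append(np.full(sizes[p], p))
    return np.concatenate(comp_rows), np.concatenate(prot_rows)


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset; a pure function of ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    nc, npr = config.n_compounds, config.n_proteins

    # hierarchical compound space: cluster centers -> series centers -> compounds
    centers = rng.standard_normal((config.n_clusters, config.compound_dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    n_series = config.n_clusters * config.n_series_per_cluster
    series_cluster = np.repeat(np.arange(config.n_clusters), config.n_series_per_cluster)
    series_centers = centers[series_cluster] + config.cluster_spread * rng.standard_normal(
        (n_series, config.compound_dim)
    )
    comp_series = rng.integers(0, n_series, size=nc)
    cluster_idx = series_cluster[comp_series]
    xc = series_centers[comp_series] + config.series_spread * rng.standard_normal(
        (nc, config.compound_dim)
    )

    xp = rng.standard_normal((npr, config.protein_dim))
    xp /= np.linalg.norm(xp, axis=1, keepdims=True)

    w_c = rng.standard_normal(config.compound_dim)
    w_p = rng.standard_normal(config.protein_dim)
    bias_c = xc @ w_c / np.linalg.norm(xc, axis=1)
    bias_p = xp @ w_p / np.linalg.norm(xp, axis=1)
    mixing = rng.standard_normal((config.compound_dim, config.protein_dim))

    ci, pi = _sample_pairs(config, rng, comp_series, n_series)

    xcs, xps = xc[ci], xp[pi]
    u = np.einsum("ij,jk,ik->i", xcs, mixing, xps)
    u /= np.linalg.norm(xcs, axis=1) * np.linalg.norm(xps, axis=1)
    logit = (
        config.intercept
        + config.bias_scale_compound * bias_c[ci]
        + config.bias_scale_protein * bias_p[pi]
        + config.interaction_strength * u
    )
    true_label = (logit > 0).astype(int)
    label = true_label.copy()
    n_flip = int(round(config.label_noise * len(label)))
    if n_flip:
        flip = rng.choice(len(label), size=n_flip, replace=False)
        label[flip] = 1 - label[flip]

    compound_ids = [f"C{i:05d}" for i in range(nc)]
    protein_ids = [f"P{i:04d}" for i in range(npr)]
    records = [
        ActivityRecord(
            compound_id=compound_ids[c],
            protein_id=protein_ids[p],
            activity_value=float(z),
            label=int(y),
        )
        for c, p, z, y in zip(ci, pi, logit, label)
    ]
    return SyntheticDataset(
        config=config,
        activity=ActivityTable(records),
        compound_embeddings=EmbeddingTable(compound_ids, xc),
        protein_embeddings=EmbeddingTable(protein_ids, xp),
        cluster_of={compound_ids[i]: int(cluster_idx[i]) for i in range(nc)},
        latent_logit=logit,
        true_label=true_label,
        compound_bias=bias_c,
        protein_bias=bias_p,
    )


def truth_metrics(dataset: SyntheticDataset) -> float:
    """MCC of the noiseless-logit (Bayes) classifier against the noisy labels.

    The ceiling any trained model can reach on this dataset up to Monte-Carlo
    fluctuation: with flip fraction rho and balanced classes it approaches
    1 - 2*rho.
    """
    y = dataset.activity.labels()
    pred = dataset.true_label
    counts = ConfusionCounts(
        tp=int(np.sum((y == 1) & (pred == 1))),
        fp=int(np.sum((y == 0) & (pred == 1))),
        tn=int(np.sum((y == 0) & (pred == 0))),
        fn=int(np.sum((y == 1) & (pred == 0))),
    )
    return mcc(counts)
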