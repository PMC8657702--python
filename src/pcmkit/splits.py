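"""Train/validation/test partitioning and split-difficulty diagnostics.

Three regimes:

* ``random`` — measurements assigned to partitions uniformly at random.
  Optimistic: congeneric compounds from one assay end up on both sides.
* ``lcco`` (leave-compound-cluster-out) — compounds are clustered on their
  descriptor vectors; one whole cluster is held out as test, so the test set
  contains chemical matter distant from training. Iterating the held-out
  cluster gives k-fold cross-validation.
* ``lpo`` (leave-protein-out) — all measurements of a group of proteins are
  held out, probing generalization to unseen targets.

Validation sets are always carved from the training side only, never from
held-out clusters or proteins, so early stopping cannot peek at test-like
matter. The mean nearest-neighbor cosine distance from test to train
compounds quantifies how chemically hard a split actually is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data_io import ActivityTable, EmbeddingTable

DEFAULT_K_CLUSTERS = 10


@dataclass
class SplitAssignment:
    """Disjoint train/valid/test partition of activity-record indices."""

    regime: str  # random | lcco | lpo
    fold_index: int
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    seed: int
    held_out: object = None  # cluster index (lcco) or tuple of protein ids (lpo)

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.valid = np.asarray(self.valid, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        parts = [set(self.train), set(self.valid), set(self.test)]
        n = sum(len(p) for p in parts)
        union = parts[0] | parts[1] | parts[2]
        if len(union) != n:
            raise ValueError("train/valid/test partitions overlap")

    @property
    def n_records(self) -> int:
        return len(self.train) + len(self.valid) + len(self.test)

    def to_dataframe(self, table: ActivityTable) -> pd.DataFrame:
        rows = []
        for part, idx in (("train", self.train), ("valid", self.valid), ("test", self.test)):
            for i in idx:
                rec = table[int(i)]
                rows.append(
                    {
                        "record_index": int(i),
                        "compound_id": rec.compound_id,
                        "protein_id": rec.protein_id,
                        "partition": part,
                        "fold": self.fold_index,
                        "regime": self.regime,
                        "seed": self.seed,
                    }
                )
        return pd.DataFrame(rows).sort_values("record_index").reset_index(drop=True)


def write_split(split: SplitAssignment, table: ActivityTable, path: str | Path) -> None:
    split.to_dataframe(table).to_csv(path, sep="\t", index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, sep="\t")
    parts = {p: df.loc[df["partition"] == p, "record_index"].to_numpy() for p in ("train", "valid", "test")}
    return SplitAssignment(
        regime=str(df["regime"].iloc[0]),
        fold_index=int(df["fold"].iloc[0]),
        train=parts["train"],
        valid=parts["valid"],
        test=parts["test"],
        seed=int(df["seed"].iloc[0]),
    )


@dataclass
class CompoundClustering:
    compound_ids: list[str]
    cluster_of: dict[str, int]
    k: int
    metric: str = "cosine-on-descriptors"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 clusters")
        missing = [c for c in self.compound_ids if c not in self.cluster_of]
        if missing:
            raise ValueError(f"compounds without cluster assignment: {missing[:5]}")

    def members(self, cluster: int) -> list[str]:
        return [c for c in self.compound_ids if self.cluster_of[c] == cluster]


def _split_fractions(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    ft, fv, fs = fractions
    if min(ft, fv, fs) <= 0 or abs(ft + fv + fs - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_train = int(round(n * ft))
    n_valid = int(round(n * fv))
    n_train = min(n_train, n - 2)
    n_valid = max(1, min(n_valid, n - n_train - 1))
    return n_train, n_valid, n - n_train - n_valid


def split_random(
    table: ActivityTable,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
    fold_index: int = 0,
) -> SplitAssignment:
    """Assign measurements to train/valid/test uniformly at random."""
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_train, n_valid, _ = _split_fractions(n, fractions)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitAssignment(
        regime="random",
        fold_index=fold_index,
        train=perm[:n_train],
        valid=perm[n_train : n_train + n_valid],
        test=perm[n_train + n_valid :],
        seed=seed,
    )


def cluster_compounds(embeddings: EmbeddingTable, k: int = DEFAULT_K_CLUSTERS, seed: int = 0) -> CompoundClustering:
    """K-means on unit-normalized descriptor vectors.

    Euclidean distance between unit vectors is a monotone function of cosine
    distance, so this clusters by descriptor direction. Deterministic for a
    fixed seed.
    """
    n = len(embeddings)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of compounds ({n})")
    norms = np.linalg.norm(embeddings.vectors, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero descriptor vector; cosine clustering undefined")
    x = embeddings.vectors / norms
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(x)
    return CompoundClustering(
        compound_ids=list(embeddings.ids),
        cluster_of={c: int(l) for c, l in zip(embeddings.ids, labels)},
        k=k,
    )


def _carve_valid(
    rest: np.ndarray, valid_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rest = rng.permutation(rest)
    n_valid = max(1, int(round(valid_fraction * len(rest))))
    if n_valid >= len(rest):
        raise ValueError("validation fraction leaves no training records")
    return rest[n_valid:], rest[:n_valid]


def split_lcco(
    table: ActivityTable,
    clustering: CompoundClustering,
    test_cluster: int,
    valid_fraction: float = 0.1,
    seed: int = 0,
) -> SplitAssignment:
    """Hold out every measurement of one compound cluster as the test set."""
    if not 0 <= test_cluster < clustering.k:
        raise ValueError(f"test_cluster {test_cluster} out of range [0, {clustering.k})")
    in_test = np.array(
        [clustering.cluster_of[r.compound_id] == test_cluster for r in table], dtype=bool
    )
    test = np.flatnonzero(in_test)
    if len(test) == 0:
        raise ValueError(f"cluster {test_cluster} holds no measurements")
    rng = np.random.default_rng(seed)
    train, valid = _carve_valid(np.flatnonzero(~in_test), valid_fraction, rng)
    return SplitAssignment(
        regime="lcco",
        fold_index=test_cluster,
        train=train,
        valid=valid,
        test=test,
        seed=seed,
        held_out=test_cluster,
    )


def split_lpo(
    table: ActivityTable,
    n_folds: int,
    fold: int,
    valid_fraction: float = 0.1,
    seed: int = 0,
) -> SplitAssignment:
    """Hold out all measurements of one fold's protein group as the test set.

    Proteins are shuffled once (by ``seed``) and dealt into ``n_folds``
    near-equal groups, so iterating ``fold`` covers every protein exactly once.
    """
    proteins = sorted(set(r.protein_id for r in table))
    if n_folds > len(proteins):
        raise ValueError("more folds than distinct proteins")
    if not 0 <= fold < n_folds:
        raise ValueError(f"fold {fold} out of range [0, {n_folds})")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(proteins))
    held = set(shuffled[fold::n_folds])
    in_test = np.array([r.protein_id in held for r in table], dtype=bool)
    test = np.flatnonzero(in_test)
    train, valid = _carve_valid(np.flatnonzero(~in_test), valid_fraction, rng)
    return SplitAssignment(
        regime="lpo",
        fold_index=fold,
        train=train,
        valid=valid,
        test=test,
        seed=seed,
        held_out=tuple(sorted(held)),
    )


def nn_distance_diagnostic(
    test_embeddings: EmbeddingTable, train_embeddings: EmbeddingTable
) -> float:
    """Mean cosine distance from each test vector to its nearest train vector.

    For each test vector, 1 minus the maximum cosine similarity to any train
    vector; ties broken by the lowest train index (irrelevant to the mean but
    keeps per-vector neighbors deterministic). Near 0 when test chemistry is
    re-represented in training; approaching 1 for orthogonal chemistry.
    """
    if len(test_embeddings) == 0 or len(train_embeddings) == 0:
        raise ValueError("both embedding tables must be non-empty")
    if test_embeddings.dim != train_embeddings.dim:
        raise ValueError("embedding dimensionality mismatch")
    for tbl in (test_embeddings, train_embeddings):
        if np.any(np.linalg.norm(tbl.vectors, axis=1) == 0):
            raise ValueError("zero vector; cosine distance undefined")
    t = test_embeddings.vectors / np.linalg.norm(test_embeddings.vectors, axis=1, keepdims=True)
    r = train_embeddings.vectors / np.linalg.norm(train_embeddings.vectors, axis=1, keepdims=True)
    # block over test rows to bound memory on large tables
    best = np.empty(len(t))
    step = max(1, int(2**22 / max(1, len(r))))
    for i in range(0, len(t), step):
        best[i : i + step] = (t[i : i + step] @ r.T).max(axis=1)
    return float(np.mean(1.0 - best))


def split_nn_distance(
    split: SplitAssignment, table: ActivityTable, compound_embeddings: EmbeddingTable
) -> float:
    """NN-distance diagnostic between a split's unique test and train compounds."""
    train_c = sorted(set(table[int(i)].compound_id for i in split.train))
    test_c = sorted(set(table[int(i)].compound_id for i in split.test))
    return nn_distance_diagnostic(
        compound_embeddings.subset(test_c), compound_embeddings.subset(train_c)
    )
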