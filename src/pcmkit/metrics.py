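"""Classification and early-enrichment metrics for PCM models.

Two headline metrics: the Matthews Correlation Coefficient (MCC), a
confusion-matrix correlation in [-1, 1] that stays informative on the
heavily imbalanced label distributions typical of bioactivity data, and
BEDROC (Boltzmann-enhanced discrimination of ROC), an exponentially
early-weighted ranking score in [0, 1] that rewards placing true actives at
the very top of the predicted ranking — the operative property when only a
small fraction of virtual-screening hits can be tested experimentally.

BEDROC follows the Truchon-Bailey closed form. At the default weighting
parameter alpha = 20, the top 8% of ranks carries 1 - exp(-0.08*20) ~ 80% of
the total exponential rank weight, i.e. 80% of the attainable score comes
from the top 8% of the ranked list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .data_io import ActivityTable, EmbeddingTable
    from .model import PCMModel
    from .splits import SplitAssignment

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 20.0
DEFAULT_DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls,
        y_true: Sequence[int],
        scores: Sequence[float],
        threshold: float = DEFAULT_DECISION_THRESHOLD,
    ) -> "ConfusionCounts":
        y = np.asarray(y_true, dtype=int)
        pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
        return cls(
            tp=int(np.sum((y == 1) & (pred == 1))),
            fp=int(np.sum((y == 0) & (pred == 1))),
            tn=int(np.sum((y == 0) & (pred == 0))),
            fn=int(np.sum((y == 1) & (pred == 0))),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient from confusion counts.

    Returns 0.0 (with a log message) when any confusion-matrix marginal is
    zero, where the usual formula is 0/0.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, fp, tn, fn = (float(counts.tp), float(counts.fp), float(counts.tn), float(counts.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        logger.info("MCC marginal is zero; returning 0.0 by convention")
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _rank_weights(order: np.ndarray, scores: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential weight exp(-alpha*i/N) per rank i (1-based), with weights
    averaged over blocks of tied scores so the result is invariant to input
    order among ties."""
    n = len(order)
    ranks = np.arange(1, n + 1, dtype=float)
    w = np.exp(-alpha * ranks / n)
    sorted_scores = scores[order]
    # average weights within maximal runs of equal scores
    start = 0
    for i in range(1, n + 1):
        if i == n or sorted_scores[i] != sorted_scores[start]:
            if i - start > 1:
                w[start:i] = w[start:i].mean()
            start = i
    return w


def bedroc(
    scores: Sequence[float],
    labels: Sequence[int],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Truchon-Bailey BEDROC score of a scored, binary-labeled list.

    Items are ranked by descending score; each rank i in 1..N carries weight
    exp(-alpha*i/N), ties sharing the mean weight of their block. The sum of
    weights at active positions is normalized (RIE) and affinely rescaled so
    the score spans [0, 1] between the worst and best possible orderings.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.shape != y.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    n = len(y)
    n_actives = int(y.sum())
    if n_actives == 0 or n_actives == n:
        raise ValueError("BEDROC requires at least one active and one inactive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    order = np.argsort(-scores, kind="stable")
    w = _rank_weights(order, scores, alpha)
    s = float(w[y[order] == 1].sum())
    ra = n_actives / n
    rie = s / (ra * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1))
    return float(
        rie * ra * math.sinh(alpha / 2) / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
        + 1 / (1 - math.exp(alpha * (1 - ra)))
    )


def top_weight_fraction(alpha: float = DEFAULT_ALPHA, top: float = 0.08, n: int = 100_000) -> float:
    """Fraction of total exponential rank weight in the top ``top`` of ranks.

    Computed numerically from the rank weights of an n-item list; converges
    to 1 - exp(-top*alpha) for large n.
    """
    ranks = np.arange(1, n + 1, dtype=float)
    w = np.exp(-alpha * ranks / n)
    k = int(round(top * n))
    return float(w[:k].sum() / w.sum())


def top_decile_overlap(
    protein_ids: Sequence[str],
    activities: Sequence[float],
    predictions: Sequence[float],
    min_compounds: int = 100,
    fraction: float = 0.1,
) -> dict[str, float]:
    """Per-protein overlap between top-decile-by-truth and top-decile-by-prediction.

    For each protein with at least ``min_compounds`` measured compounds, takes
    the ceil(fraction*n) compounds with the highest measured activity and the
    same number with the highest predicted score, and reports the fraction of
    the truth set recovered by the prediction set. Proteins below the
    compound-count cutoff are omitted (with fewer compounds a decile overlap
    is dominated by discreteness noise).
    """
    pids = np.asarray(protein_ids, dtype=object)
    act = np.asarray(activities, dtype=float)
    pred = np.asarray(predictions, dtype=float)
    if not (len(pids) == len(act) == len(pred)):
        raise ValueError("inputs must have the same length")
    out: dict[str, float] = {}
    for pid in dict.fromkeys(pids.tolist()):
        mask = pids == pid
        n = int(mask.sum())
        if n < min_compounds:
            continue
        k = math.ceil(fraction * n)
        idx = np.flatnonzero(mask)
        # deterministic tie-break: lower original index wins
        top_truth = set(idx[np.lexsort((idx, -act[idx]))][:k])
        top_pred = set(idx[np.lexsort((idx, -pred[idx]))][:k])
        out[str(pid)] = len(top_truth & top_pred) / k
    return out


@dataclass
class EvaluationResult:
    """Per-split, per-model metric bundle."""

    regime: str
    fold: int
    variant: str
    mcc: float
    bedroc: float | None
    n_test: int
    seed: int
    compound_descriptor: str = ""
    protein_descriptor: str = ""
    per_protein_overlap: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "compound_descriptor": self.compound_descriptor,
            "protein_descriptor": self.protein_descriptor,
            "regime": self.regime,
            "fold": self.fold,
            "variant": self.variant,
            "mcc": self.mcc,
            "bedroc": self.bedroc,
            "n_test": self.n_test,
            "seed": self.seed,
        }


def evaluate(
    model: "PCMModel",
    split: "SplitAssignment",
    table: "ActivityTable",
    compound_embeddings: "EmbeddingTable",
    protein_embeddings: "EmbeddingTable",
    threshold: float = DEFAULT_DECISION_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    compound_descriptor: str = "",
    protein_descriptor: str = "",
) -> EvaluationResult:
    """Score a trained model on the test partition of a split.

    MCC is computed at the given probability threshold; BEDROC on the
    score-ranked test set. If the test partition contains a single class,
    BEDROC is undefined and reported as None (logged).
    """
    test_idx = np.asarray(split.test, dtype=int)
    if len(test_idx) == 0:
        raise ValueError("test partition is empty")
    pairs = [(table[i].compound_id, table[i].protein_id) for i in test_idx]
    y = np.array([table[i].label for i in test_idx], dtype=int)
    scores = model.predict(pairs, compound_embeddings, protein_embeddings)
    counts = ConfusionCounts.from_predictions(y, scores, threshold)
    m = mcc(counts)
    if 0 < y.sum() < len(y):
        b = bedroc(scores, y, alpha)
    else:
        logger.info("test partition has a single class; BEDROC omitted")
        b = None
    return EvaluationResult(
        regime=split.regime,
        fold=split.fold_index,
        variant=model.config.variant,
        mcc=m,
        bedroc=b,
        n_test=len(test_idx),
        seed=split.seed,
        compound_descriptor=compound_descriptor,
        protein_descriptor=protein_descriptor,
    )
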