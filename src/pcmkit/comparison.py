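"""Aggregation and significance analysis over evaluation results.

Works on a long-format results table with one row per (compound descriptor,
protein descriptor, regime, fold, model variant) carrying the metric columns.
Provides descriptor-marginal means, full-model vs No-Interaction-Terms
percent improvement with per-regime averages, and Wilcoxon signed-rank
tests over paired fold results.

Computations keep full precision; display rounding is half-away-from-zero to
the conventional printed precision (3 decimals for MCC/BEDROC, 1 for a
percentage, 0 for an averaged percentage) via :func:`round_display`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

RESULT_COLUMNS = [
    "compound_descriptor",
    "protein_descriptor",
    "regime",
    "fold",
    "variant",
    "mcc",
    "bedroc",
    "n_test",
    "seed",
]

#: Above this sample size the exact Wilcoxon null is replaced by the normal
#: approximation with continuity correction.
WILCOXON_EXACT_MAX_N = 25


def round_display(x: float, ndigits: int = 3) -> float:
    """Half-away-from-zero rounding (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    return df


def save_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _check_matrix(df: pd.DataFrame, metric: str) -> None:
    if metric not in df.columns:
        raise ValueError(f"unknown metric column {metric!r}")
    keys = ["compound_descriptor", "protein_descriptor", "regime", "fold", "variant"]
    if df.duplicated(subset=[k for k in keys if k in df.columns]).any():
        raise ValueError("results matrix has duplicate keys")


def marginal_performance(
    df: pd.DataFrame,
    descriptor: str,
    regime: str,
    metric: str = "mcc",
    variant: str = "full",
) -> float:
    """Unweighted mean of ``metric`` over all combinations containing ``descriptor``.

    A combination "contains" a descriptor when it appears on either the
    compound or the protein side. Returns the full-precision mean; apply
    ``round_display(value, 3)`` for table output.
    """
    _check_matrix(df, metric)
    sel = df[
        (df["regime"] == regime)
        & (df["variant"] == variant)
        & ((df["compound_descriptor"] == descriptor) | (df["protein_descriptor"] == descriptor))
    ]
    if sel.empty:
        raise ValueError(f"descriptor {descriptor!r} absent for regime {regime!r}")
    return float(sel[metric].mean())


def percent_improvement(full: float, no_int: float) -> float:
    """Percent improvement of the full model over the no-interaction baseline."""
    if no_int == 0:
        raise ZeroDivisionError("no-interaction baseline metric is zero")
    return 100.0 * (full - no_int) / no_int


def improvement_grid(
    df: pd.DataFrame, regime: str, metric: str = "mcc"
) -> pd.DataFrame:
    """Per-combination percent improvement (full vs no_interaction) for a regime.

    Folds are averaged within each (combination, variant) before comparison.
    """
    _check_matrix(df, metric)
    sel = df[df["regime"] == regime]
    if sel.empty:
        raise ValueError(f"no rows for regime {regime!r}")
    agg = (
        sel.groupby(["compound_descriptor", "protein_descriptor", "variant"])[metric]
        .mean()
        .unstack("variant")
    )
    for needed in ("full", "no_interaction"):
        if needed not in agg.columns or agg[needed].isna().any():
            raise ValueError(f"missing {needed!r} rows for some combination in {regime!r}")
    agg = agg.reset_index()
    agg["pct_improvement"] = [
        percent_improvement(f, b) for f, b in zip(agg["full"], agg["no_interaction"])
    ]
    return agg


def average_improvement(df: pd.DataFrame, regime: str, metric: str = "mcc") -> float:
    """Mean per-combination percent improvement for a regime (full precision;
    display with ``round_display(value, 0)``)."""
    return float(improvement_grid(df, regime, metric)["pct_improvement"].mean())


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired samples (a vs b).

    Zero differences are dropped before ranking. The exact null distribution
    is used for n <= 25 when the absolute differences are tie-free; otherwise
    the normal approximation with continuity correction. ``alternative`` is
    "two-sided" or "greater" (a > b).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    exact_ok = len(d) <= WILCOXON_EXACT_MAX_N and len(np.unique(np.abs(d))) == len(d)
    res = stats.wilcoxon(
        d,
        alternative=alternative,
        correction=not exact_ok,
        method="exact" if exact_ok else "approx",
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonReport:
    """Bundle of marginal means, improvement grids, and pairwise significance."""

    marginal: pd.DataFrame
    improvement: pd.DataFrame
    avg_pct_improvement: dict[str, float]
    wilcoxon: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self, significance: float = 0.05) -> str:
        lines = ["Marginal performance (mean MCC per descriptor and regime):"]
        lines.append(self.marginal.to_string(index=False))
        lines.append("")
        lines.append("Full vs No-Interaction-Terms percent improvement:")
        lines.append(self.improvement.to_string(index=False))
        lines.append("")
        for regime, v in self.avg_pct_improvement.items():
            lines.append(f"Average improvement on {regime}: {round_display(v, 0):.0f}%")
        if not self.wilcoxon.empty:
            lines.append("")
            lines.append(f"Wilcoxon signed-rank contrasts (significance {significance}):")
            lines.append(self.wilcoxon.to_string(index=False))
        return "\n".join(lines)


def build_report(df: pd.DataFrame, metric: str = "mcc") -> ComparisonReport:
    """Assemble the full comparison report from a results matrix."""
    _check_matrix(df, metric)
    regimes = list(dict.fromkeys(df["regime"]))
    descriptors = sorted(
        (set(df["compound_descriptor"]) | set(df["protein_descriptor"])) - {""}
    )
    marg_rows = []
    for desc, regime in itertools.product(descriptors, regimes):
        try:
            v = marginal_performance(df, desc, regime, metric)
        except ValueError:
            continue
        marg_rows.append(
            {"descriptor": desc, "regime": regime, metric: round_display(v, 3)}
        )
    marginal = pd.DataFrame(marg_rows)

    imp_frames = []
    avg: dict[str, float] = {}
    wil_rows = []
    for regime in regimes:
        try:
            grid = improvement_grid(df, regime, metric)
        except (ValueError, ZeroDivisionError):
            continue
        grid.insert(0, "regime", regime)
        grid["pct_improvement"] = [round_display(v, 1) for v in grid["pct_improvement"]]
        imp_frames.append(grid)
        avg[regime] = average_improvement(df, regime, metric)
        # paired over folds within each combination
        sel = df[df["regime"] == regime]
        piv = sel.pivot_table(
            index=["compound_descriptor", "protein_descriptor", "fold"],
            columns="variant",
            values=metric,
        )
        if {"full", "no_interaction"} <= set(piv.columns):
            pairs = piv.dropna(subset=["full", "no_interaction"])
            if (pairs["full"] - pairs["no_interaction"]).ne(0).sum() >= 5:
                stat, p = wilcoxon_signed_rank(
                    pairs["full"].to_numpy(),
                    pairs["no_interaction"].to_numpy(),
                    alternative="greater",
                )
                wil_rows.append(
                    {
                        "regime": regime,
                        "contrast": "full>no_interaction",
                        "n_pairs": len(pairs),
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    improvement = (
        pd.concat(imp_frames, ignore_index=True) if imp_frames else pd.DataFrame()
    )
    return ComparisonReport(
        marginal=marginal,
        improvement=improvement,
        avg_pct_improvement=avg,
        wilcoxon=pd.DataFrame(wil_rows),
    )
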