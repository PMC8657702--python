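"""Readers and writers for activity tables, embedding tables, sequences and SMILES.

An *activity table* holds one row per compound-protein measurement with an
optional continuous activity (log-activity units such as pChEMBL) and a
binary active/inactive label. An *embedding table* maps opaque string IDs to
fixed-length real vectors. Both are exchanged as delimited text (comma or
tab, auto-detected) so every pipeline artifact stays human-inspectable.

IDs are case-sensitive opaque strings and are never normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Default column mapping for activity tables: role -> column name.
DEFAULT_SCHEMA = {
    "compound_id": "compound_id",
    "protein_id": "protein_id",
    "activity": "activity",
    "label": "label",
}

#: Default binarization threshold in log-activity units. The classification
#: convention of the Lenselink et al. ChEMBL benchmark; configurable
#: everywhere it is used.
DEFAULT_ACTIVITY_THRESHOLD = 6.5


@dataclass(frozen=True)
class ActivityRecord:
    """One compound-protein measurement."""

    compound_id: str
    protein_id: str
    activity_value: float | None = None
    label: int | None = None  # 1 = active, 0 = inactive

    def __post_init__(self) -> None:
        if not self.compound_id or not self.protein_id:
            raise ValueError("compound_id and protein_id must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class ActivityTable:
    """Ordered collection of deduplicated activity records."""

    records: list[ActivityRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> ActivityRecord:
        return self.records[i]

    @property
    def compound_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.compound_id)
        return list(seen)

    @property
    def protein_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.protein_id)
        return list(seen)

    @property
    def n_compounds(self) -> int:
        return len(set(r.compound_id for r in self.records))

    @property
    def n_proteins(self) -> int:
        return len(set(r.protein_id for r in self.records))

    def labels(self) -> np.ndarray:
        if any(r.label is None for r in self.records):
            raise ValueError("table contains unlabeled records")
        return np.array([r.label for r in self.records], dtype=np.int64)

    def activity_values(self) -> np.ndarray:
        if any(r.activity_value is None for r in self.records):
            raise ValueError("table contains records without activity values")
        return np.array([r.activity_value for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "protein_id": [r.protein_id for r in self.records],
                "activity": [r.activity_value for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


@dataclass
class EmbeddingTable:
    """ID-keyed matrix of fixed-length real vectors."""

    ids: list[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D array")
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("one vector row required per id")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in embedding table")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding table contains non-finite entries")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._index

    def vector(self, id_: str) -> np.ndarray:
        try:
            return self.vectors[self._index[id_]]
        except KeyError:
            raise KeyError(f"id {id_!r} not in embedding table") from None

    def subset(self, ids: Sequence[str]) -> "EmbeddingTable":
        """Rows for ``ids`` in request order; KeyError on any missing id."""
        rows = [self._index[i] if i in self._index else self._missing(i) for i in ids]
        return EmbeddingTable(list(ids), self.vectors[rows])

    @staticmethod
    def _missing(id_: str):
        raise KeyError(f"id {id_!r} not in embedding table")

    def matrix_for(self, ids: Sequence[str]) -> np.ndarray:
        rows = np.array([self._index[i] for i in ids], dtype=int)
        return self.vectors[rows]


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_activity_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ActivityTable:
    """Parse a delimited activity table into an :class:`ActivityTable`.

    ``schema`` maps the roles ``compound_id``/``protein_id`` (required) and
    ``activity``/``label`` (optional) onto column names in the file. Rows
    whose activity cell cannot be parsed as a number are dropped and counted
    in the log. Duplicate (compound, protein) pairs keep the record with the
    highest activity value (first occurrence when activities are absent or
    tied); the number dropped is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    sep = sep or _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for role in ("compound_id", "protein_id"):
        if schema[role] not in df.columns:
            raise ValueError(f"mapped column {schema[role]!r} ({role}) not in header")
    has_activity = schema.get("activity") in df.columns
    has_label = schema.get("label") in df.columns

    records: list[ActivityRecord] = []
    n_unparseable = 0
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        activity = None
        if has_activity:
            cell = row[schema["activity"]]
            if cell is not None and not (isinstance(cell, float) and math.isnan(cell)):
                try:
                    activity = float(cell)
                except (TypeError, ValueError):
                    n_unparseable += 1
                    continue
                if not math.isfinite(activity):
                    n_unparseable += 1
                    continue
        label = None
        if has_label:
            cell = row[schema["label"]]
            if cell is not None and not (isinstance(cell, float) and math.isnan(cell)):
                label = int(float(cell))
        records.append(
            ActivityRecord(
                compound_id=str(row[schema["compound_id"]]),
                protein_id=str(row[schema["protein_id"]]),
                activity_value=activity,
                label=label,
            )
        )
    if n_unparseable:
        logger.info("dropped %d rows with unparseable activity", n_unparseable)
    records, n_dup = deduplicate(records)
    if n_dup:
        logger.info("dropped %d duplicate (compound, protein) measurements", n_dup)
    if not records:
        raise ValueError(f"no parseable records in {path}")
    return ActivityTable(records)


def deduplicate(records: Iterable[ActivityRecord]) -> tuple[list[ActivityRecord], int]:
    """Keep one record per (compound, protein): the highest activity value.

    Deterministic and conservative toward activity; the first occurrence wins
    when activities are missing or tied.
    """
    best: dict[tuple[str, str], ActivityRecord] = {}
    order: list[tuple[str, str]] = []
    n_dropped = 0
    for rec in records:
        key = (rec.compound_id, rec.protein_id)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            n_dropped += 1
            old = best[key]
            if (
                rec.activity_value is not None
                and (old.activity_value is None or rec.activity_value > old.activity_value)
            ):
                best[key] = rec
    return [best[k] for k in order], n_dropped


def write_activity_table(table: ActivityTable, path: str | Path, sep: str = ",") -> None:
    table.to_dataframe().to_csv(path, sep=sep, index=False, float_format="%.17g")


def binarize(table: ActivityTable, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> ActivityTable:
    """Label records active iff ``activity_value >= threshold``.

    Continuous values are preserved; the operation is idempotent and monotone
    in the threshold. Raises if any record lacks an activity value.
    """
    out = []
    for rec in table.records:
        if rec.activity_value is None:
            raise ValueError(
                f"record ({rec.compound_id}, {rec.protein_id}) has no activity value"
            )
        out.append(replace(rec, label=int(rec.activity_value >= threshold)))
    return ActivityTable(out)


def read_embedding_table(path: str | Path, sep: str | None = None) -> EmbeddingTable:
    """Read a delimited embedding table: first column ID, rest numeric.

    The dimensionality is inferred from the first row; ragged rows, duplicate
    IDs and non-numeric cells are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _detect_sep(path)
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"empty embedding table {path}")
        dim = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if dim is None:
                dim = len(cells) - 1
                if dim < 1:
                    raise ValueError(f"{path}:{lineno}: no numeric columns")
            elif len(cells) - 1 != dim:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(cells) - 1} values, expected {dim})"
                )
            try:
                vec = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            ids.append(cells[0])
            rows.append(vec)
    if not ids:
        raise ValueError(f"no vectors in {path}")
    return EmbeddingTable(ids, np.array(rows, dtype=float))


def write_embedding_table(table: EmbeddingTable, path: str | Path, sep: str = ",") -> None:
    """Write with header ``id,dim_0..dim_{d-1}`` at full float precision."""
    with open(path, "w") as fh:
        fh.write(sep.join(["id"] + [f"dim_{j}" for j in range(table.dim)]) + "\n")
        for id_, row in zip(table.ids, table.vectors):
            fh.write(sep.join([id_] + [f"{x:.17g}" for x in row]) + "\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{protein_id: uppercase sequence}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def read_smiles(path: str | Path) -> dict[str, str]:
    """Read a ``SMILES<tab>ID`` list into ``{compound_id: smiles}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: missing ID column")
            out[parts[1].strip()] = parts[0].strip()
    return out
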