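"""Descriptor backends: precomputed embedding tables and handcrafted baselines.

Learned compound/protein embeddings (CDDD, MolBert, UniRep, SeqVec, ESM) are
consumed strictly as precomputed ID-keyed vector tables; a registry carries
their expected dimensionality and generator metadata so pipelines can
validate inputs without the multi-hundred-million-parameter generator
networks. Two handcrafted baselines are built in:

* compounds — a hashed, folded circular-substructure (Morgan) fingerprint,
  binary bits, default radius 2 folded to 1024 bits;
* proteins — an alignment-free physicochemical summary: the 20 amino-acid
  composition fractions plus the mean and standard deviation of each of five
  z-scale property scales aggregated over the sequence (dim 20 + 2*5 = 30).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .data_io import EmbeddingTable, read_embedding_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorRegistryEntry:
    name: str
    entity_kind: str  # compound | protein
    repr_size: int
    n_params: str  # of the originating generator; metadata only
    model_type: str


#: Pretrained embedding generators this toolkit knows about, with the
#: representation size each produces. Used to validate user-supplied tables.
REGISTRY: dict[str, DescriptorRegistryEntry] = {
    e.name: e
    for e in [
        DescriptorRegistryEntry("cddd", "compound", 512, "26 M", "GRU-Autoencoder"),
        DescriptorRegistryEntry("molbert", "compound", 768, "85 M", "Transformer"),
        DescriptorRegistryEntry("unirep", "protein", 256, "1.8 M", "m-LSTM"),
        DescriptorRegistryEntry("seqvec", "protein", 1024, "93 M", "Stacked LSTM"),
        DescriptorRegistryEntry("esm", "protein", 1280, "650 M", "Transformer"),
    ]
}

#: Sandberg z-scales (z1..z5) for the 20 standard amino acids: principal
#: properties summarizing hydrophobicity, size/polarizability and
#: electronic character.
Z_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def handcrafted_compound(smiles: str, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Hashed circular-substructure fingerprint folded to ``n_bits`` binary bits.

    Deterministic for a given molecule: equivalent SMILES spellings of the
    same structure give identical vectors.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=float)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def handcrafted_protein(
    sequence: str,
    scales: Mapping[str, Sequence[float]] | None = None,
    strict: bool = False,
) -> np.ndarray:
    """Alignment-free physicochemical protein descriptor.

    Concatenates (i) the 20 amino-acid composition fractions and (ii) the
    mean and standard deviation (population, ddof=0) of each property scale
    over the sequence: dim = 20 + 2 * n_scales. The unknown residue 'X'
    contributes zero to composition and is skipped in scale aggregation;
    other non-standard letters are errors in strict mode and skipped (with a
    log message) otherwise. Permutations of a sequence map to the same vector.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if scales is None:
        scale_matrix = np.array([Z_SCALES[a] for a in AMINO_ACIDS])  # 20 x 5
    else:
        cols = []
        for sname, vals in scales.items():
            if isinstance(vals, Mapping):
                col = [float(vals[a]) for a in AMINO_ACIDS]
            else:
                vals = list(vals)
                if len(vals) != 20:
                    raise ValueError(
                        f"scale {sname!r} must give 20 values in {AMINO_ACIDS} order"
                    )
                col = [float(v) for v in vals]
            cols.append(col)
        scale_matrix = np.array(cols).T  # 20 x n_scales
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros(20)
    for ch in seq:
        if ch in aa_index:
            counts[aa_index[ch]] += 1
        elif ch == "X":
            continue
        elif strict:
            raise ValueError(f"illegal residue {ch!r}")
        else:
            logger.info("skipping non-standard residue %r", ch)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    comp = counts / total
    per_residue = scale_matrix.T @ counts / total  # mean of each scale
    sq = (scale_matrix**2).T @ counts / total
    std = np.sqrt(np.maximum(sq - per_residue**2, 0.0))
    return np.concatenate([comp, per_residue, std])


class DescriptorBackend:
    """Uniform interface: a named source of fixed-length vectors per ID."""

    name: str
    entity_kind: str
    source: str

    @property
    def dim(self) -> int:
        raise NotImplementedError

    def embed(self, ids: Sequence[str], strict: bool = True) -> EmbeddingTable:
        raise NotImplementedError


class TableBackend(DescriptorBackend):
    """Precomputed embedding table (the consumption mode for learned descriptors)."""

    source = "precomputed-table"

    def __init__(self, name: str, table: EmbeddingTable, entity_kind: str = "compound"):
        self.name = name
        self.table = table
        self.entity_kind = entity_kind
        entry = REGISTRY.get(name)
        if entry is not None:
            if table.dim != entry.repr_size:
                raise ValueError(
                    f"table dim {table.dim} conflicts with registry dim "
                    f"{entry.repr_size} for descriptor {name!r}"
                )
            self.entity_kind = entry.entity_kind

    @property
    def dim(self) -> int:
        return self.table.dim

    def embed(self, ids: Sequence[str], strict: bool = True) -> EmbeddingTable:
        if strict:
            missing = [i for i in ids if i not in self.table]
            if missing:
                raise KeyError(f"ids missing from {self.name!r} table: {missing[:5]}")
            kept = list(ids)
        else:
            kept = [i for i in ids if i in self.table]
            dropped = len(ids) - len(kept)
            if dropped:
                logger.info("%s: dropped %d ids without embeddings", self.name, dropped)
        return self.table.subset(kept)


class HandcraftedCompoundBackend(DescriptorBackend):
    """Circular-fingerprint backend over an ID -> SMILES map."""

    name = "handcrafted_compound"
    entity_kind = "compound"
    source = "handcrafted"

    def __init__(self, smiles_by_id: Mapping[str, str], n_bits: int = 1024, radius: int = 2):
        self.smiles_by_id = dict(smiles_by_id)
        self.n_bits = n_bits
        self.radius = radius

    @property
    def dim(self) -> int:
        return self.n_bits

    def embed(self, ids: Sequence[str], strict: bool = True) -> EmbeddingTable:
        kept, rows = [], []
        for i in ids:
            if i not in self.smiles_by_id:
                if strict:
                    raise KeyError(f"no SMILES for id {i!r}")
                logger.info("dropping id %r without SMILES", i)
                continue
            kept.append(i)
            rows.append(handcrafted_compound(self.smiles_by_id[i], self.n_bits, self.radius))
        return EmbeddingTable(kept, np.array(rows))


class HandcraftedProteinBackend(DescriptorBackend):
    """Composition + z-scale-summary backend over an ID -> sequence map."""

    name = "handcrafted_protein"
    entity_kind = "protein"
    source = "handcrafted"

    def __init__(self, sequences_by_id: Mapping[str, str], strict: bool = False):
        self.sequences_by_id = dict(sequences_by_id)
        self.strict = strict

    @property
    def dim(self) -> int:
        return 20 + 2 * 5

    def embed(self, ids: Sequence[str], strict: bool = True) -> EmbeddingTable:
        kept, rows = [], []
        for i in ids:
            if i not in self.sequences_by_id:
                if strict:
                    raise KeyError(f"no sequence for id {i!r}")
                logger.info("dropping id %r without sequence", i)
                continue
            kept.append(i)
            rows.append(handcrafted_protein(self.sequences_by_id[i], strict=self.strict))
        return EmbeddingTable(kept, np.array(rows))


def get_backend(name: str, config: Mapping | None = None) -> DescriptorBackend:
    """Resolve a descriptor backend by name.

    ``name`` is either a registry name (requires ``config['table_path']``),
    ``"table:<path>"`` / plain ``"table"`` with a path for ad-hoc embedding
    tables, or a handcrafted baseline (``handcrafted_compound`` needs
    ``smiles`` or ``smiles_path``; ``handcrafted_protein`` needs
    ``sequences`` or ``fasta_path``).
    """
    from .data_io import read_sequences, read_smiles  # local to avoid cycles

    config = dict(config or {})
    if name.startswith("table:"):
        config.setdefault("table_path", name.split(":", 1)[1])
        name = "table"
    if name in REGISTRY or name == "table":
        path = config.get("table_path")
        table = config.get("table")
        if table is None:
            if path is None:
                raise ValueError(f"descriptor {name!r} needs a precomputed table")
            table = read_embedding_table(path)
        return TableBackend(name if name != "table" else f"table:{path}", table,
                            entity_kind=config.get("entity_kind", "compound"))
    if name == "handcrafted_compound":
        smiles = config.get("smiles") or read_smiles(config["smiles_path"])
        return HandcraftedCompoundBackend(
            smiles, n_bits=config.get("n_bits", 1024), radius=config.get("radius", 2)
        )
    if name == "handcrafted_protein":
        seqs = config.get("sequences") or read_sequences(config["fasta_path"])
        return HandcraftedProteinBackend(seqs, strict=config.get("strict", False))
    raise ValueError(f"unknown descriptor backend {name!r}")
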