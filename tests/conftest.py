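import numpy as np
import pandas as pd
import pytest

from pcmkit.data_io import ActivityRecord, ActivityTable, EmbeddingTable

# Published benchmark test MCCs for the six descriptor combinations
# (compound x protein descriptor) under each split regime, and their
# no-interaction baseline counterparts: worked inputs for the aggregation
# arithmetic.
BENCHMARK_MCC = {
    ("cddd", "unirep"): {"random": 0.645, "lcco": 0.490, "lpo": 0.307},
    ("cddd", "seqvec"): {"random": 0.575, "lcco": 0.475, "lpo": 0.322},
    ("cddd", "esm"): {"random": 0.609, "lcco": 0.484, "lpo": 0.297},
    ("molbert", "unirep"): {"random": 0.654, "lcco": 0.505, "lpo": 0.312},
    ("molbert", "seqvec"): {"random": 0.607, "lcco": 0.487, "lpo": 0.311},
    ("molbert", "esm"): {"random": 0.630, "lcco": 0.499, "lpo": 0.294},
}

BASELINE_MCC = {
    ("cddd", "unirep"): {"random": 0.565, "lcco": 0.424, "lpo": 0.281},
    ("cddd", "seqvec"): {"random": 0.548, "lcco": 0.411, "lpo": 0.287},
    ("cddd", "esm"): {"random": 0.557, "lcco": 0.416, "lpo": 0.287},
    ("molbert", "unirep"): {"random": 0.574, "lcco": 0.439, "lpo": 0.283},
    ("molbert", "seqvec"): {"random": 0.558, "lcco": 0.430, "lpo": 0.290},
    ("molbert", "esm"): {"random": 0.567, "lcco": 0.434, "lpo": 0.292},
}


def benchmark_frame() -> pd.DataFrame:
    rows = []
    for variant, table in (("full", BENCHMARK_MCC), ("no_interaction", BASELINE_MCC)):
        for (c, p), per_regime in table.items():
            for regime, v in per_regime.items():
                rows.append(dict(compound_descriptor=c, protein_descriptor=p, regime=regime,
                                 fold=0, variant=variant, mcc=v, bedroc=np.nan,
                                 n_test=0, seed=0))
    return pd.DataFrame(rows)


@pytest.fixture
def toy_table() -> ActivityTable:
    """Nine measurements over 3 compounds x 3 proteins with labels."""
    recs = []
    for i, c in enumerate(["c1", "c2", "c3"]):
        for j, p in enumerate(["p1", "p2", "p3"]):
            value = 5.0 + i + 0.5 * j
            recs.append(ActivityRecord(c, p, value, int(value >= 6.5)))
    return ActivityTable(recs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_table(n_compounds: int, n_proteins: int, rng: np.random.Generator,
               density: float = 1.0) -> ActivityTable:
    recs = []
    for i in range(n_compounds):
        for j in range(n_proteins):
            if rng.random() <= density:
                recs.append(
                    ActivityRecord(f"c{i}", f"p{j}", float(rng.normal(6.5, 1)), int(rng.random() < 0.5))
                )
    return ActivityTable(recs)


def make_embeddings(ids, dim, rng) -> EmbeddingTable:
    return EmbeddingTable(list(ids), rng.standard_normal((len(ids), dim)))
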