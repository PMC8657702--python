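import numpy as np
import pytest

from pcmkit import splits
from pcmkit.data_io import EmbeddingTable

from conftest import make_embeddings, make_table


def all_indices(s: splits.SplitAssignment) -> set:
    return set(s.train) | set(s.valid) | set(s.test)


class TestSplitRandom:
    def test_sizes_match_fractions(self, rng):
        t = make_table(20, 5, rng)  # 100 records
        s = splits.split_random(t, (0.7, 0.1, 0.2), seed=1)
        assert (len(s.train), len(s.valid), len(s.test)) == (70, 10, 20)

    def test_seed_determinism(self, rng):
        t = make_table(10, 5, rng)
        a = splits.split_random(t, seed=1)
        b = splits.split_random(t, seed=1)
        np.testing.assert_array_equal(a.test, b.test)
        c = splits.split_random(t, seed=2)
        assert set(a.test) != set(c.test)

    def test_too_few_records(self, rng):
        t = make_table(1, 2, rng)
        with pytest.raises(ValueError, match="at least 3"):
            splits.split_random(t, seed=0)


class TestClusterCompounds:
    def test_two_blobs_recovered(self, rng):
        a = rng.normal([5, 0, 0], 0.1, size=(20, 3))
        b = rng.normal([0, 5, 0], 0.1, size=(20, 3))
        emb = EmbeddingTable([f"c{i}" for i in range(40)], np.vstack([a, b]))
        clus = splits.cluster_compounds(emb, k=2, seed=0)
        labels = np.array([clus.cluster_of[f"c{i}"] for i in range(40)])
        # brute-force nearest-centroid oracle on the known blob structure
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[20]

    def test_singletons_when_k_equals_n(self, rng):
        emb = make_embeddings([f"c{i}" for i in range(6)], 4, rng)
        clus = splits.cluster_compounds(emb, k=6, seed=0)
        assert sorted(clus.cluster_of.values()) == list(range(6))

    def test_duplicate_vectors_share_cluster(self, rng):
        v = rng.standard_normal((3, 4))
        emb = EmbeddingTable(["a", "b", "c", "a2"], np.vstack([v, v[0]]))
        clus = splits.cluster_compounds(emb, k=3, seed=0)
        assert clus.cluster_of["a"] == clus.cluster_of["a2"]

    def test_k_exceeds_n(self, rng):
        emb = make_embeddings(["a", "b"], 3, rng)
        with pytest.raises(ValueError, match="exceeds"):
            splits.cluster_compounds(emb, k=5)


class TestLCCO:
    @pytest.fixture
    def clustered(self, rng):
        t = make_table(12, 4, rng)
        emb = make_embeddings(t.compound_ids, 5, rng)
        return t, splits.cluster_compounds(emb, k=3, seed=0)

    def test_folds_partition_records(self, clustered):
        t, clus = clustered
        seen = []
        for c in range(clus.k):
            s = splits.split_lcco(t, clus, c, seed=1)
            seen.extend(s.test)
            assert all_indices(s) == set(range(len(t)))
        assert sorted(seen) == list(range(len(t)))

    def test_no_cluster_leak(self, clustered):
        t, clus = clustered
        s = splits.split_lcco(t, clus, 0, seed=1)
        test_clusters = {clus.cluster_of[t[int(i)].compound_id] for i in s.test}
        train_clusters = {clus.cluster_of[t[int(i)].compound_id] for i in np.concatenate([s.train, s.valid])}
        assert test_clusters == {0} and 0 not in train_clusters

    def test_test_size_is_cluster_size(self, clustered):
        t, clus = clustered
        n0 = sum(clus.cluster_of[r.compound_id] == 0 for r in t)
        assert len(splits.split_lcco(t, clus, 0, seed=1).test) == n0

    def test_out_of_range_cluster(self, clustered):
        t, clus = clustered
        with pytest.raises(ValueError, match="out of range"):
            splits.split_lcco(t, clus, 99, seed=1)


class TestLPO:
    def test_each_fold_holds_out_two_of_ten_proteins(self, rng):
        t = make_table(10, 10, rng)
        for f in range(5):
            s = splits.split_lpo(t, 5, f, seed=3)
            held = {t[int(i)].protein_id for i in s.test}
            assert len(held) == 2
            train_prots = {t[int(i)].protein_id for i in np.concatenate([s.train, s.valid])}
            assert not held & train_prots

    def test_fold_tests_cover_all_records(self, rng):
        t = make_table(8, 6, rng, density=0.7)
        seen = []
        for f in range(3):
            seen.extend(splits.split_lpo(t, 3, f, seed=3).test)
        assert sorted(seen) == list(range(len(t)))

    def test_errors(self, rng):
        t = make_table(5, 3, rng)
        with pytest.raises(ValueError, match="more folds"):
            splits.split_lpo(t, 10, 0)
        with pytest.raises(ValueError, match="out of range"):
            splits.split_lpo(t, 2, 5)


class TestNNDistance:
    def test_subset_gives_zero(self, rng):
        train = make_embeddings([f"c{i}" for i in range(10)], 6, rng)
        test = train.subset(["c3", "c7"])
        assert splits.nn_distance_diagnostic(test, train) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_gives_one(self):
        train = EmbeddingTable(["a", "b"], np.array([[1.0, 0, 0], [0, 1.0, 0]]))
        test = EmbeddingTable(["t"], np.array([[0, 0, 2.0]]))
        assert splits.nn_distance_diagnostic(test, train) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        test = make_embeddings([f"t{i}" for i in range(3)], 4, rng)
        train = make_embeddings([f"r{i}" for i in range(5)], 4, rng)
        expected = np.mean(
            [
                min(
                    1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
                    for v in train.vectors
                )
                for u in test.vectors
            ]
        )
        assert splits.nn_distance_diagnostic(test, train) == pytest.approx(expected, rel=1e-12)

    def test_errors(self, rng):
        a = make_embeddings(["a"], 3, rng)
        b = make_embeddings(["b"], 4, rng)
        with pytest.raises(ValueError, match="mismatch"):
            splits.nn_distance_diagnostic(a, b)
        z = EmbeddingTable(["z"], np.zeros((1, 3)))
        with pytest.raises(ValueError, match="zero vector"):
            splits.nn_distance_diagnostic(z, a)


class TestInvariantsAcrossRegimes:
    """Partition/disjointness contract over randomly drawn instances."""

    @pytest.mark.parametrize("trial", range(5))
    def test_partition_contract(self, trial):
        rng = np.random.default_rng(100 + trial)
        t = make_table(int(rng.integers(8, 20)), int(rng.integers(3, 8)), rng, density=0.8)
        emb = make_embeddings(t.compound_ids, 4, rng)
        k = min(3, len(t.compound_ids))
        clus = splits.cluster_compounds(emb, k=k, seed=trial)
        candidates = [splits.split_random(t, seed=trial)]
        for c in range(k):
            try:
                candidates.append(splits.split_lcco(t, clus, c, seed=trial))
            except ValueError:
                pass  # empty cluster
        n_folds = min(3, t.n_proteins)
        candidates.extend(splits.split_lpo(t, n_folds, f, seed=trial) for f in range(n_folds))
        for s in candidates:
            assert all_indices(s) == set(range(len(t)))
            assert len(s.train) + len(s.valid) + len(s.test) == len(t)

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            splits.SplitAssignment("random", 0, [0, 1], [1, 2], [3], seed=0)


class TestSplitFiles:
    def test_roundtrip(self, tmp_path, rng):
        t = make_table(10, 4, rng)
        s = splits.split_random(t, seed=5)
        path = tmp_path / "split.tsv"
        splits.write_split(s, t, path)
        back = splits.read_split(path)
        assert back.regime == "random" and back.seed == 5
        assert set(back.test) == set(s.test)
        assert set(back.train) == set(s.train)
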