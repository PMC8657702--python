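import numpy as np
import pytest

from pcmkit import metrics, model, splits
from pcmkit.data_io import ActivityRecord, ActivityTable, EmbeddingTable
from pcmkit.model import ModelConfig, build, train

from conftest import make_embeddings


def separable_problem(rng, n_compounds=40, n_proteins=5, dim=4):
    """Labels are the sign of a fixed linear functional of the joint features."""
    xc = rng.standard_normal((n_compounds, dim))
    xp = rng.standard_normal((n_proteins, dim))
    w = rng.standard_normal(2 * dim)
    cids = [f"c{i}" for i in range(n_compounds)]
    pids = [f"p{i}" for i in range(n_proteins)]
    recs = []
    for i in range(n_compounds):
        for j in range(n_proteins):
            z = float(w @ np.concatenate([xc[i], xp[j]]))
            recs.append(ActivityRecord(cids[i], pids[j], z, int(z > 0)))
    return ActivityTable(recs), EmbeddingTable(cids, xc), EmbeddingTable(pids, xp)


class TestBuild:
    def test_full_parameter_count_closed_form(self):
        cfg = ModelConfig(variant="full", hidden_sizes=(2048, 1024, 512))
        m = build(cfg, 768, 256)
        expected = (
            1024 * 2048 + 2048 * 1024 + 1024 * 512 + 512 * 1  # weights
            + 2048 + 1024 + 512 + 1  # biases
        )
        assert m.n_parameters == expected

    def test_no_interaction_towers_are_separate(self):
        cfg = ModelConfig(variant="no_interaction", hidden_sizes=(16, 8, 4))
        m = build(cfg, 10, 6)
        assert len(m.networks) == 2
        # compound tower consumes only the compound vector, protein tower only the protein vector
        assert m.networks[0].weights[0].shape[0] == 10
        assert m.networks[1].weights[0].shape[0] == 6

    def test_seeded_init_is_reproducible(self):
        cfg = ModelConfig(variant="full", hidden_sizes=(8, 8, 8), seed=11)
        a, b = build(cfg, 5, 5), build(cfg, 5, 5)
        for wa, wb in zip(a.networks[0].weights, b.networks[0].weights):
            np.testing.assert_array_equal(wa, wb)

    def test_three_layers_enforced(self):
        with pytest.raises(ValueError, match="3 hidden layers"):
            ModelConfig(hidden_sizes=(10, 10))


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(0)
    table, cemb, pemb = separable_problem(rng)
    s = splits.split_random(table, (0.7, 0.15, 0.15), seed=1)
    cfg = ModelConfig(variant="full", hidden_sizes=(32, 16, 8), dropout=0.0,
                      max_epochs=300, early_stop_patience=30, seed=2)
    m = train(build(cfg, 4, 4), s, cemb, pemb, table)
    return m, s, table, cemb, pemb


class TestTrain:
    def test_separable_data_reaches_perfect_training_mcc(self, trained):
        m, s, table, cemb, pemb = trained
        pairs = [(table[int(i)].compound_id, table[int(i)].protein_id) for i in s.train]
        y = np.array([table[int(i)].label for i in s.train])
        scores = m.predict(pairs, cemb, pemb)
        assert metrics.mcc(metrics.ConfusionCounts.from_predictions(y, scores)) == 1.0

    def test_best_validation_weights_restored(self, trained):
        m, s, table, cemb, pemb = trained
        xc = cemb.matrix_for([table[int(i)].compound_id for i in s.valid])
        xp = pemb.matrix_for([table[int(i)].protein_id for i in s.valid])
        y = np.array([table[int(i)].label for i in s.valid], dtype=float)
        probs = m.predict_matrix(xc, xp)
        val_loss = -np.mean(y * np.log(probs) + (1 - y) * np.log(1 - probs))
        best_logged = min(e["val_loss"] for e in m.training_log)
        assert val_loss == pytest.approx(best_logged, rel=1e-9)

    def test_early_stopping_bounds_epochs(self, trained):
        m, *_ = trained
        losses = [e["val_loss"] for e in m.training_log]
        best_epoch = int(np.argmin(losses))
        assert len(losses) <= best_epoch + 1 + m.config.early_stop_patience

    def test_learning_rate_halves_on_plateau(self, rng):
        # pure-noise labels: validation loss plateaus almost immediately
        table, cemb, pemb = separable_problem(rng, n_compounds=10, n_proteins=4)
        from dataclasses import replace as dc_replace

        noisy = ActivityTable(
            [dc_replace(r, label=int(rng.random() < 0.5)) for r in table]
        )
        s = splits.split_random(noisy, seed=1)
        cfg = ModelConfig(variant="full", hidden_sizes=(4, 4, 4), max_epochs=300,
                          lr_halving_patience=3, early_stop_patience=12,
                          min_delta=0.02, seed=2)
        m = train(build(cfg, 4, 4), s, cemb, pemb, noisy)
        lrs = [e["lr"] for e in m.training_log]
        assert lrs[0] == cfg.learning_rate
        assert min(lrs) < cfg.learning_rate  # halving fired on the plateau
        assert len(lrs) < cfg.max_epochs  # and the early stop ended the run

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(3)
        table, cemb, pemb = separable_problem(rng, n_compounds=15, n_proteins=4)
        s = splits.split_random(table, seed=4)
        cfg = ModelConfig(variant="full", hidden_sizes=(8, 8, 8), max_epochs=15,
                          early_stop_patience=5, seed=5)
        m1 = train(build(cfg, 4, 4), s, cemb, pemb, table)
        m2 = train(build(cfg, 4, 4), s, cemb, pemb, table)
        for wa, wb in zip(m1.networks[0].weights, m2.networks[0].weights):
            np.testing.assert_array_equal(wa, wb)

    def test_missing_embedding_errors(self, rng):
        table = ActivityTable([ActivityRecord("c0", "p0", 6.0, 1),
                               ActivityRecord("c1", "p0", 5.0, 0),
                               ActivityRecord("c2", "p0", 7.0, 1),
                               ActivityRecord("c3", "p0", 5.5, 0)])
        cemb = make_embeddings(["c0", "c1"], 3, rng)
        pemb = make_embeddings(["p0"], 3, rng)
        s = splits.split_random(table, (0.5, 0.25, 0.25), seed=0)
        cfg = ModelConfig(hidden_sizes=(4, 4, 4), max_epochs=2)
        with pytest.raises(ValueError, match="missing embedding"):
            train(build(cfg, 3, 3), s, cemb, pemb, table)


class TestPredict:
    def test_outputs_strictly_inside_unit_interval(self, rng):
        cfg = ModelConfig(variant="full", hidden_sizes=(8, 8, 8), seed=0)
        m = build(cfg, 3, 3)
        cemb = make_embeddings(["c0", "c1"], 3, rng)
        pemb = make_embeddings(["p0", "p1"], 3, rng)
        p = m.predict([("c0", "p0"), ("c1", "p1")], cemb, pemb)
        assert np.all((p > 0) & (p < 1))

    def test_no_interaction_quartet_additivity_is_exact(self, rng):
        cfg = ModelConfig(variant="no_interaction", hidden_sizes=(8, 8, 8), seed=0)
        m = build(cfg, 3, 3)
        cemb = make_embeddings(["c1", "c2"], 3, rng)
        pemb = make_embeddings(["p1", "p2"], 3, rng)
        p = lambda c, pr: m.predict([(c, pr)], cemb, pemb)[0]
        lhs = p("c1", "p1") + p("c2", "p2")
        rhs = p("c1", "p2") + p("c2", "p1")
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_full_model_breaks_additivity_on_interacting_data(self):
        # product-structured labels force a learned interaction term
        rng = np.random.default_rng(8)
        xc = np.array([[1.0, 0], [-1.0, 0]])
        xp = np.array([[1.0, 0], [-1.0, 0]])
        cids, pids = ["c1", "c2"], ["p1", "p2"]
        recs = []
        for _ in range(2):  # train on one copy of the quartet, validate on the other
            for i, c in enumerate(cids):
                for j, p in enumerate(pids):
                    label = int(xc[i, 0] * xp[j, 0] > 0)
                    recs.append(ActivityRecord(f"{c}", f"{p}", float(label), label))
        table = ActivityTable(recs)
        cemb = EmbeddingTable(cids, xc + 1e-3 * rng.standard_normal((2, 2)))
        pemb = EmbeddingTable(pids, xp + 1e-3 * rng.standard_normal((2, 2)))
        s = splits.SplitAssignment("random", 0, [0, 1, 2, 3], [4, 5, 6, 7], [], seed=0)
        cfg = ModelConfig(variant="full", hidden_sizes=(16, 8, 4), dropout=0.0,
                          max_epochs=400, early_stop_patience=50, seed=1)
        m = train(build(cfg, 2, 2), s, cemb, pemb, table)
        p = lambda c, pr: m.predict([(c, pr)], cemb, pemb)[0]
        contrast = p("c1", "p1") + p("c2", "p2") - p("c1", "p2") - p("c2", "p1")
        assert abs(contrast) > 0.5

    def test_unknown_id_errors(self, rng):
        cfg = ModelConfig(hidden_sizes=(4, 4, 4))
        m = build(cfg, 3, 3)
        cemb = make_embeddings(["c0"], 3, rng)
        pemb = make_embeddings(["p0"], 3, rng)
        with pytest.raises(KeyError):
            m.predict([("nope", "p0")], cemb, pemb)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = ModelConfig(variant="no_interaction", hidden_sizes=(8, 8, 8), seed=3)
        m = build(cfg, 4, 5)
        cemb = make_embeddings(["c0", "c1"], 4, rng)
        pemb = make_embeddings(["p0"], 5, rng)
        path = tmp_path / "model.npz"
        m.save(path)
        back = model.PCMModel.load(path)
        np.testing.assert_array_equal(
            m.predict([("c0", "p0"), ("c1", "p0")], cemb, pemb),
            back.predict([("c0", "p0"), ("c1", "p0")], cemb, pemb),
        )
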