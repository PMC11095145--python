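import numpy as np
import pytest
from rdkit import Chem

from dualscreen.balance import LabeledMatrix
from dualscreen.evalmetrics import classification_metrics
from dualscreen.models import (
    GraphBatch,
    GraphNetConfig,
    SearchError,
    TabularNetConfig,
    cross_validate,
    hyperparameter_search,
    load_model,
    predict,
    save_model,
    train_graph,
    train_tabular,
)
from dualscreen.molgraph import featurize_graph

QUICK_TAB = dict(hidden_sizes=(32,), max_epochs=40, patience=10, batch_size=32)


@pytest.fixture(scope="module")
def blobs():
    """Two well-separated Gaussian blobs: linearly separable by design."""
    rng = np.random.default_rng(7)
    x = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(6, 1, (100, 2))])
    y = np.array([0] * 100 + [1] * 100)
    return LabeledMatrix(x, y, [f"s{i}" for i in range(200)])


@pytest.fixture(scope="module")
def blob_model(blobs):
    return train_tabular(blobs, TabularNetConfig(seed=1, max_epochs=200, **{k: v for k, v in QUICK_TAB.items() if k != "max_epochs"}))


class TestTabular:
    def test_separable_data_perfect_training_accuracy(self, blobs, blob_model):
        probs = predict(blob_model, blobs.x)
        report = classification_metrics(blobs.y, probs)
        assert report.accuracy == 1.0

    def test_same_seed_same_fingerprint(self, blobs):
        cfg = TabularNetConfig(seed=3, **QUICK_TAB)
        m1 = train_tabular(blobs, cfg)
        m2 = train_tabular(blobs, cfg)
        assert m1.training_fingerprint == m2.training_fingerprint

    def test_different_seed_different_fingerprint(self, blobs):
        m1 = train_tabular(blobs, TabularNetConfig(seed=3, **QUICK_TAB))
        m2 = train_tabular(blobs, TabularNetConfig(seed=4, **QUICK_TAB))
        assert m1.training_fingerprint != m2.training_fingerprint

    def test_constant_labels_rejected(self, rng):
        data = LabeledMatrix(rng.normal(size=(20, 3)), np.ones(20, dtype=int), [str(i) for i in range(20)])
        with pytest.raises(ValueError, match="both classes"):
            train_tabular(data, TabularNetConfig())

    def test_nonfinite_inputs_rejected(self, blobs):
        x = blobs.x.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_tabular(LabeledMatrix(x, blobs.y, blobs.ids), TabularNetConfig())

    def test_focal_loss_training_works(self, blobs):
        model = train_tabular(blobs, TabularNetConfig(seed=1, loss="focal", **QUICK_TAB))
        probs = predict(model, blobs.x)
        assert classification_metrics(blobs.y, probs).auc > 0.95

    def test_smote_sampler_path(self, rng):
        x = np.vstack([rng.normal(0, 1, (80, 3)), rng.normal(4, 1, (16, 3))])
        y = np.array([0] * 80 + [1] * 16)
        data = LabeledMatrix(x, y, [str(i) for i in range(96)])
        model = train_tabular(data, TabularNetConfig(seed=2, sampler="smote", **QUICK_TAB))
        assert classification_metrics(y, predict(model, x)).auc > 0.9


class TestPredict:
    def test_codomain_and_alignment(self, blobs, blob_model):
        probs = predict(blob_model, blobs.x)
        assert probs.shape == (len(blobs),)
        assert ((probs > 0) & (probs < 1)).all()

    def test_batch_independence(self, blobs, blob_model):
        single = predict(blob_model, blobs.x[:1])
        batched = predict(blob_model, blobs.x[:50])
        assert single[0] == pytest.approx(batched[0], abs=1e-6)

    def test_input_permutation_permutes_output(self, blobs, blob_model, rng):
        perm = rng.permutation(len(blobs))
        probs = predict(blob_model, blobs.x)
        probs_perm = predict(blob_model, blobs.x[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-12)

    def test_width_mismatch_rejected(self, blob_model):
        with pytest.raises(ValueError, match="features"):
            predict(blob_model, np.zeros((3, 5)))


@pytest.fixture(scope="module")
def ring_data(vocabulary):
    """Labels = contains an aromatic nitrogen (graph-detectable)."""

    def has_arom_n(s):
        mol = Chem.MolFromSmiles(s)
        return any(a.GetSymbol() == "N" and a.GetIsAromatic() for a in mol.GetAtoms())

    smis = list(vocabulary[::3])[:200]
    graphs = [featurize_graph(s, str(i)) for i, s in enumerate(smis)]
    y = np.array([has_arom_n(s) for s in smis], dtype=int)
    return graphs, y


@pytest.fixture(scope="module")
def ring_model(ring_data):
    graphs, y = ring_data
    return train_graph(graphs, y, GraphNetConfig(seed=0, hidden_dim=32, max_epochs=150))


class TestGraphNet:
    def test_hand_oracle_two_atom_chain(self):
        """Ethane-like 2-node graph, planted 1-D features [1, 3], one conv
        layer with W=1, b=0: A_hat is all 0.5, so H' = [2, 2], pool = 2."""
        batch = GraphBatch.from_arrays([np.array([[1.0], [3.0]])], [np.array([[0, 1]])])
        np.testing.assert_allclose(batch.adj_norm.toarray(), [[0.5, 0.5], [0.5, 0.5]])
        h = np.maximum((batch.adj_norm @ batch.features) @ np.array([[1.0]]), 0)
        np.testing.assert_allclose(h.ravel(), [2.0, 2.0])
        np.testing.assert_allclose((batch.pooling @ h).ravel(), [2.0])

    def test_detects_planted_substructure(self, ring_data, ring_model):
        graphs, y = ring_data
        probs = predict(ring_model, graphs)
        assert classification_metrics(y, probs).auc >= 0.9

    def test_atom_relabeling_leaves_predictions_unchanged(self, ring_data, ring_model, rng):
        graphs, _ = ring_data
        smis = ["c1ccncc1", "CSc1ccc(Cl)cc1", "OCC(O)CO"]
        orig = [featurize_graph(s) for s in smis]
        permuted = []
        for s in smis:
            mol = Chem.MolFromSmiles(s)
            perm = list(map(int, rng.permutation(mol.GetNumAtoms())))
            permuted.append(featurize_graph(Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)))
        np.testing.assert_allclose(predict(ring_model, orig), predict(ring_model, permuted), atol=1e-6)

    def test_duplicate_graph_in_batch(self, ring_data, ring_model):
        graphs, _ = ring_data
        p1 = predict(ring_model, [graphs[0]])
        p2 = predict(ring_model, [graphs[0], graphs[0], graphs[1]])
        assert p1[0] == pytest.approx(p2[0], abs=1e-9)
        assert p2[0] == pytest.approx(p2[1], abs=1e-12)

    def test_determinism(self, ring_data):
        graphs, y = ring_data
        cfg = GraphNetConfig(seed=5, hidden_dim=8, max_epochs=10)
        assert train_graph(graphs, y, cfg).training_fingerprint == train_graph(graphs, y, cfg).training_fingerprint

    def test_empty_graph_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_graph([], np.array([]), GraphNetConfig())


class TestCrossValidate:
    def test_folds_partition_and_stratify(self, blobs):
        report = cross_validate(blobs, TabularNetConfig(seed=0, max_epochs=5, hidden_sizes=(8,)), k=5, seed=1)
        assert len(report.per_fold) == 5
        sizes = [m.n for m in report.per_fold]
        assert sum(sizes) == len(blobs)
        assert max(sizes) - min(sizes) <= 1
        # per-fold class counts within +-1 of proportional
        for m in report.per_fold:
            assert abs((m.tp + m.fn) - 20) <= 1

    def test_tie_breaks_to_lowest_fold(self, blobs):
        # separable data: every fold reaches F1 = 1.0, so ties -> fold 0
        report = cross_validate(blobs, TabularNetConfig(seed=0, max_epochs=60, hidden_sizes=(16,)), k=3, seed=0)
        f1s = [m.f1 for m in report.per_fold]
        assert report.selected_fold == int(np.argmax(f1s))
        if len(set(f1s)) == 1:
            assert report.selected_fold == 0

    def test_selected_fold_maximizes_f1(self, blobs):
        report = cross_validate(blobs, TabularNetConfig(seed=0, max_epochs=5, hidden_sizes=(8,)), k=4, seed=2)
        best = max(m.f1 for m in report.per_fold)
        assert report.per_fold[report.selected_fold].f1 == best

    def test_small_class_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError, match="5-fold"):
            cross_validate(LabeledMatrix(x, y, [str(i) for i in range(20)]), TabularNetConfig(), k=5, seed=0)

    def test_reproducible_fold_assignment(self, blobs):
        cfg = TabularNetConfig(seed=0, max_epochs=3, hidden_sizes=(8,))
        r1 = cross_validate(blobs, cfg, k=3, seed=9)
        r2 = cross_validate(blobs, cfg, k=3, seed=9)
        assert [m.f1 for m in r1.per_fold] == [m.f1 for m in r2.per_fold]


class TestHyperparameterSearch:
    def test_single_trial_returns_it(self):
        best, trials = hyperparameter_search({"a": [1, 2]}, lambda c: float(c["a"]), budget=1, seed=0)
        assert len(trials) == 1 and best == trials[0].config

    def test_exhaustive_indicator_finds_best_cell(self):
        best, _ = hyperparameter_search(
            {"cell": [0, 1]}, lambda c: 1.0 if c["cell"] == 1 else 0.0, budget=16, seed=1
        )
        assert best["cell"] == 1

    def test_same_seed_same_trajectory(self):
        space = {"lr": (1e-4, 1e-1), "width": [8, 16, 32]}
        _, t1 = hyperparameter_search(space, lambda c: c["lr"], budget=5, seed=7)
        _, t2 = hyperparameter_search(space, lambda c: c["lr"], budget=5, seed=7)
        assert [t.config for t in t1] == [t.config for t in t2]

    def test_all_failures_raise_with_log(self):
        def boom(c):
            raise RuntimeError("nope")

        with pytest.raises(SearchError) as err:
            hyperparameter_search({"a": [1]}, boom, budget=3, seed=0)
        assert len(err.value.trials) == 3


class TestModelArchive:
    def test_round_trip_preserves_predictions(self, blobs, blob_model, tmp_path):
        path = tmp_path / "model.npz"
        save_model(blob_model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(predict(loaded, blobs.x), predict(blob_model, blobs.x), atol=1e-12)
        assert loaded.training_fingerprint == blob_model.training_fingerprint

    def test_graph_model_round_trip(self, tmp_path):
        graphs = [featurize_graph(s) for s in ("CCO", "c1ccncc1", "CCN", "c1ccccc1", "CCC", "CNC")]
        y = np.array([0, 1, 0, 1, 0, 1])
        model = train_graph(graphs, y, GraphNetConfig(seed=0, hidden_dim=4, max_epochs=5, val_frac=0.34))
        path = tmp_path / "g.npz"
        save_model(model, path)
        np.testing.assert_allclose(predict(load_model(path), graphs), predict(model, graphs), atol=1e-12)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(open(path, "wb"), meta='{"magic": "other"}')
        with pytest.raises(ValueError, match="archive"):
            load_model(path)
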