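import numpy as np
import pandas as pd
import pytest

from dualscreen.compound_io import ValidationError
from dualscreen.screen import (
    ScreenConfig,
    applicability_domain,
    cumulative_score,
    embed_map,
    perplexity_calibration,
    predict_attributes,
    run_screen,
)
from dualscreen.synthfix import ScreenFixtureSpec, default_schema, generate_screen_fixture


@pytest.fixture(scope="module")
def schema():
    return default_schema()


@pytest.fixture(scope="module")
def config(schema):
    return ScreenConfig.from_schema(schema)


def make_table(schema, rows, ids=None):
    ids = ids or [f"c{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, columns=schema.attribute_ids, index=pd.Index(ids, name="compound_id"))


class TestScreenConfig:
    def test_gate_excluded_from_score_by_default(self, schema, config):
        assert config.gate_attribute == "bbb"
        assert "bbb" not in config.score_attributes
        assert len(config.score_attributes) == 9

    def test_ten_attribute_convention_switch(self, schema):
        cfg = ScreenConfig.from_schema(schema, include_gate_in_score=True)
        assert cfg.score_attributes[0] == "bbb"
        assert len(cfg.score_attributes) == 10

    def test_threshold_cannot_exceed_scored_attributes(self, schema):
        with pytest.raises(ValidationError, match="score_threshold"):
            ScreenConfig.from_schema(schema, score_threshold=10)


class TestCumulativeScore:
    def test_binarized_sum(self, schema, config):
        row = [0.9] + [0.9, 0.9, 0.9, 0.1, 0.9, 0.9, 0.1, 0.1, 0.9]  # gate + 9 activities
        table = make_table(schema, [row])
        assert cumulative_score(table, config).iloc[0] == 6

    def test_extremes(self, schema, config):
        table = make_table(schema, [[0.0] * 10, [1.0] * 10])
        scores = cumulative_score(table, config)
        assert list(scores) == [0, 9]

    def test_column_order_invariance(self, schema, config):
        rng = np.random.default_rng(0)
        table = make_table(schema, rng.uniform(size=(5, 10)))
        shuffled = table[list(reversed(table.columns))]
        pd.testing.assert_series_equal(
            cumulative_score(table, config), cumulative_score(shuffled, config)
        )


class TestRunScreen:
    def test_three_compound_funnel(self, schema, config):
        # A: gate pass, score 6, nontoxic -> hit.  B: gate fail, score 9.
        # C: gate pass, score 3.
        rows = [
            [0.9] + [0.9] * 6 + [0.1] * 3,
            [0.1] + [0.9] * 9,
            [0.9] + [0.9] * 3 + [0.1] * 6,
        ]
        table = make_table(schema, rows, ids=["A", "B", "C"])
        toxic = pd.Series([False, False, False], index=table.index)
        result = run_screen(table, toxic, config)
        assert result.hits == ["A"]
        assert result.stage_counts == {
            "n_input": 3, "n_gate_pass": 2, "n_score_pass": 1, "n_nontoxic": 1
        }

    def test_empty_input(self, schema, config):
        table = make_table(schema, np.empty((0, 10)))
        result = run_screen(table, pd.Series(dtype=bool), config)
        assert result.hits == []
        assert all(v == 0 for v in result.stage_counts.values())

    def test_planted_fixture_counts_exact(self):
        fixture = generate_screen_fixture(ScreenFixtureSpec(n=50, seed=7))
        cfg = ScreenConfig.from_schema(fixture.schema)
        result = run_screen(fixture.table, fixture.toxic, cfg)
        assert result.stage_counts == fixture.truth["stage_counts"]
        assert sorted(result.hits) == sorted(fixture.truth["final_hits"])

    def test_ranking_is_reproducible_total_order(self):
        fixture = generate_screen_fixture(ScreenFixtureSpec(n=80, seed=3, activity_rate=0.7))
        cfg = ScreenConfig.from_schema(fixture.schema)
        r1 = run_screen(fixture.table, fixture.toxic, cfg)
        r2 = run_screen(fixture.table, fixture.toxic, cfg)
        assert r1.hits == r2.hits
        ranks = r1.frame.loc[r1.hits, "rank"]
        assert list(ranks) == list(range(1, len(r1.hits) + 1))
        # score weakly decreasing down the ranking
        scores = list(r1.frame.loc[r1.hits, "score"])
        assert scores == sorted(scores, reverse=True)

    def test_stage_counts_weakly_decreasing(self):
        fixture = generate_screen_fixture(ScreenFixtureSpec(n=60, seed=11))
        cfg = ScreenConfig.from_schema(fixture.schema)
        c = run_screen(fixture.table, fixture.toxic, cfg).stage_counts
        assert c["n_input"] >= c["n_gate_pass"] >= c["n_score_pass"] >= c["n_nontoxic"]

    def test_missing_toxicity_rejected(self, schema, config):
        table = make_table(schema, [[0.9] * 10])
        with pytest.raises(ValidationError, match="toxicity"):
            run_screen(table, None, config)

    def test_toxicity_filter_off(self, schema):
        cfg = ScreenConfig.from_schema(schema, apply_toxicity_filter=False, score_threshold=5)
        table = make_table(schema, [[0.9] * 10])
        result = run_screen(table, None, cfg)
        assert result.hits == ["c0"]


@pytest.fixture(scope="module")
def trained(schema3, vocabulary):
    """Tiny models for each attribute of the 3-attribute schema."""
    from dualscreen.balance import LabeledMatrix
    from dualscreen.descriptors import featurize_table
    from dualscreen.models import GraphNetConfig, TabularNetConfig, train_graph, train_tabular
    from dualscreen.molgraph import batch_featurize
    from tests.conftest import make_dataset

    smis = list(vocabulary[::11])[:60]
    ds = make_dataset(schema3, [(f"c{i}", s, (None,) * 3) for i, s in enumerate(smis)])
    desc = featurize_table(ds)
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    lm = LabeledMatrix(desc.to_numpy(), y, ds.compound_ids)
    tab_cfg = TabularNetConfig(seed=0, hidden_sizes=(8,), max_epochs=3, val_frac=0.3)
    graphs = batch_featurize(ds)
    models = {
        "bbb": train_tabular(lm, tab_cfg),
        "act_t": train_tabular(lm, tab_cfg),
        "act_g": train_graph(graphs, y, GraphNetConfig(seed=0, hidden_dim=4, max_epochs=3, val_frac=0.3)),
    }
    for attr_id, model in models.items():
        model.attribute_id = attr_id
    return ds, models


class TestPredictAttributes:
    def test_table_shape_and_order(self, trained):
        ds, models = trained
        table = predict_attributes(models, ds)
        assert table.shape == (len(ds), 3)
        assert list(table.columns) == ["bbb", "act_t", "act_g"]
        assert list(table.index) == ds.compound_ids
        assert ((table.to_numpy() > 0) & (table.to_numpy() < 1)).all()

    def test_deterministic(self, trained):
        ds, models = trained
        pd.testing.assert_frame_equal(predict_attributes(models, ds), predict_attributes(models, ds))

    def test_missing_model_rejected(self, trained):
        ds, models = trained
        with pytest.raises(ValidationError, match="act_g"):
            predict_attributes({k: v for k, v in models.items() if k != "act_g"}, ds)

    def test_path_mismatch_rejected(self, trained):
        ds, models = trained
        swapped = dict(models)
        swapped["act_g"] = models["act_t"]  # tabular model on a graph attribute
        with pytest.raises(ValidationError, match="routes"):
            predict_attributes(swapped, ds)

    def test_featurization_failure_names_compound(self, trained, schema3):
        from tests.conftest import make_dataset

        _, models = trained
        bad = make_dataset(schema3, [("fine", "CCO", (None,) * 3), ("broken", "C1CC", (None,) * 3)])
        with pytest.raises(ValidationError, match="broken"):
            predict_attributes(models, bad)


class TestApplicabilityDomain:
    def test_training_row_is_in_domain(self, rng):
        train = rng.normal(size=(30, 12))
        result = applicability_domain(train, train[:3], k=1)
        np.testing.assert_allclose(result["coverage"], 0.0, atol=1e-12)
        assert result["in_domain"].all()

    def test_distant_query_out_of_domain(self, rng):
        train = rng.normal(size=(30, 12))
        far = np.full((1, 12), 100.0)
        result = applicability_domain(train, far, k=3)
        assert not result["in_domain"].any()

    def test_cutoff_matches_brute_force_loo(self, rng):
        train = rng.normal(size=(20, 12))
        k = 4
        mean = train.mean(axis=0)
        sd = train.std(axis=0)
        z = (train - mean) / sd
        loo = []
        for i in range(20):
            d = np.linalg.norm(z - z[i], axis=1)
            d[i] = np.inf
            loo.append(np.sort(d)[:k].mean())
        expected = np.percentile(loo, 95)
        result = applicability_domain(train, train[:1], k=k)
        assert result["cutoff"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_k_bounds(self, rng):
        train = rng.normal(size=(10, 12))
        with pytest.raises(ValueError):
            applicability_domain(train, train, k=10)


class TestEmbedMap:
    def test_perplexity_calibration_postcondition(self, rng):
        x = np.vstack([rng.normal(0, 1, (70, 12)), rng.normal(8, 1, (70, 12))])
        p, achieved = perplexity_calibration(x, 30.0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.abs(achieved - 30.0).max() <= 1e-3
        assert np.diagonal(p).max() == 0.0

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        x = np.vstack([rng.normal(0, 1, (60, 12)), rng.normal(8, 1, (60, 12))])
        emb = embed_map(x, perplexity=30, iterations=500, seed=0)
        assert emb.shape == (120, 2)
        assert silhouette_score(emb, [0] * 60 + [1] * 60) > 0.5

    def test_duplicated_points_land_together(self, rng):
        base = rng.normal(size=(100, 5))
        x = np.vstack([base, base])
        emb = embed_map(x, perplexity=30, iterations=1000, seed=1)
        diameter = np.linalg.norm(emb.max(axis=0) - emb.min(axis=0))
        pair_dist = np.linalg.norm(emb[:100] - emb[100:], axis=1)
        assert (pair_dist < 0.01 * diameter).mean() > 0.9

    def test_deterministic(self, rng):
        x = rng.normal(size=(40, 6))
        e1 = embed_map(x, perplexity=10, iterations=100, seed=5)
        e2 = embed_map(x, perplexity=10, iterations=100, seed=5)
        np.testing.assert_array_equal(e1, e2)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 5"):
            embed_map(np.zeros((4, 3)))

    def test_small_n_warns(self, rng):
        with pytest.warns(UserWarning, match="perplexity"):
            embed_map(rng.normal(size=(20, 3)), perplexity=30, iterations=50, seed=0)
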