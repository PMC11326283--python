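import math

import numpy as np
import pytest

from modpep.mlm import ModelConfig, RoPEMaskedLM
from modpep.permeability import (
    ClusterPlan,
    FinetuneConfig,
    PermeabilityRecord,
    SchemaError,
    aggregate_scores,
    embed_records,
    ensemble_predict,
    filter_records,
    finetune_regression,
    make_locv_schedule,
    read_permeability_table,
    reduce_and_cluster,
    score,
    write_permeability_table,
)


def rec(id, smiles="NCC(=O)O", assay="PAMPA", logp=-6.0):
    return PermeabilityRecord(id=id, smiles=smiles, assay=assay, logp_exp=logp)


class TestTableIO:
    def test_three_row_table(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "id,SMILES,assay,logP_exp\n"
            "a,NCC(=O)O,PAMPA,-5.0\n"
            "b,CC(N)C(=O)O,Caco2,-6.0\n"
            "c,NCC(=O)NCC(=O)O,PAMPA,-7.0\n"
        )
        result = read_permeability_table(path)
        assert len(result.records) == 3
        assert not result.rejected

    def test_bad_smiles_rejected_with_line(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,SMILES,assay,logP_exp\na,NotASmiles((,PAMPA,-5.0\n")
        result = read_permeability_table(path)
        assert result.records == []
        assert result.rejected == [(2, "unparsable SMILES")]

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("id,SMILES,logP_exp\na,NCC(=O)O,-5.0\n")
        with pytest.raises(SchemaError):
            read_permeability_table(path)

    def test_round_trip(self, tmp_path):
        records = [rec("a", logp=-5.5), rec("b", assay="Caco2", logp=-7.25)]
        path = tmp_path / "t.csv"
        write_permeability_table(records, path)
        assert read_permeability_table(path).records == records


class TestFilter:
    def test_keeps_only_detectable_pampa(self):
        records = [
            rec("a", logp=-5.0),
            rec("b", assay="Caco2", logp=-5.0),
            rec("c", logp=-10.0),
        ]
        kept = filter_records(records)
        assert [r.id for r in kept] == ["a"]

    def test_identity_on_clean_input(self):
        records = [rec("a"), rec("b", logp=-4.0)]
        assert filter_records(records) == records

    def test_empty(self):
        assert filter_records([]) == []


class TestEmbedding:
    def test_shape_and_duplicate_rows(self, tiny_model, vocab):
        records = [rec("a"), rec("b", smiles="CC(N)C(=O)O"), rec("c")]
        X = embed_records(records, tiny_model, vocab)
        assert X.shape == (3, tiny_model.config.hidden)
        assert np.array_equal(X[0], X[2])  # identical SMILES embed identically
        assert not np.array_equal(X[0], X[1])


class TestClustering:
    @staticmethod
    def blobs(seed=0, n=60, d=8, centers=((0,) * 8, (8,) * 8, (-8, 8) * 4)):
        rng = np.random.default_rng(seed)
        X = np.concatenate(
            [rng.normal(c, 1.0, size=(n, d)) for c in np.array(centers, dtype=float)]
        )
        return X

    def test_three_blobs_recovered(self):
        plan = reduce_and_cluster(self.blobs(), k_candidates=(2, 3, 4, 5, 6), seed=0)
        assert plan.k == 3
        assert plan.quality[3]["silhouette"] > 0.5
        counts = np.bincount(plan.labels)
        assert sorted(counts.tolist()) == [60, 60, 60]

    def test_full_variance_keeps_all_components(self):
        X = self.blobs()
        plan = reduce_and_cluster(X, variance_target=1.0, k_candidates=(3,), seed=0)
        assert plan.pca_components == min(X.shape)

    def test_duplicated_rows_same_partition(self):
        X = self.blobs()
        plan = reduce_and_cluster(X, k_candidates=(3,), seed=0)
        doubled = reduce_and_cluster(np.concatenate([X, X]), k_candidates=(3,), seed=0)
        base = plan.labels
        twice = doubled.labels[: len(X)]
        # same partition up to label permutation
        mapping = {}
        for a, b in zip(base, twice):
            mapping.setdefault(a, b)
            assert mapping[a] == b
        assert np.array_equal(twice, doubled.labels[len(X):])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            reduce_and_cluster(np.ones((30, 4)), k_candidates=(2,), seed=0)


def make_plan(labels, k):
    return ClusterPlan(
        labels=np.asarray(labels), k=k, pca_components=2, explained_variance=0.99, quality={}
    )


class TestSchedule:
    def test_six_clusters_cluster_granular_folds(self):
        labels = np.repeat(np.arange(6), 30)
        schedule = make_locv_schedule(make_plan(labels, 6), folds=5, seed=0)
        assert len(schedule) == 6
        assert sorted(it.test_cluster for it in schedule) == list(range(6))
        for it in schedule:
            assert len(it.folds) == 5
            # each validation fold is exactly one remaining cluster
            for train_idx, val_idx in it.folds:
                val_clusters = set(labels[val_idx])
                assert len(val_clusters) == 1
                assert it.test_cluster not in val_clusters
                assert not (set(train_idx) | set(val_idx)) & set(it.test_indices)

    def test_two_clusters_record_granular_fallback(self):
        labels = np.array([0] * 20 + [1] * 25)
        schedule = make_locv_schedule(make_plan(labels, 2), folds=5, seed=0)
        assert len(schedule) == 2
        for it in schedule:
            covered = np.sort(np.concatenate([v for _, v in it.folds]))
            rest = np.sort(np.nonzero(labels != it.test_cluster)[0])
            assert np.array_equal(covered, rest)

    def test_test_sets_partition_all_records(self):
        labels = np.array([0, 1, 2, 0, 1, 2, 1, 2, 0, 1] * 4)
        schedule = make_locv_schedule(make_plan(labels, 3), folds=3, seed=0)
        seen = np.concatenate([it.test_indices for it in schedule])
        assert sorted(seen.tolist()) == list(range(len(labels)))

    def test_too_many_folds_rejected(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            make_locv_schedule(make_plan(labels, 2), folds=5, seed=0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            make_locv_schedule(make_plan(np.zeros(10, dtype=int), 1), folds=2)


class TestScoring:
    def test_perfect_ordering(self):
        records = [rec("a", logp=-4.0), rec("b", logp=-7.0), rec("c", logp=-5.0)]
        result = score([-4.0, -7.0, -5.0], records)
        assert result.roc_auc == 1.0
        assert result.rmse == 0.0

    def test_constant_predictions(self):
        records = [rec(str(i), logp=v) for i, v in enumerate([-4.0, -6.0, -5.0, -7.0])]
        result = score([-5.5] * 4, records)
        assert result.roc_auc == 0.5
        truth = np.array([-4.0, -6.0, -5.0, -7.0])
        assert math.isclose(result.rmse, np.sqrt(np.mean((truth + 5.5) ** 2)))

    def test_hand_rmse(self):
        records = [rec("a", logp=-4.9), rec("b", logp=-6.1)]
        result = score([-5.0, -6.0], records)
        assert math.isclose(result.rmse, 0.1, rel_tol=1e-9)

    def test_single_class_marks_aucs_undefined(self):
        records = [rec("a", logp=-7.0), rec("b", logp=-8.0)]
        result = score([-7.0, -8.0], records)
        assert math.isnan(result.roc_auc) and math.isnan(result.pr_auc)
        assert result.rmse == 0.0

    def test_cutoff_changes_labels_not_rmse(self):
        records = [rec(str(i), logp=v) for i, v in enumerate([-4.0, -5.2, -6.0, -7.0])]
        preds = [-4.5, -5.0, -6.5, -6.8]
        loose = score(preds, records, cutoff=-5.5)
        strict = score(preds, records, cutoff=-6.5)
        assert loose.rmse == strict.rmse
        assert loose.n_permeable != strict.n_permeable

    def test_aggregate_excludes_undefined(self):
        defined = score([-5.0, -6.0], [rec("a", logp=-5.0), rec("b", logp=-6.0)], cluster=0)
        undefined = score([-7.0, -8.0], [rec("c", logp=-7.0), rec("d", logp=-8.0)], cluster=1)
        report = aggregate_scores([defined, undefined])
        assert len(report.per_cluster) == 2
        assert not math.isnan(report.aggregate["roc_auc"]["mean"])
        assert report.aggregate["rmse"]["mean"] == pytest.approx(
            (defined.rmse + undefined.rmse) / 2
        )


class _StubModel:
    def __init__(self, value, config):
        self.value = value
        self.config = config

    def predict(self, ids, flags, batch_size=64):
        return np.full(len(ids), self.value)


class TestEnsemble:
    def test_mean_of_outputs(self, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=64)
        models = [_StubModel(v, config) for v in (-5.0, -6.0, -7.0, -5.0, -7.0)]
        preds = ensemble_predict(models, vocab, [rec("a"), rec("b")])
        assert np.allclose(preds, -6.0)

    def test_identical_models_equal_single(self, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=64)
        models = [_StubModel(-5.5, config)] * 5
        assert np.allclose(ensemble_predict(models, vocab, [rec("a")]), -5.5)

    def test_empty_ensemble_rejected(self, vocab):
        with pytest.raises(ValueError):
            ensemble_predict([], vocab, [rec("a")])


@pytest.fixture(scope="module")
def signal_records():
    """Peptides whose target depends strongly on visible structural features."""
    from modpep.fixtures import make_toy_permeability_dataset

    fixture = make_toy_permeability_dataset(120, noise_sd=0.05, seed=9)
    return fixture.clean_records


class TestFinetune:
    def test_beats_constant_predictor(self, tiny_model, vocab, signal_records):
        train, val = signal_records[:90], signal_records[90:]
        model = finetune_regression(
            tiny_model, vocab, train, val,
            FinetuneConfig(lr=1e-3, dropout=0.0, weight_decay=0.0, batch_size=16,
                           max_steps=150, seed=0),
        )
        from modpep.permeability import _encode_records

        ids, flags = _encode_records(val, vocab, tiny_model.config.context)
        preds = model.predict(ids, flags)
        truth = np.array([r.logp_exp for r in val])
        mse = np.mean((preds - truth) ** 2)
        baseline = np.mean((np.mean([r.logp_exp for r in train]) - truth) ** 2)
        assert mse < baseline

    def test_zero_steps_returns_initial_head(self, tiny_model, vocab, signal_records):
        model = finetune_regression(
            tiny_model, vocab, signal_records[:20], signal_records[20:30],
            FinetuneConfig(max_steps=0, seed=0),
        )
        assert model.encoder.state().keys() == tiny_model.encoder.state().keys()
        for name, value in model.encoder.state().items():
            assert np.array_equal(value, tiny_model.encoder.state()[name])

    def test_deterministic(self, tiny_model, vocab, signal_records):
        cfg = FinetuneConfig(lr=1e-3, dropout=0.1, batch_size=16, max_steps=20, seed=4)
        a = finetune_regression(tiny_model, vocab, signal_records[:40], signal_records[40:50], cfg)
        b = finetune_regression(tiny_model, vocab, signal_records[:40], signal_records[40:50], cfg)
        from modpep.permeability import _encode_records

        ids, flags = _encode_records(signal_records[50:60], vocab, tiny_model.config.context)
        assert np.array_equal(a.predict(ids, flags), b.predict(ids, flags))

    def test_empty_validation_rejected(self, tiny_model, vocab, signal_records):
        with pytest.raises(ValueError):
            finetune_regression(tiny_model, vocab, signal_records[:10], [], FinetuneConfig())
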