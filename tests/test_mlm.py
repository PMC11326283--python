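import math

import numpy as np
import pytest

from modpep.mlm import (
    IGNORE_INDEX,
    MaskingConfig,
    ModelConfig,
    RoPEMaskedLM,
    TrainConfig,
    apply_masking,
    encode_corpus,
    evaluate_mlm,
    load_checkpoint,
    save_checkpoint,
    train_mlm,
)
from modpep.nn import autodiff as ad


@pytest.fixture(scope="module")
def encoded(corpus_path, vocab):
    return encode_corpus(corpus_path, vocab, 192)


class TestMasking:
    def test_selection_and_corruption_rates(self, encoded, vocab):
        ids, flags = encoded
        reps = max(1, 100_000 // max(((flags == 1) & (ids >= 5)).sum(), 1) + 1)
        ids = np.tile(ids, (reps, 1))
        flags = np.tile(flags, (reps, 1))
        rng = np.random.default_rng(0)
        batch = apply_masking((ids, flags), len(vocab), MaskingConfig(), rng)
        eligible = (flags == 1) & (ids >= 5)
        assert eligible.sum() >= 100_000
        selected = batch.labels != IGNORE_INDEX
        rate = selected.sum() / eligible.sum()
        assert abs(rate - 0.15) < 3 * math.sqrt(0.15 * 0.85 / eligible.sum())
        n_sel = selected.sum()
        masked = ((batch.input_ids == 4) & selected).sum() / n_sel
        kept = ((batch.input_ids == ids) & selected).sum() / n_sel
        randomized = 1.0 - masked - kept
        assert abs(masked - 0.80) < 3 * math.sqrt(0.8 * 0.2 / n_sel)
        assert abs(kept - 0.10) < 3 * math.sqrt(0.1 * 0.9 / n_sel)
        assert abs(randomized - 0.10) < 3 * math.sqrt(0.1 * 0.9 / n_sel)

    def test_specials_and_padding_untouched(self, encoded, vocab):
        ids, flags = encoded
        rng = np.random.default_rng(1)
        batch = apply_masking((ids, flags), len(vocab), MaskingConfig(), rng)
        protected = ~((flags == 1) & (ids >= 5))
        assert (batch.input_ids[protected] == ids[protected]).all()
        assert (batch.labels[protected] == IGNORE_INDEX).all()

    def test_zero_selection_probability(self, encoded, vocab):
        ids, flags = encoded
        rng = np.random.default_rng(2)
        batch = apply_masking((ids, flags), len(vocab), MaskingConfig(select_prob=0.0), rng)
        assert (batch.input_ids == ids).all()
        assert (batch.labels == IGNORE_INDEX).all()

    def test_labels_record_originals(self, encoded, vocab):
        ids, flags = encoded
        rng = np.random.default_rng(3)
        batch = apply_masking((ids, flags), len(vocab), MaskingConfig(), rng)
        selected = batch.labels != IGNORE_INDEX
        assert (batch.labels[selected] == ids[selected]).all()

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            MaskingConfig(mask_share=0.7, random_share=0.1, keep_share=0.1)


class TestForward:
    def test_softmax_normalization(self, vocab, encoded):
        ids, flags = encoded
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=192)
        model = RoPEMaskedLM(config, seed=0)
        probs = model.predict_proba(ids[:3], flags[:3])
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_token_input(self, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=8)
        model = RoPEMaskedLM(config, seed=0)
        probs = model.predict_proba(np.array([[6]]), np.array([[1]]))
        assert probs.shape == (1, 1, len(vocab))

    def test_over_length_rejected(self, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=4)
        model = RoPEMaskedLM(config, seed=0)
        with pytest.raises(ValueError):
            model(np.zeros((1, 8), dtype=int), np.ones((1, 8), dtype=int))

    def test_rotary_positions_are_relative(self, vocab, encoded):
        """Prepending masked-out padding shifts absolute positions but must not
        change content outputs: attention depends only on relative offsets."""
        ids, flags = encoded
        config = ModelConfig(vocab_size=len(vocab), layers=2, heads=2, hidden=16,
                             intermediate=32, context=192)
        model = RoPEMaskedLM(config, seed=1)
        x, f = ids[:1, :40], flags[:1, :40]
        shift = 9
        x2 = np.concatenate([np.zeros((1, shift), dtype=int), x], axis=1)
        f2 = np.concatenate([np.zeros((1, shift), dtype=int), f], axis=1)
        with ad.no_grad():
            direct = model(x, f).data
            shifted = model(x2, f2).data
        assert np.abs(direct[0] - shifted[0, shift:]).max() < 1e-4


def test_full_size_model_parameter_count():
    config = ModelConfig(vocab_size=586)
    model = RoPEMaskedLM(config, seed=0)
    assert 42_000_000 <= model.num_parameters() <= 46_000_000


class TestTraining:
    def test_loss_decreases(self, corpus_path, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=32,
                             intermediate=64, context=160)
        model, reports = train_mlm(
            corpus_path, vocab, config,
            TrainConfig(steps=40, batch_size=16, lr=1e-3, seed=0),
        )
        assert reports[-1].loss < reports[0].loss

    def test_zero_lr_leaves_loss_unchanged(self, corpus_path, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=160)
        _, reports = train_mlm(
            corpus_path, vocab, config,
            TrainConfig(steps=10, batch_size=16, lr=0.0, eval_interval=10, seed=0),
        )
        assert math.isclose(reports[0].loss, reports[-1].loss, rel_tol=1e-6)

    def test_same_seed_same_trajectory(self, corpus_path, vocab):
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=160)
        cfg = TrainConfig(steps=12, batch_size=16, lr=1e-3, eval_interval=4, seed=5)
        _, first = train_mlm(corpus_path, vocab, config, cfg)
        _, second = train_mlm(corpus_path, vocab, config, cfg)
        assert [r.loss for r in first] == [r.loss for r in second]

    def test_corpus_smaller_than_batch_rejected(self, tmp_path, vocab):
        path = tmp_path / "tiny.txt"
        path.write_text("CC\nCCC\n")
        config = ModelConfig(vocab_size=len(vocab), layers=1, heads=2, hidden=16,
                             intermediate=32, context=16)
        with pytest.raises(ValueError):
            train_mlm(path, vocab, config, TrainConfig(steps=5, batch_size=64))


class TestEvaluation:
    def test_macro_accuracy_upper_bound_on_perfect_data(self, vocab, encoded, tiny_model):
        ids, flags = encoded
        rng = np.random.default_rng(0)
        report = evaluate_mlm(tiny_model, (ids[:50], flags[:50]), MaskingConfig(), rng)
        assert 0.0 <= report.macro_accuracy <= 1.0
        assert report.loss >= 0.0
        assert math.isclose(report.loss_sum, report.loss * report.n_positions, rel_tol=1e-9)

    def test_empty_evaluation_set_rejected(self, vocab, tiny_model):
        with pytest.raises(ValueError):
            evaluate_mlm(
                tiny_model,
                (np.zeros((0, 4), dtype=int), np.zeros((0, 4), dtype=int)),
                MaskingConfig(),
                np.random.default_rng(0),
            )


class TestCheckpoint:
    def test_round_trip(self, tiny_model, vocab, encoded, tmp_path):
        ids, flags = encoded
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, vocab, path)
        restored = load_checkpoint(path, vocab)
        with ad.no_grad():
            a = tiny_model(ids[:2, :30], flags[:2, :30]).data
            b = restored(ids[:2, :30], flags[:2, :30]).data
        assert np.array_equal(a, b)

    def test_vocabulary_mismatch_rejected(self, tiny_model, vocab, tmp_path):
        from modpep.tokenizer import Vocabulary

        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, vocab, path)
        other = Vocabulary(list(vocab.tokens) + ["ZZ"])
        with pytest.raises(ValueError):
            load_checkpoint(path, other)
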