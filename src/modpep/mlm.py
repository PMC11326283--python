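"""Masked-language-model pretraining of a rotary-embedding BERT-style encoder.

The encoder follows the BERT recipe adapted for SMILES: token embeddings
(no absolute-position table — positions enter via rotary query/key rotation),
post-LN transformer blocks, and a language-modeling head producing a softmax
distribution over the vocabulary at every position. Pretraining corrupts 15%
of eligible positions with the classic 80/10/10 mask/random/keep split and
optimizes cross-entropy at the corrupted positions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .tokenizer import EncodedSequence, Vocabulary, encode

__all__ = [
    "ModelConfig",
    "MaskingConfig",
    "MaskedBatch",
    "TrainConfig",
    "TrainReport",
    "Encoder",
    "RoPEMaskedLM",
    "RegressionModel",
    "apply_masking",
    "sum_pool",
    "mean_pool",
    "train_mlm",
    "evaluate_mlm",
    "encode_corpus",
    "save_checkpoint",
    "load_checkpoint",
    "vocab_hash",
]

IGNORE_INDEX = -100
N_SPECIAL = 5


@dataclass(frozen=True)
class ModelConfig:
    """Encoder architecture. Defaults are the full-size configuration
    (6 layers, 12 heads, 768 hidden, 3072 intermediate, 768 context)."""

    vocab_size: int
    layers: int = 6
    heads: int = 12
    hidden: int = 768
    intermediate: int = 3072
    context: int = 768

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden must be divisible by heads")
        if self.context < 3:
            raise ValueError("context must be at least 3")
        if self.vocab_size <= N_SPECIAL:
            raise ValueError("vocabulary must contain non-special tokens")


@dataclass(frozen=True)
class MaskingConfig:
    """BERT-style corruption: select 15% of eligible positions, then
    mask 80%, randomize 10%, keep 10% of the selected ones."""

    select_prob: float = 0.15
    mask_share: float = 0.80
    random_share: float = 0.10
    keep_share: float = 0.10

    def __post_init__(self):
        total = self.mask_share + self.random_share + self.keep_share
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mask/random/keep shares must sum to 1")
        if not 0.0 <= self.select_prob <= 1.0:
            raise ValueError("select_prob must lie in [0, 1]")


@dataclass
class MaskedBatch:
    input_ids: np.ndarray  # corrupted ids (B, T)
    labels: np.ndarray  # original ids at selected positions, IGNORE_INDEX elsewhere
    attention_flags: np.ndarray


def apply_masking(
    batch: list[EncodedSequence] | tuple[np.ndarray, np.ndarray],
    vocab_size: int,
    cfg: MaskingConfig,
    rng: np.random.Generator,
) -> MaskedBatch:
    """Corrupt a batch for masked prediction. Special and padding positions
    are never selected."""
    if isinstance(batch, (list, tuple)) and batch and isinstance(batch[0], EncodedSequence):
        ids = np.stack([s.ids for s in batch])
        flags = np.stack([s.attention_flags for s in batch])
    else:
        ids, flags = batch
        ids = np.asarray(ids)
        flags = np.asarray(flags)

    eligible = (flags == 1) & (ids >= N_SPECIAL)
    selected = (rng.random(ids.shape) < cfg.select_prob) & eligible

    u = rng.random(ids.shape)
    random_ids = rng.integers(N_SPECIAL, vocab_size, size=ids.shape)

    input_ids = ids.copy()
    mask_positions = selected & (u < cfg.mask_share)
    random_positions = selected & (u >= cfg.mask_share) & (u < cfg.mask_share + cfg.random_share)
    input_ids[mask_positions] = 4  # [MASK]
    input_ids[random_positions] = random_ids[random_positions]

    labels = np.where(selected, ids, IGNORE_INDEX)
    return MaskedBatch(input_ids, labels, flags)


class Encoder(nn.Module):
    """Token embedding + rotary post-LN transformer stack."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.embedding = nn.Embedding(config.vocab_size, config.hidden, rng)
        self.blocks = [
            nn.EncoderBlock(config.hidden, config.heads, config.intermediate, rng)
            for _ in range(config.layers)
        ]
        self.rope = nn.RotaryCache(config.hidden // config.heads, config.context)

    def __call__(self, ids, flags, p_drop: float = 0.0, drop_rng=None) -> Tensor:
        ids = np.asarray(ids)
        flags = np.asarray(flags)
        if ids.ndim != 2:
            raise ValueError("ids must be (batch, length)")
        if ids.shape[1] > self.config.context:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds context {self.config.context}"
            )
        if ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of range for the model vocabulary")
        attn_bias = ((1 - flags) * -1e9).astype(np.float32)[:, None, None, :]
        rope = self.rope.tables(ids.shape[1])
        x = self.embedding(ids)
        for block in self.blocks:
            x = block(x, attn_bias, rope, p_drop=p_drop, rng=drop_rng)
        return x


class MLMHead(nn.Module):
    """BERT LM head: dense + GELU + LN + decoder to vocabulary logits."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.dense = nn.Linear(config.hidden, config.hidden, rng)
        self.norm = nn.LayerNorm(config.hidden)
        self.decoder = nn.Linear(config.hidden, config.vocab_size, rng)

    def __call__(self, hidden: Tensor) -> Tensor:
        return self.decoder(self.norm(self.dense(hidden).gelu()))


class RoPEMaskedLM(nn.Module):
    """Encoder plus language-modeling head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.head = MLMHead(config, rng)

    def __call__(self, ids, flags, p_drop: float = 0.0, drop_rng=None) -> Tensor:
        return self.head(self.encoder(ids, flags, p_drop=p_drop, drop_rng=drop_rng))

    def predict_proba(self, ids, flags) -> np.ndarray:
        """Per-position softmax distribution over the vocabulary."""
        with ad.no_grad():
            logits = self(ids, flags)
            return ad.softmax(logits, axis=-1).data


class RegressionModel(nn.Module):
    """Encoder with the LM head replaced by a single hidden-width dense layer
    producing one scalar from pooled content positions.

    The default pooling for regression is a sum over content positions: a
    linear head on summed token states is a token-additive scorer, so counted
    structural motifs (methylated amides, PEG units, ring closures, chain
    length itself) stay linearly accessible. Mean pooling, which normalizes
    counts away, is available for comparison.
    """

    def __init__(
        self,
        config: ModelConfig,
        seed: int = 0,
        encoder: Encoder | None = None,
        pooling: str = "sum",
    ):
        if pooling not in {"sum", "mean"}:
            raise ValueError(f"pooling must be 'sum' or 'mean', got {pooling!r}")
        rng = np.random.default_rng(seed)
        self.config = config
        self.pooling = pooling
        self.encoder = encoder if encoder is not None else Encoder(config, rng)
        self.head = nn.Linear(config.hidden, 1, rng)

    def __call__(self, ids, flags, p_drop: float = 0.0, drop_rng=None) -> Tensor:
        hidden = self.encoder(ids, flags, p_drop=p_drop, drop_rng=drop_rng)
        if self.pooling == "sum":
            pooled = sum_pool(hidden, np.asarray(ids), np.asarray(flags))
        else:
            pooled = mean_pool(hidden, np.asarray(ids), np.asarray(flags))
        if p_drop > 0.0:
            pooled = ad.dropout(pooled, p_drop, drop_rng)
        return self.head(pooled).reshape(-1)

    def predict(self, ids, flags, batch_size: int = 64) -> np.ndarray:
        ids = np.asarray(ids)
        flags = np.asarray(flags)
        out = []
        with ad.no_grad():
            for start in range(0, len(ids), batch_size):
                sl = slice(start, start + batch_size)
                trimmed_ids, trimmed_flags = _trim(ids[sl], flags[sl])
                out.append(self(trimmed_ids, trimmed_flags).data)
        return np.concatenate(out) if out else np.zeros(0)


def sum_pool(hidden: Tensor, ids: np.ndarray, flags: np.ndarray) -> Tensor:
    """Sum final-layer states over non-special, non-padding positions."""
    mask = ((flags == 1) & (ids >= N_SPECIAL)).astype(np.float32)
    return (hidden * Tensor(mask[:, :, None])).sum(axis=1)


def mean_pool(hidden: Tensor, ids: np.ndarray, flags: np.ndarray) -> Tensor:
    """Average final-layer states over non-special, non-padding positions."""
    mask = ((flags == 1) & (ids >= N_SPECIAL)).astype(np.float32)
    counts = np.maximum(mask.sum(axis=1, keepdims=True), np.float32(1.0))
    weighted = hidden * Tensor(mask[:, :, None])
    return weighted.sum(axis=1) * Tensor((1.0 / counts).astype(np.float32))


# -- training ----------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Pretraining hyperparameters (paper-scale defaults: batch 64, lr 5e-5)."""

    steps: int = 1000
    batch_size: int = 64
    lr: float = 5e-5
    warmup_steps: int = 0
    weight_decay: float = 0.0
    validation_fraction: float = 0.1
    eval_interval: int | None = None  # default: every 20% of the step budget
    seed: int = 0


@dataclass
class TrainReport:
    """Held-out metrics at one evaluation point."""

    step: int
    loss: float  # mean cross-entropy per masked position
    loss_sum: float  # summed cross-entropy over masked positions
    macro_accuracy: float
    n_positions: int

    def to_dict(self) -> dict:
        return asdict(self)


def encode_corpus(corpus, vocab: Vocabulary, context_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Encode a one-SMILES-per-line file into stacked id/flag matrices."""
    ids, flags = [], []
    with open(corpus, encoding="utf-8") as fh:
        for line in fh:
            smiles = line.strip()
            if not smiles:
                continue
            seq = encode(smiles, vocab, context_len=context_len)
            ids.append(seq.ids)
            flags.append(seq.attention_flags)
    if not ids:
        raise ValueError("corpus contains no sequences")
    return np.stack(ids), np.stack(flags)


def _trim(ids: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop all-padding tail columns of a batch (padding never affects content)."""
    max_len = max(int(flags.sum(axis=1).max()), 1)
    return ids[:, :max_len], flags[:, :max_len]


def _mlm_loss(model, batch: MaskedBatch):
    """Cross-entropy over selected positions; returns (loss tensor, flat labels, logits)."""
    logits = model(batch.input_ids, batch.attention_flags)
    b, t, v = logits.shape
    flat_logits = logits.reshape(b * t, v)
    flat_labels = batch.labels.reshape(-1)
    keep = np.nonzero(flat_labels != IGNORE_INDEX)[0]
    if keep.size == 0:
        return None, None, None
    selected = ad.index_select(flat_logits, keep)
    loss = ad.cross_entropy(selected, flat_labels[keep], reduction="mean")
    return loss, flat_labels[keep], selected


def evaluate_mlm(
    model: RoPEMaskedLM,
    data: tuple[np.ndarray, np.ndarray],
    masking: MaskingConfig,
    rng: np.random.Generator,
    step: int = 0,
    batch_size: int = 64,
) -> TrainReport:
    """Masked-prediction metrics on held-out sequences.

    Reports mean and summed cross-entropy over masked positions and
    macro-averaged accuracy (per-token-class accuracy averaged unweighted
    over the classes observed in the evaluation set).
    """
    ids, flags = data
    if len(ids) == 0:
        raise ValueError("empty evaluation set")
    total_nll = 0.0
    n_positions = 0
    correct: dict[int, int] = {}
    seen: dict[int, int] = {}
    with ad.no_grad():
        for start in range(0, len(ids), batch_size):
            sl = slice(start, start + batch_size)
            batch_ids, batch_flags = _trim(ids[sl], flags[sl])
            batch = apply_masking((batch_ids, batch_flags), model.config.vocab_size, masking, rng)
            loss, labels, logits = _mlm_loss(model, batch)
            if loss is None:
                continue
            total_nll += float(loss.data) * len(labels)
            n_positions += len(labels)
            preds = logits.data.argmax(axis=-1)
            for label, pred in zip(labels.tolist(), preds.tolist()):
                seen[label] = seen.get(label, 0) + 1
                if label == pred:
                    correct[label] = correct.get(label, 0) + 1
    if n_positions == 0:
        raise ValueError("no eligible positions in the evaluation set")
    macro = float(np.mean([correct.get(c, 0) / n for c, n in seen.items()]))
    return TrainReport(
        step=step,
        loss=total_nll / n_positions,
        loss_sum=total_nll,
        macro_accuracy=macro,
        n_positions=n_positions,
    )


def train_mlm(
    corpus,
    vocab: Vocabulary,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    masking: MaskingConfig = MaskingConfig(),
) -> tuple[RoPEMaskedLM, list[TrainReport]]:
    """Pretrain a masked LM on a SMILES corpus; returns the model and the
    held-out evaluation trajectory (including the pre-training baseline)."""
    ids, flags = encode_corpus(corpus, vocab, model_config.context)
    rng = np.random.default_rng(train_config.seed)
    mask_rng = np.random.default_rng(train_config.seed + 1)

    n_val = max(1, int(round(train_config.validation_fraction * len(ids))))
    if len(ids) - n_val < train_config.batch_size:
        raise ValueError(
            f"corpus provides {len(ids) - n_val} training sequences, "
            f"fewer than one batch of {train_config.batch_size}"
        )
    perm = rng.permutation(len(ids))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    val_data = (ids[val_idx], flags[val_idx])

    model = RoPEMaskedLM(model_config, seed=train_config.seed)
    optimizer = nn.AdamW(
        model.parameters(),
        lr=train_config.lr,
        weight_decay=train_config.weight_decay,
        warmup_steps=train_config.warmup_steps,
    )
    interval = train_config.eval_interval or max(1, train_config.steps // 5)

    def run_eval(step):
        eval_rng = np.random.default_rng(train_config.seed + 2)
        return evaluate_mlm(model, val_data, masking, eval_rng, step=step,
                            batch_size=train_config.batch_size)

    reports = [run_eval(0)]
    order = rng.permutation(train_idx)
    cursor = 0
    for step in range(1, train_config.steps + 1):
        if cursor + train_config.batch_size > len(order):
            order = rng.permutation(train_idx)
            cursor = 0
        take = order[cursor : cursor + train_config.batch_size]
        cursor += train_config.batch_size
        batch_ids, batch_flags = _trim(ids[take], flags[take])
        batch = apply_masking((batch_ids, batch_flags), model_config.vocab_size, masking, mask_rng)
        loss, _, _ = _mlm_loss(model, batch)
        if loss is None:
            continue
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        if step % interval == 0 or step == train_config.steps:
            reports.append(run_eval(step))
    return model, reports


# -- checkpoints -------------------------------------------------------------


def vocab_hash(vocab: Vocabulary) -> str:
    return hashlib.sha256("\n".join(vocab.tokens).encode("utf-8")).hexdigest()


def save_checkpoint(model, vocab: Vocabulary, path, extra: dict | None = None) -> None:
    """Self-describing archive: architecture, vocabulary hash and weights."""
    meta = {
        "kind": type(model).__name__,
        "config": asdict(model.config),
        "vocab_sha256": vocab_hash(vocab),
        "pooling": getattr(model, "pooling", None),
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v for k, v in model.state().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, vocab: Vocabulary):
    """Load a checkpoint; refuses a vocabulary whose hash does not match."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param:"):]: archive[k] for k in archive.files if k.startswith("param:")}
    if meta["vocab_sha256"] != vocab_hash(vocab):
        raise ValueError("checkpoint was trained with a different vocabulary")
    config = ModelConfig(**meta["config"])
    if meta["kind"] == "RoPEMaskedLM":
        model = RoPEMaskedLM(config)
    else:
        model = RegressionModel(config, pooling=meta.get("pooling") or "sum")
    model.load_state(state)
    return model
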