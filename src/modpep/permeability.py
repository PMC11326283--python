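"""Membrane-permeability regression with leave-one-cluster-out evaluation.

Pipeline: read a PAMPA permeability table, clean it (PAMPA-only, drop the
-10 "undetectable" marker rows), embed every peptide with a pretrained
encoder, reduce the embeddings by PCA (99% variance retained) and k-means
them into clusters; then hold out each cluster in turn, train a 5-fold
ensemble of regression models on the remainder, and score the ensemble's
held-out predictions as both a regression (RMSE) and a binary permeability
classification at the log10 cm/s cutoff of -5.5 (ROC-AUC, PR-AUC).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    average_precision_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    roc_auc_score,
    silhouette_score,
)
from sklearn.model_selection import KFold
from rdkit import Chem

from . import nn
from .nn import autodiff as ad
from .mlm import RegressionModel, RoPEMaskedLM, mean_pool, _trim
from .tokenizer import Vocabulary, encode

logger = logging.getLogger(__name__)

__all__ = [
    "PermeabilityRecord",
    "ReadResult",
    "SchemaError",
    "ClusterPlan",
    "FinetuneConfig",
    "ClusterScore",
    "EvalReport",
    "read_permeability_table",
    "write_permeability_table",
    "filter_records",
    "embed_records",
    "reduce_and_cluster",
    "make_locv_schedule",
    "finetune_regression",
    "ensemble_predict",
    "score",
    "aggregate_scores",
    "run_locv",
]

ASSAYS = ("PAMPA", "Caco2", "MDCK", "RRCK")
UNDETECTABLE = -10.0
DEFAULT_CUTOFF = -5.5


@dataclass(frozen=True)
class PermeabilityRecord:
    """One peptide with an assay type and experimental log10 permeability."""

    id: str
    smiles: str
    assay: str
    logp_exp: float


class SchemaError(ValueError):
    """Input table is missing a required column."""


@dataclass
class ReadResult:
    records: list[PermeabilityRecord]
    rejected: list[tuple[int, str]]  # (line number, reason)


DEFAULT_COLUMNS = {"id": "id", "smiles": "SMILES", "assay": "assay", "logp": "logP_exp"}


def read_permeability_table(path, columns: dict[str, str] | None = None) -> ReadResult:
    """Read a delimited permeability table into typed records.

    Rows whose SMILES does not parse or whose permeability is not finite are
    rejected and reported with their line number.
    """
    colmap = dict(DEFAULT_COLUMNS, **(columns or {}))
    frame = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records: list[PermeabilityRecord] = []
    rejected: list[tuple[int, str]] = []
    for row_idx, row in enumerate(frame.itertuples(index=False)):
        line = row_idx + 2  # header is line 1
        smiles = str(getattr(row, colmap["smiles"]))
        logp = getattr(row, colmap["logp"])
        if Chem.MolFromSmiles(smiles) is None:
            rejected.append((line, "unparsable SMILES"))
            continue
        try:
            logp = float(logp)
        except (TypeError, ValueError):
            rejected.append((line, "non-numeric permeability"))
            continue
        if not math.isfinite(logp):
            rejected.append((line, "non-finite permeability"))
            continue
        records.append(
            PermeabilityRecord(
                id=str(getattr(row, colmap["id"])),
                smiles=smiles,
                assay=str(getattr(row, colmap["assay"])),
                logp_exp=logp,
            )
        )
    return ReadResult(records, rejected)


def write_permeability_table(records, path, columns: dict[str, str] | None = None) -> None:
    colmap = dict(DEFAULT_COLUMNS, **(columns or {}))
    frame = pd.DataFrame(
        {
            colmap["id"]: [r.id for r in records],
            colmap["smiles"]: [r.smiles for r in records],
            colmap["assay"]: [r.assay for r in records],
            colmap["logp"]: [r.logp_exp for r in records],
        }
    )
    frame.to_csv(path, index=False)


def filter_records(records) -> list[PermeabilityRecord]:
    """Keep PAMPA measurements, dropping the -10 "undetectable" marker rows."""
    return [
        r for r in records if r.assay == "PAMPA" and r.logp_exp != UNDETECTABLE
    ]


# -- embeddings and clustering ----------------------------------------------


def _encode_records(records, vocab: Vocabulary, context: int):
    ids, flags = [], []
    for record in records:
        seq = encode(record.smiles, vocab, context_len=context)
        ids.append(seq.ids)
        flags.append(seq.attention_flags)
    return np.stack(ids), np.stack(flags)


def embed_records(
    records, model: RoPEMaskedLM | RegressionModel, vocab: Vocabulary, batch_size: int = 64
) -> np.ndarray:
    """One fixed-length embedding per record: mean of final-layer states over
    content (non-special, non-padding) positions."""
    context = model.config.context
    for record in records:
        seq = encode(record.smiles, vocab, context_len=context)
        if seq.true_length == context and len(record.smiles) > context:
            warnings.warn(f"record {record.id}: SMILES truncated to context {context}")
    ids, flags = _encode_records(records, vocab, context)
    out = []
    encoder = model.encoder
    with ad.no_grad():
        for start in range(0, len(ids), batch_size):
            sl = slice(start, start + batch_size)
            batch_ids, batch_flags = _trim(ids[sl], flags[sl])
            hidden = encoder(batch_ids, batch_flags)
            out.append(mean_pool(hidden, batch_ids, batch_flags).data)
    return np.concatenate(out, axis=0)


@dataclass
class ClusterPlan:
    """Cluster labels plus the PCA/k-selection diagnostics behind them."""

    labels: np.ndarray
    k: int
    pca_components: int
    explained_variance: float
    quality: dict[int, dict[str, float]]  # per candidate k: silhouette/DB/CH

    def cluster_indices(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def reduce_and_cluster(
    X: np.ndarray,
    variance_target: float = 0.99,
    k_candidates=(2, 3, 4, 5, 6),
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterPlan:
    """PCA to the minimal subspace retaining ``variance_target`` variance
    (centering only), then k-means over candidate k; k is selected by maximum
    silhouette, with Davies-Bouldin and Calinski-Harabasz reported alongside."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) < max(k_candidates):
        raise ValueError("fewer samples than the largest candidate k")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("embedding matrix has zero variance")

    pca = PCA(svd_solver="full", random_state=seed)
    reduced_full = pca.fit_transform(X)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    n_components = min(n_components, reduced_full.shape[1])
    reduced = reduced_full[:, :n_components]

    quality: dict[int, dict[str, float]] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in sorted(k_candidates):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(reduced)
        if len(np.unique(labels)) < 2:
            continue
        quality[k] = {
            "silhouette": float(silhouette_score(reduced, labels)),
            "davies_bouldin": float(davies_bouldin_score(reduced, labels)),
            "calinski_harabasz": float(calinski_harabasz_score(reduced, labels)),
        }
        labels_by_k[k] = labels
    if not quality:
        raise ValueError("no candidate k produced a valid clustering")
    best_k = max(sorted(quality), key=lambda k: quality[k]["silhouette"])
    return ClusterPlan(
        labels=labels_by_k[best_k],
        k=best_k,
        pca_components=n_components,
        explained_variance=float(cumulative[n_components - 1]),
        quality=quality,
    )


@dataclass
class LocvIteration:
    """One leave-one-cluster-out round: the held-out cluster and the 5
    train/validation folds over the remaining records."""

    test_cluster: int
    test_indices: np.ndarray
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train, validation) record indices


def make_locv_schedule(plan: ClusterPlan, folds: int = 5, seed: int = 0) -> list[LocvIteration]:
    """Each cluster is held out once; the remaining records are split into
    ``folds`` train/validation folds — at cluster granularity when the number
    of remaining clusters equals ``folds``, at record granularity otherwise."""
    if plan.k < 2:
        raise ValueError("leave-one-cluster-out needs at least 2 clusters")
    schedule: list[LocvIteration] = []
    clusters = sorted(np.unique(plan.labels).tolist())
    for test_cluster in clusters:
        test_idx = plan.cluster_indices(test_cluster)
        rest_clusters = [c for c in clusters if c != test_cluster]
        rest_idx = np.nonzero(plan.labels != test_cluster)[0]
        if len(rest_idx) < folds:
            raise ValueError(
                f"cluster {test_cluster}: only {len(rest_idx)} non-test records "
                f"for {folds} folds"
            )
        fold_splits: list[tuple[np.ndarray, np.ndarray]] = []
        if len(rest_clusters) == folds:
            # one-cluster-out validation folds
            for val_cluster in rest_clusters:
                val_idx = plan.cluster_indices(val_cluster)
                train_idx = np.nonzero(
                    (plan.labels != test_cluster) & (plan.labels != val_cluster)
                )[0]
                fold_splits.append((train_idx, val_idx))
        else:
            kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
            for train_pos, val_pos in kf.split(rest_idx):
                fold_splits.append((rest_idx[train_pos], rest_idx[val_pos]))
        schedule.append(LocvIteration(test_cluster, test_idx, fold_splits))
    return schedule


# -- finetuning ---------------------------------------------------------------


def _enumerate_smiles(records, n_per_record: int, seed: int) -> list[PermeabilityRecord]:
    """Randomized SMILES rewrites of each record (same molecule, same target),
    deterministic in ``seed``."""
    out: list[PermeabilityRecord] = []
    for rec_no, record in enumerate(records):
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is None:
            continue
        variants = Chem.MolToRandomSmilesVect(
            mol, n_per_record, randomSeed=seed + rec_no
        )
        for j, rewritten in enumerate(variants):
            out.append(
                PermeabilityRecord(
                    id=f"{record.id}#aug{j}",
                    smiles=rewritten,
                    assay=record.assay,
                    logp_exp=record.logp_exp,
                )
            )
    return out


@dataclass(frozen=True)
class FinetuneConfig:
    """Regression finetuning hyperparameters (paper-scale defaults).

    ``augment`` adds that many randomized (non-canonical) SMILES rewrites of
    each training record — SMILES enumeration, the standard augmentation for
    string-based molecular models; validation and test data are never
    augmented. ``cosine_decay`` anneals the learning rate to zero over
    ``max_steps``.
    """

    lr: float = 5e-6
    dropout: float = 0.15
    weight_decay: float = 0.001
    batch_size: int = 16
    max_steps: int = 10_000
    augment: int = 0
    cosine_decay: bool = False
    seed: int = 0


def finetune_regression(
    pretrained: RoPEMaskedLM,
    vocab: Vocabulary,
    train_records,
    val_records,
    config: FinetuneConfig = FinetuneConfig(),
) -> RegressionModel:
    """Finetune the full encoder plus a fresh scalar head under MSE loss.

    Validation MSE is measured after every epoch and the weights with the
    lowest validation MSE are returned.
    """
    if not len(train_records):
        raise ValueError("empty training set")
    if not len(val_records):
        raise ValueError("empty validation set: checkpoint selection is undefined")

    context = pretrained.config.context
    train_records = list(train_records)
    if config.augment > 0:
        train_records = train_records + _enumerate_smiles(
            train_records, config.augment, config.seed
        )
    train_ids, train_flags = _encode_records(train_records, vocab, context)
    val_ids, val_flags = _encode_records(val_records, vocab, context)
    train_y = np.array([r.logp_exp for r in train_records], dtype=np.float32)
    val_y = np.array([r.logp_exp for r in val_records], dtype=np.float32)

    model = RegressionModel(pretrained.config, seed=config.seed)
    model.encoder.load_state(pretrained.encoder.state())
    # start the scalar head at the training-target mean: Adam moves a bias by
    # roughly lr per step, so an uncentered head wastes the whole step budget
    model.head.bias.data = np.full(1, train_y.mean(), dtype=np.float32)

    if config.max_steps == 0:
        return model

    rng = np.random.default_rng(config.seed)
    drop_rng = np.random.default_rng(config.seed + 1)
    optimizer = nn.AdamW(
        model.parameters(),
        lr=config.lr,
        weight_decay=config.weight_decay,
        decay_steps=config.max_steps if config.cosine_decay else 0,
    )

    def val_mse() -> float:
        preds = model.predict(val_ids, val_flags, batch_size=config.batch_size)
        return float(np.mean((preds - val_y) ** 2))

    best = (val_mse(), model.state())
    steps_done = 0
    while steps_done < config.max_steps:
        order = rng.permutation(len(train_ids))
        for start in range(0, len(order), config.batch_size):
            take = order[start : start + config.batch_size]
            ids_b, flags_b = _trim(train_ids[take], train_flags[take])
            preds = model(ids_b, flags_b, p_drop=config.dropout, drop_rng=drop_rng)
            err = preds - nn.Tensor(train_y[take])
            loss = (err * err).mean()
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            steps_done += 1
            if steps_done >= config.max_steps:
                break
        mse = val_mse()  # epoch boundary (or step budget exhausted)
        if mse < best[0]:
            best = (mse, model.state())
    model.load_state(best[1])
    return model


def ensemble_predict(
    models, vocab: Vocabulary, records, batch_size: int = 64, tta: int = 0, tta_seed: int = 0
) -> np.ndarray:
    """Arithmetic mean of the fold models' scalar predictions.

    With ``tta`` > 0, each model's prediction is itself averaged over the
    canonical SMILES plus ``tta`` randomized rewrites (test-time SMILES
    enumeration); targets are untouched.
    """
    models = list(models)
    if not models:
        raise ValueError("ensemble needs at least one model")
    records = list(records)
    context = models[0].config.context
    views = [_encode_records(records, vocab, context)]
    for k in range(tta):
        rewrites = _enumerate_smiles(records, 1, seed=tta_seed + 7919 * (k + 1))
        views.append(_encode_records(rewrites, vocab, context))
    preds = [
        m.predict(ids, flags, batch_size=batch_size) for m in models for ids, flags in views
    ]
    return np.mean(preds, axis=0)


# -- scoring ------------------------------------------------------------------


@dataclass
class ClusterScore:
    """Classification and regression metrics for one held-out cluster."""

    cluster: int
    n: int
    n_permeable: int
    roc_auc: float  # nan when the cluster is single-class
    pr_auc: float
    rmse: float

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "n": self.n,
            "n_permeable": self.n_permeable,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "rmse": self.rmse,
        }


def score(predictions, records, cutoff: float = DEFAULT_CUTOFF, cluster: int = -1) -> ClusterScore:
    """Score continuous predictions against one cluster's records.

    Records at or above ``cutoff`` (log10 cm/s) count as permeable. ROC-AUC
    and PR-AUC use the raw predictions as ranking scores; RMSE compares them
    to the experimental values directly.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.array([r.logp_exp for r in records], dtype=float)
    if len(predictions) != len(truth):
        raise ValueError("predictions and records are misaligned")
    labels = (truth >= cutoff).astype(int)
    rmse = float(np.sqrt(np.mean((predictions - truth) ** 2)))
    if labels.min() == labels.max():
        logger.warning("cluster %s is single-class; AUCs undefined", cluster)
        roc = pr = float("nan")
    else:
        roc = float(roc_auc_score(labels, predictions))
        pr = float(average_precision_score(labels, predictions))
    return ClusterScore(
        cluster=cluster,
        n=len(truth),
        n_permeable=int(labels.sum()),
        roc_auc=roc,
        pr_auc=pr,
        rmse=rmse,
    )


@dataclass
class EvalReport:
    """Per-cluster scores plus their mean and standard deviation.

    Clusters with undefined AUCs are excluded from the AUC aggregates (with a
    logged warning); RMSE aggregates always use every cluster.
    """

    per_cluster: list[ClusterScore]
    aggregate: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.aggregate:
            agg = {}
            for metric in ("roc_auc", "pr_auc", "rmse"):
                values = np.array([getattr(s, metric) for s in self.per_cluster])
                defined = values[~np.isnan(values)]
                if len(defined) < len(values):
                    logger.warning(
                        "%d clusters excluded from %s aggregate (single-class)",
                        len(values) - len(defined), metric,
                    )
                agg[metric] = {
                    "mean": float(defined.mean()) if len(defined) else float("nan"),
                    "sd": float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
                }
            self.aggregate = agg

    def to_dict(self) -> dict:
        return {
            "per_cluster": [s.to_dict() for s in self.per_cluster],
            "aggregate": self.aggregate,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        lines = ["cluster    n  perm  roc_auc  pr_auc   rmse"]
        for s in self.per_cluster:
            lines.append(
                f"{s.cluster:7d} {s.n:4d} {s.n_permeable:5d}  "
                f"{s.roc_auc:7.3f} {s.pr_auc:7.3f} {s.rmse:6.3f}"
            )
        agg = self.aggregate
        lines.append(
            "mean+-sd        "
            f"  {agg['roc_auc']['mean']:7.3f} {agg['pr_auc']['mean']:7.3f} "
            f"{agg['rmse']['mean']:6.3f}"
        )
        lines.append(
            "                "
            f"+-{agg['roc_auc']['sd']:6.3f} +-{agg['pr_auc']['sd']:5.3f} "
            f"+-{agg['rmse']['sd']:5.3f}"
        )
        return "\n".join(lines)


def aggregate_scores(scores) -> EvalReport:
    return EvalReport(per_cluster=list(scores))


def run_locv(
    pretrained: RoPEMaskedLM,
    vocab: Vocabulary,
    records,
    schedule: list[LocvIteration],
    config: FinetuneConfig = FinetuneConfig(),
    cutoff: float = DEFAULT_CUTOFF,
    tta: int = 0,
) -> tuple[EvalReport, pd.DataFrame]:
    """Run the full leave-one-cluster-out protocol.

    For every iteration, train one regression model per fold, predict the
    held-out cluster with the fold-mean ensemble, and score it. Returns the
    report and a per-record prediction table (id, prediction, truth, cluster).
    """
    records = list(records)
    scores: list[ClusterScore] = []
    rows = []
    for iteration in schedule:
        test_records = [records[i] for i in iteration.test_indices]
        test_ids = {records[i].id for i in iteration.test_indices}
        models = []
        for fold_no, (train_idx, val_idx) in enumerate(iteration.folds):
            overlap = (set(train_idx) | set(val_idx)) & set(iteration.test_indices.tolist())
            if overlap:
                raise RuntimeError("train/test leakage in schedule")
            fold_cfg = dataclasses.replace(
                config, seed=config.seed + 1000 * iteration.test_cluster + fold_no
            )
            models.append(
                finetune_regression(
                    pretrained,
                    vocab,
                    [records[i] for i in train_idx],
                    [records[i] for i in val_idx],
                    fold_cfg,
                )
            )
        preds = ensemble_predict(
            models, vocab, test_records, tta=tta, tta_seed=config.seed
        )
        scores.append(score(preds, test_records, cutoff=cutoff, cluster=iteration.test_cluster))
        logger.info(
            "cluster %d: roc=%.3f pr=%.3f rmse=%.3f",
            iteration.test_cluster, scores[-1].roc_auc, scores[-1].pr_auc, scores[-1].rmse,
        )
        for record, pred in zip(test_records, preds):
            assert record.id in test_ids
            rows.append(
                {
                    "id": record.id,
                    "prediction": float(pred),
                    "logP_exp": record.logp_exp,
                    "label": int(record.logp_exp >= cutoff),
                    "cluster": iteration.test_cluster,
                }
            )
    return aggregate_scores(scores), pd.DataFrame(rows)
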