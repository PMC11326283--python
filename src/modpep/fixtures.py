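"""Synthetic permeability fixtures and the end-to-end desk-scale pipeline.

The toy permeability dataset stands in for a curated cyclic-peptide PAMPA
table (synthetic throughout — no measured data): peptides come from the
package's own generator and their log10 permeability is planted as a linear
function of four descriptors recomputable from the SMILES alone —

* ``length``  — alpha-carbon count (residues),
* ``n_methyl`` — N-methylated backbone amide count,
* ``peg``     — PEG chain present (0/1),
* ``cyclic``  — macrocycle present (0/1),

plus Gaussian noise. Modifications known to help membrane permeation
(N-methylation, cyclization) get positive weights; PEGylation and size get
negative ones. A configurable share of "undetectable" (-10) rows and
non-PAMPA assay rows is injected so the cleaning stage has work to do.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .chem import alpha_carbon_count
from .generator import GeneratorConfig, generate_record
from .mlm import (
    ModelConfig,
    TrainConfig,
    load_checkpoint,
    save_checkpoint,
    train_mlm,
)
from .permeability import (
    FinetuneConfig,
    PermeabilityRecord,
    embed_records,
    filter_records,
    make_locv_schedule,
    read_permeability_table,
    reduce_and_cluster,
    run_locv,
    write_permeability_table,
)
from .residues import ResidueLibrary, default_library
from .tokenizer import TokenizerConfig, Vocabulary, train_vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "ToyPermeabilityFixture",
    "compute_descriptors",
    "make_toy_permeability_dataset",
    "ArchConfig",
    "FixtureConfig",
    "ClusterConfig",
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "config_hash",
]

_NMETHYL_SMARTS = Chem.MolFromSmarts("[CH3][NX3][CX3]=O")
_PEG_SMARTS = Chem.MolFromSmarts("[NX3]CCOC")

#: planted descriptor weights (log10 cm/s units): modest size penalty,
#: permeability-enhancing N-methylation and cyclization, PEG penalty
DEFAULT_COEFFICIENTS = {
    "intercept": -5.6,
    "length": -0.05,
    "n_methyl": 0.3,
    "peg": -1.0,
    "cyclic": 0.8,
}

DESCRIPTOR_NAMES = ("length", "n_methyl", "peg", "cyclic")


def _is_macrocyclic(mol: Chem.Mol) -> bool:
    """A ring that runs through an amide bond or a disulfide marks a peptide
    macrocycle; proline rings and aromatic side chains contain neither."""
    for bond in mol.GetBonds():
        if not bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 16 and b.GetAtomicNum() == 16:
            return True
        for c_atom, n_atom in ((a, b), (b, a)):
            if (
                c_atom.GetAtomicNum() == 6
                and not c_atom.GetIsAromatic()
                and n_atom.GetAtomicNum() == 7
            ):
                has_carbonyl = any(
                    nb.GetBondType() == Chem.BondType.DOUBLE
                    and nb.GetOtherAtom(c_atom).GetAtomicNum() == 8
                    for nb in c_atom.GetBonds()
                )
                if has_carbonyl:
                    return True
    return False


def compute_descriptors(smiles: str) -> dict[str, float]:
    """The four planted descriptors, computed from the SMILES string alone."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    return {
        "length": float(alpha_carbon_count(mol)),
        "n_methyl": float(len(mol.GetSubstructMatches(_NMETHYL_SMARTS))),
        "peg": float(bool(mol.GetSubstructMatches(_PEG_SMARTS))),
        "cyclic": float(_is_macrocyclic(mol)),
    }


@dataclass
class ToyPermeabilityFixture:
    """Synthetic permeability table with known ground truth."""

    records: list[PermeabilityRecord]
    planted_coefficients: dict[str, float]
    noise_sd: float
    descriptors: pd.DataFrame  # rows aligned with the clean PAMPA records

    @property
    def clean_records(self) -> list[PermeabilityRecord]:
        return filter_records(self.records)


def make_toy_permeability_dataset(
    n: int,
    generator_config: GeneratorConfig | None = None,
    coefficients: dict[str, float] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    undetectable_fraction: float = 0.05,
    other_assay_fraction: float = 0.05,
    library: ResidueLibrary | None = None,
    path=None,
) -> ToyPermeabilityFixture:
    """Build a synthetic PAMPA table of ``n`` clean records plus injected
    distractor rows (-10 "undetectable" markers and non-PAMPA assays)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    coefficients = dict(DEFAULT_COEFFICIENTS, **(coefficients or {}))
    unknown = set(coefficients) - ({"intercept"} | set(DESCRIPTOR_NAMES))
    if unknown:
        raise ValueError(f"unknown coefficient names {sorted(unknown)}")
    if generator_config is None:
        # shorter chains and richer modification variety than the pretraining
        # defaults, so every descriptor varies within a small dataset
        generator_config = GeneratorConfig(
            max_length=10,
            nmeth_peptide_fraction=0.4,
            peg_fraction=0.4,
            seed=seed,
        )
    library = library or default_library()
    rng = np.random.default_rng(seed + 1)

    n_und = int(round(n * undetectable_fraction))
    n_other = int(round(n * other_assay_fraction))
    total = n + n_und + n_other

    records: list[PermeabilityRecord] = []
    desc_rows: list[dict] = []
    other_assays = ("Caco2", "MDCK", "RRCK")
    for i in range(total):
        generated = generate_record(library, generator_config, i)
        desc = compute_descriptors(generated.smiles)
        logp = coefficients["intercept"] + sum(
            coefficients[name] * desc[name] for name in DESCRIPTOR_NAMES
        )
        logp += float(rng.normal(0.0, noise_sd))
        if i < n:
            assay, value = "PAMPA", logp
            desc_rows.append({"id": f"pep-{i:05d}", **desc, "logP_exp": value})
        elif i < n + n_und:
            assay, value = "PAMPA", -10.0
        else:
            assay, value = other_assays[(i - n - n_und) % len(other_assays)], logp
        records.append(
            PermeabilityRecord(
                id=f"pep-{i:05d}", smiles=generated.smiles, assay=assay, logp_exp=value
            )
        )
    order = rng.permutation(total)
    records = [records[i] for i in order]
    fixture = ToyPermeabilityFixture(
        records=records,
        planted_coefficients=coefficients,
        noise_sd=noise_sd,
        descriptors=pd.DataFrame(desc_rows),
    )
    if path is not None:
        write_permeability_table(records, path)
    return fixture


# -- pipeline configuration ---------------------------------------------------


@dataclass(frozen=True)
class ArchConfig:
    """Encoder architecture block (vocabulary size comes from the tokenizer)."""

    layers: int = 2
    heads: int = 4
    hidden: int = 64
    intermediate: int = 128
    context: int = 160

    def to_model_config(self, vocab_size: int) -> ModelConfig:
        return ModelConfig(vocab_size=vocab_size, **asdict(self))


@dataclass(frozen=True)
class FixtureConfig:
    n: int = 500
    noise_sd: float = 0.3
    undetectable_fraction: float = 0.05
    other_assay_fraction: float = 0.05
    coefficients: dict = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))


@dataclass(frozen=True)
class ClusterConfig:
    variance_target: float = 0.99
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_restarts: int = 10


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; defaults are desk scale (minutes on one
    CPU) while exercising every stage."""

    seed: int = 0
    out_dir: str = "modpep_run"
    n_molecules: int = 2000
    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(max_length=10))
    tokenizer: TokenizerConfig = field(default_factory=TokenizerConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    pretrain: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            steps=1000, batch_size=32, lr=1e-3, validation_fraction=0.05
        )
    )
    fixture: FixtureConfig = field(default_factory=FixtureConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    finetune: FinetuneConfig = field(
        default_factory=lambda: FinetuneConfig(
            lr=1e-3, dropout=0.0, weight_decay=1e-3, batch_size=16, max_steps=600, augment=2
        )
    )
    folds: int = 5
    cutoff: float = -5.5
    tta: int = 4

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            generator=dataclasses.replace(self.generator, seed=seed),
            pretrain=dataclasses.replace(self.pretrain, seed=seed),
            finetune=dataclasses.replace(self.finetune, seed=seed),
        )

    def to_dict(self) -> dict:
        out = asdict(self)
        out["generator"]["cyclization_types"] = list(self.generator.cyclization_types)
        out["generator"]["peg_monomers"] = list(self.generator.peg_monomers)
        out["cluster"]["k_candidates"] = list(self.cluster.k_candidates)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        blocks = {
            "generator": GeneratorConfig,
            "tokenizer": TokenizerConfig,
            "arch": ArchConfig,
            "pretrain": TrainConfig,
            "fixture": FixtureConfig,
            "cluster": ClusterConfig,
            "finetune": FinetuneConfig,
        }
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in data.items():
            if key in blocks:
                block_cls = blocks[key]
                block_fields = {f.name for f in dataclasses.fields(block_cls)}
                bad = set(value) - block_fields
                if bad:
                    raise ValueError(f"unknown keys in {key!r} block: {sorted(bad)}")
                if key == "generator":
                    value = dict(value)
                    if "cyclization_types" in value:
                        value["cyclization_types"] = tuple(value["cyclization_types"])
                    if "peg_monomers" in value:
                        value["peg_monomers"] = tuple(value["peg_monomers"])
                if key == "cluster" and "k_candidates" in value:
                    value = dict(value)
                    value["k_candidates"] = tuple(value["k_candidates"])
                kwargs[key] = block_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode("utf-8")
    ).hexdigest()[:16]


# -- pipeline -----------------------------------------------------------------


@dataclass
class PipelineResult:
    out_dir: Path
    corpus_summary: dict
    vocab_size: int
    pretrain_reports: list
    cluster_plan: object
    report: object  # EvalReport
    predictions: pd.DataFrame


def _write_meta(path: Path, digest: str) -> None:
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"config_sha256": digest}) + "\n", encoding="utf-8"
    )


def _meta_matches(path: Path, digest: str) -> bool:
    meta = path.with_suffix(path.suffix + ".meta.json")
    if not path.exists() or not meta.exists():
        return False
    try:
        stored = json.loads(meta.read_text(encoding="utf-8"))["config_sha256"]
    except (json.JSONDecodeError, KeyError):
        return False
    if stored != digest:
        warnings.warn(f"{path.name}: artifact was produced by a different configuration")
        return False
    return True


def run_pipeline(config: RunConfig, resume: bool = True) -> PipelineResult:
    """generate -> tokenize -> pretrain -> fixture -> cluster -> finetune/evaluate.

    Every artifact carries a sidecar with the configuration hash; with
    ``resume`` enabled, stages whose artifact matches the hash are reloaded
    instead of recomputed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config_hash(config)
    config.to_yaml(out / "config.yaml")
    library = default_library()

    # stage 1: corpus
    corpus_path = out / "corpus.txt"
    summary_path = out / "corpus_summary.json"
    if resume and _meta_matches(corpus_path, digest) and _meta_matches(summary_path, digest):
        corpus_summary = json.loads(summary_path.read_text(encoding="utf-8"))
        logger.info("stage=generate status=resumed")
    else:
        from .generator import generate_corpus

        summary = generate_corpus(config.n_molecules, library, config.generator, corpus_path)
        corpus_summary = summary.to_dict()
        summary_path.write_text(json.dumps(corpus_summary, indent=2), encoding="utf-8")
        _write_meta(corpus_path, digest)
        _write_meta(summary_path, digest)
        logger.info("stage=generate n=%d seed=%d", config.n_molecules, config.generator.seed)

    # stage 2: tokenizer
    vocab_path = out / "vocab.txt"
    if resume and _meta_matches(vocab_path, digest):
        vocab = Vocabulary.load(vocab_path)
        logger.info("stage=tokenize status=resumed")
    else:
        vocab = train_vocabulary(corpus_path, config.tokenizer)
        vocab.save(vocab_path)
        _write_meta(vocab_path, digest)
        logger.info("stage=tokenize vocab=%d", len(vocab))

    # stage 3: pretraining
    model_config = config.arch.to_model_config(len(vocab))
    checkpoint_path = out / "pretrained.npz"
    reports_path = out / "pretrain_reports.json"
    if resume and _meta_matches(checkpoint_path, digest) and _meta_matches(reports_path, digest):
        model = load_checkpoint(checkpoint_path, vocab)
        pretrain_reports = json.loads(reports_path.read_text(encoding="utf-8"))
        logger.info("stage=pretrain status=resumed")
    else:
        model, reports = train_mlm(corpus_path, vocab, model_config, config.pretrain)
        save_checkpoint(model, vocab, checkpoint_path)
        pretrain_reports = [r.to_dict() for r in reports]
        reports_path.write_text(json.dumps(pretrain_reports, indent=2), encoding="utf-8")
        _write_meta(checkpoint_path, digest)
        _write_meta(reports_path, digest)
        for r in reports:
            logger.info(
                "stage=pretrain step=%d loss=%.4f macro_acc=%.4f seed=%d",
                r["step"] if isinstance(r, dict) else r.step,
                r["loss"] if isinstance(r, dict) else r.loss,
                r["macro_accuracy"] if isinstance(r, dict) else r.macro_accuracy,
                config.pretrain.seed,
            )

    # stage 4: fixture table
    fixture_path = out / "fixture.csv"
    fixture_gen = dataclasses.replace(
        GeneratorConfig(
            max_length=config.generator.max_length,
            nmeth_peptide_fraction=0.4,
            peg_fraction=0.4,
        ),
        seed=config.seed + 101,
    )
    if not (resume and _meta_matches(fixture_path, digest)):
        make_toy_permeability_dataset(
            config.fixture.n,
            generator_config=fixture_gen,
            coefficients=config.fixture.coefficients,
            noise_sd=config.fixture.noise_sd,
            seed=config.seed + 202,
            undetectable_fraction=config.fixture.undetectable_fraction,
            other_assay_fraction=config.fixture.other_assay_fraction,
            library=library,
            path=fixture_path,
        )
        _write_meta(fixture_path, digest)
        logger.info("stage=fixture n=%d noise_sd=%.2f", config.fixture.n, config.fixture.noise_sd)

    # stage 5: clean, embed, cluster
    table = read_permeability_table(fixture_path)
    records = filter_records(table.records)
    embeddings = embed_records(records, model, vocab)
    plan = reduce_and_cluster(
        embeddings,
        variance_target=config.cluster.variance_target,
        k_candidates=config.cluster.k_candidates,
        seed=config.seed,
        n_restarts=config.cluster.n_restarts,
    )
    clusters_path = out / "clusters.json"
    clusters_path.write_text(
        json.dumps(
            {
                "k": plan.k,
                "pca_components": plan.pca_components,
                "explained_variance": plan.explained_variance,
                "quality": plan.quality,
                "labels": plan.labels.tolist(),
                "record_ids": [r.id for r in records],
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    _write_meta(clusters_path, digest)
    logger.info("stage=cluster k=%d pca=%d", plan.k, plan.pca_components)

    # stage 6: leave-one-cluster-out finetuning and scoring
    schedule = make_locv_schedule(plan, folds=config.folds, seed=config.seed)
    report, predictions = run_locv(
        model, vocab, records, schedule, config=config.finetune, cutoff=config.cutoff,
        tta=config.tta,
    )
    report.to_json(out / "eval_report.json")
    _write_meta(out / "eval_report.json", digest)
    predictions.to_csv(out / "predictions.csv", index=False)
    _write_meta(out / "predictions.csv", digest)
    logger.info(
        "stage=evaluate roc=%.3f pr=%.3f rmse=%.3f",
        report.aggregate["roc_auc"]["mean"],
        report.aggregate["pr_auc"]["mean"],
        report.aggregate["rmse"]["mean"],
    )
    return PipelineResult(
        out_dir=out,
        corpus_summary=corpus_summary,
        vocab_size=len(vocab),
        pretrain_reports=pretrain_reports,
        cluster_plan=plan,
        report=report,
        predictions=predictions,
    )
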