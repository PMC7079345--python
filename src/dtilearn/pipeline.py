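"""End-to-end orchestration: featurize -> fuse -> split -> train -> evaluate.

The pipeline reads a directory of PSI-BLAST ASCII PSSMs, a fingerprint
table and a labelled pairs file, computes Legendre-moment protein features,
concatenates them with the drug fingerprints, fits sparse PCA on the
training split only (validation/test rows are transformed with the frozen
model), trains the requested classifier and reports test-set metrics.
Every run writes a manifest with all seeds and a hash of the configuration
so results are exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .evaluation import (
    MetricsReport,
    evaluate_predictions,
    read_pairs_tsv,
    split_dataset,
)
from .fingerprints import parse_fingerprint_table
from .fusion import ElasticNetSparsePCA, build_pair_matrix, save_spca
from .legendre import LegendreMomentTransformer
from .models import (
    DeepLSTMClassifier,
    GridSearchSVM,
    MLPBaselineClassifier,
    history_to_tsv,
    save_network_model,
)
from .pssm import load_pssm_directory

logger = logging.getLogger("dtilearn.pipeline")

__all__ = ["PipelineConfig", "run_full_pipeline", "PipelineResult"]


class MissingInputError(FileNotFoundError):
    """An input path named in the configuration does not exist."""


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    pssm_dir: str
    fingerprints: str
    pairs: str
    out_dir: str = "dtilearn_run"
    arch: str = "lstm"  # lstm | mlp | svm
    a_max: int = 30
    b_max: int = 30
    normalization: str = "minmax"
    n_components: int = 400
    l1_weight: float = 0.1
    ridge_weight: float = 1e-2
    spca_max_iter: int = 500
    n_hidden_layers: int = 4
    units_per_layer: int = 36
    dropout_rate: float = 0.5
    batch_size: int = 64
    max_epochs: int = 500
    learning_rate: float = 0.002
    lr_decay: float = 0.004
    momentum: float = 0.5
    early_stop_patience: int = 50
    threshold: float = 0.5
    split_seed: int = 0
    model_seed: int = 0

    def config_hash(self) -> str:
        # out_dir names where results go, not what is computed
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    metrics: MetricsReport
    n_pairs: int
    n_components_used: int
    out_dir: Path
    best_epoch: int | None = None


def _build_classifier(config: PipelineConfig):
    common = dict(
        n_hidden_layers=config.n_hidden_layers,
        units_per_layer=config.units_per_layer,
        dropout_rate=config.dropout_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        learning_rate=config.learning_rate,
        lr_decay=config.lr_decay,
        momentum=config.momentum,
        early_stop_patience=config.early_stop_patience,
        random_state=config.model_seed,
    )
    if config.arch == "lstm":
        return DeepLSTMClassifier(**common)
    if config.arch == "mlp":
        return MLPBaselineClassifier(**common)
    if config.arch == "svm":
        return GridSearchSVM(random_state=config.model_seed)
    raise ValueError(f"unknown architecture {config.arch!r}")


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow and write all artifacts to ``out_dir``."""
    for name in ("pssm_dir", "fingerprints", "pairs"):
        path = Path(getattr(config, name))
        if not path.exists():
            raise MissingInputError(f"input path for {name!r} not found: {path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    # --- featurize proteins -------------------------------------------------
    pssms = load_pssm_directory(config.pssm_dir)
    featurizer = LegendreMomentTransformer(
        a_max=config.a_max, b_max=config.b_max, normalization=config.normalization
    ).fit()
    from .legendre import featurize_protein

    descriptors = {
        pid: featurize_protein(p, featurizer.order_config_, config.normalization)
        for pid, p in pssms.items()
    }
    any_pssm = next(iter(pssms.values()))
    logger.info("featurized %d proteins (PSSM %dx20 -> %d features)",
                len(pssms), any_pssm.n_residues, featurizer.n_features_out_)

    # --- drugs --------------------------------------------------------------
    fingerprints = {fp.drug_id: fp for fp in parse_fingerprint_table(config.fingerprints)}
    logger.info("loaded %d fingerprints (881 bits)", len(fingerprints))

    # --- pairs and fusion ---------------------------------------------------
    pairs, labels = read_pairs_tsv(config.pairs)
    X = build_pair_matrix(pairs, fingerprints, descriptors)
    logger.info("assembled %d pair vectors of dim %d", *X.shape)

    split = split_dataset(len(pairs), seed=config.split_seed, labels=labels)
    n_comp = min(config.n_components, split.train_idx.size, X.shape[1])
    spca = ElasticNetSparsePCA(
        n_components=n_comp,
        l1_weight=config.l1_weight,
        ridge_weight=config.ridge_weight,
        max_iter=config.spca_max_iter,
        random_state=config.model_seed,
    ).fit(X[split.train_idx])
    Z = spca.transform(X)
    save_spca(spca, out_dir / "spca_model.npz")
    logger.info("sparse PCA: %d -> %d components (zero-loading fraction %.3f)",
                X.shape[1], n_comp, spca.zero_loading_fraction)

    # --- train --------------------------------------------------------------
    model = _build_classifier(config)
    best_epoch = None
    if config.arch == "svm":
        model.fit(Z[split.train_idx], labels[split.train_idx])
    else:
        model.fit(
            Z[split.train_idx], labels[split.train_idx],
            X_val=Z[split.val_idx], y_val=labels[split.val_idx],
        )
        best_epoch = model.best_epoch_
        save_network_model(model, out_dir / "model.npz")
        history_to_tsv(model, out_dir / "history.tsv")

    # --- evaluate -----------------------------------------------------------
    scores = model.predict_score(Z[split.test_idx])
    report = evaluate_predictions(labels[split.test_idx], scores, config.threshold)
    logger.info("test metrics: %s", report.as_dict())

    metrics_payload = {
        "config_hash": cfg_hash,
        "arch": config.arch,
        "n_pairs": len(pairs),
        "n_components": n_comp,
        "split": {k: int(getattr(split, k).size) for k in ("train_idx", "val_idx", "test_idx")},
        "metrics": report.as_dict(),
    }
    (out_dir / "metrics.json").write_text(json.dumps(metrics_payload, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config_hash": cfg_hash,
        "config": asdict(config),
        "seeds": {"split_seed": config.split_seed, "model_seed": config.model_seed},
        "shapes": {"pair_matrix": list(X.shape), "reduced": list(Z.shape)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        metrics=report,
        n_pairs=len(pairs),
        n_components_used=n_comp,
        out_dir=out_dir,
        best_epoch=best_epoch,
    )
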