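"""End-to-end pipeline: simulate -> condition -> classify (kNN and CNN) -> evaluate.

One master seed deterministically derives an independent seed per stage, so
changing, say, the CNN initialization does not perturb the simulated data.
Every run writes its intermediate datasets, trained model, training history,
per-classifier reports, a comparison table/plot and a manifest with the
config hash and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import cnn as cnn_mod
from . import evaluation, features, knn, preprocessing
from .preprocessing import FilterSpec, SegmentDataset
from .synthetic import LesionRegime, SimulationConfig, generate_dataset

logger = logging.getLogger("emglesion")

__all__ = ["RunConfig", "stage_seed", "run_pipeline",
           "knn_fit_predict", "cnn_fit_predict"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Complete configuration of one pipeline run."""

    n_pre: int = 400
    n_post: int = 400
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    lesion: LesionRegime = field(default_factory=LesionRegime)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    window_length: int = 1000
    test_fraction: float = 0.2
    split_by_recording: bool = False
    turns_threshold: Optional[float] = None  # None -> 0.1 x training range
    zc_threshold: float = 0.0
    k_neighbors: int = 9
    training: cnn_mod.TrainingConfig = field(default_factory=cnn_mod.TrainingConfig)
    cv_folds: int = 0  # 0 -> single held-out split only
    master_seed: int = 0
    output_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if sim.get("lesion"):
                sim["lesion"] = LesionRegime(**sim["lesion"])
            kwargs["simulation"] = SimulationConfig(**sim)
        if "lesion" in kwargs:
            kwargs["lesion"] = LesionRegime(**kwargs["lesion"])
        if "filter_spec" in kwargs:
            kwargs["filter_spec"] = FilterSpec(**kwargs["filter_spec"])
        if "training" in kwargs:
            kwargs["training"] = cnn_mod.TrainingConfig(**kwargs["training"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def knn_fit_predict(
    train_set: SegmentDataset,
    test_set: SegmentDataset,
    k: int = 9,
    thresholds: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Feature extraction + kNN: the classical arm as a classifier recipe."""
    train_fm = features.build_feature_matrix(train_set, thresholds)
    test_fm = features.build_feature_matrix(
        test_set, thresholds, scaling=train_fm.scaling
    )
    model = knn.knn_fit(train_fm, train_set.labels, k=k)
    return knn_predict_with_model(model, test_fm.values)


def knn_predict_with_model(model, queries):
    return knn.knn_predict(model, queries)


def cnn_fit_predict(
    train_set: SegmentDataset,
    test_set: SegmentDataset,
    spec: Optional[cnn_mod.ArchitectureSpec] = None,
    cfg: Optional[cnn_mod.TrainingConfig] = None,
) -> np.ndarray:
    """Train the CNN on the train split and predict the test split."""
    spec = spec or cnn_mod.default_architecture(train_set.window_length)
    cfg = cfg or cnn_mod.TrainingConfig()
    model, _ = cnn_mod.train(spec, train_set, test_set, cfg)
    _, labels = cnn_mod.predict(model, test_set.segments)
    return labels


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return {'knn': report, 'cnn': report, ...}.

    Artifacts are written under ``config.output_dir``; a stage failure
    aborts with a stage-named error while earlier outputs stay on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: stage_seed(config.master_seed, name)
             for name in ("simulate", "preprocess", "knn", "cnn", "evaluate")}
    results: dict = {}

    stage = "simulate"
    try:
        logger.info("stage %s: %d pre + %d post recordings", stage,
                    config.n_pre, config.n_post)
        recordings = generate_dataset(
            config.n_pre, config.n_post, config.simulation, config.lesion,
            seed=seeds["simulate"],
        )

        stage = "preprocess"
        logger.info("stage %s", stage)
        train_set, test_set = preprocessing.preprocess_recordings(
            recordings,
            spec=config.filter_spec,
            window_length=config.window_length,
            test_fraction=config.test_fraction,
            seed=seeds["preprocess"],
            split_by_recording=config.split_by_recording,
        )
        train_set.save(out / "train_set.npz")
        test_set.save(out / "test_set.npz")

        thresholds = None
        if config.turns_threshold is not None:
            thresholds = (config.turns_threshold, config.zc_threshold)

        stage = "knn"
        logger.info("stage %s (k=%d)", stage, config.k_neighbors)
        knn_preds = knn_fit_predict(
            train_set, test_set, k=config.k_neighbors, thresholds=thresholds
        )
        knn_report = evaluation.EvaluationReport(classifier="knn")
        knn_report.per_fold.append(
            evaluation.metrics(evaluation.confusion(knn_preds, test_set.labels))
        )
        results["knn"] = knn_report

        stage = "cnn"
        cfg_train = dataclasses.replace(config.training, seed=seeds["cnn"])
        logger.info("stage %s (%d epochs)", stage, cfg_train.epochs)
        spec = cnn_mod.default_architecture(config.window_length)
        model, history = cnn_mod.train(spec, train_set, test_set, cfg_train)
        model.save(out / "cnn_model.npz")
        history.to_dataframe().to_csv(out / "cnn_history.csv", index=False)
        _plot_history(history, out / "cnn_curves.png")
        _, cnn_preds = cnn_mod.predict(model, test_set.segments)
        cnn_report = evaluation.EvaluationReport(classifier="cnn")
        cnn_report.per_fold.append(
            evaluation.metrics(evaluation.confusion(cnn_preds, test_set.labels))
        )
        results["cnn"] = cnn_report
        results["history"] = history

        stage = "evaluate"
        logger.info("stage %s", stage)
        if config.cv_folds >= 2:
            full = _concat(train_set, test_set)
            results["knn_cv"] = evaluation.kfold_cv(
                lambda tr, te: knn_fit_predict(tr, te, k=config.k_neighbors,
                                               thresholds=thresholds),
                full, k=config.cv_folds, seed=seeds["evaluate"],
                classifier_name="knn",
            )
            results["cnn_cv"] = evaluation.kfold_cv(
                lambda tr, te: cnn_fit_predict(tr, te, spec=spec, cfg=cfg_train),
                full, k=config.cv_folds, seed=seeds["evaluate"],
                classifier_name="cnn",
            )
            report_pair = [results["knn_cv"], results["cnn_cv"]]
        else:
            report_pair = [knn_report, cnn_report]
        evaluation.compare_report(report_pair, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "files": {
            p.name: _file_checksum(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results


def _concat(a: SegmentDataset, b: SegmentDataset) -> SegmentDataset:
    return SegmentDataset(
        np.concatenate([a.segments, b.segments]),
        np.concatenate([a.labels, b.labels]),
        a.window_length,
        np.concatenate([a.source_index, b.source_index]),
    )


def _plot_history(history: cnn_mod.TrainingHistory, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = np.arange(1, len(history.train_loss) + 1)
    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(10, 4))
    ax_loss.plot(epochs, history.train_loss, label="train")
    ax_loss.plot(epochs, history.test_loss, label="test")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("binary cross-entropy")
    ax_loss.legend()
    ax_acc.plot(epochs, history.train_acc, label="train")
    ax_acc.plot(epochs, history.test_acc, label="test")
    ax_acc.set_xlabel("epoch")
    ax_acc.set_ylabel("accuracy")
    ax_acc.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
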