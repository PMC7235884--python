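"""End-to-end benchmark: preprocess -> CNN and HOG baselines -> k-fold report.

One global seed deterministically derives every stage seed (data generation,
fold assignment, weight init, shuffling, baseline randomness), so two runs
with the same :class:`RunConfig` produce byte-identical metric reports.
Wall-clock timings are recorded in the JSON report and the log only; the
CSV report carries nothing non-deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline

from .baselines import ClassicalBaseline
from .cnn import ShallowCNNClassifier
from .datasets import LabeledImageSet, load_manifest
from .evaluate import METRIC_COLUMNS, cross_validate, make_folds, roc_auc
from .hog import HOGFeaturizer
from .preprocess import ImageStandardizer, PreprocessPlan
from .synthetic import SynthConfig, generate_dataset

__all__ = ["RunConfig", "derive_seeds", "build_recipe", "run_benchmark"]

logger = logging.getLogger("akscreen")

MODEL_NAMES = ("cnn", "svm", "rf", "knn")


@dataclass(frozen=True)
class RunConfig:
    """Flat, fully-defaulted configuration of one benchmark run."""

    # data source: a manifest, or the synthetic generator
    manifest: str | None = None
    image_dir: str | None = None
    synthetic: bool = True
    n_per_class: int = 200
    image_size: int = 64
    separation: float = 1.0
    noise_sd: float = 8.0
    # preprocessing
    equalization: str = "per_channel_rgb"
    input_space: str = "lab"
    augment: bool = True
    # network + training
    fc_width: int = 120
    dropout_p: float = 0.5
    epochs: int = 30
    # evaluation
    models: tuple[str, ...] = MODEL_NAMES
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown model name(s) {sorted(unknown)}; choose from {MODEL_NAMES}")
        if not self.synthetic and not (self.manifest and self.image_dir):
            raise ValueError("either set synthetic=True or provide manifest and image_dir")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in d:
            d = dict(d)
            models = d["models"]
            if isinstance(models, str):
                models = [m for m in models.split(",") if m]
            d["models"] = tuple(models)
        return cls(**d)


def derive_seeds(seed: int) -> dict[str, int]:
    """Stage seeds (all < 2^31) derived from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(5) % (2 ** 31)
    names = ("data", "folds", "init", "shuffle", "baseline")
    return {name: int(s) for name, s in zip(names, state)}


def build_recipe(name: str, config: RunConfig, seeds: dict[str, int]):
    """Zero-argument estimator factory for one benchmark row."""
    if name == "cnn":
        def recipe():
            return Pipeline([
                ("standardize", ImageStandardizer(equalization=config.equalization,
                                                  color_space=config.input_space)),
                ("cnn", ShallowCNNClassifier(fc_width=config.fc_width,
                                             dropout_p=config.dropout_p,
                                             epochs=config.epochs,
                                             init_seed=seeds["init"],
                                             shuffle_seed=seeds["shuffle"])),
            ])
    elif name in ("svm", "rf", "knn"):
        def recipe():
            return Pipeline([
                ("hog", HOGFeaturizer()),
                ("clf", ClassicalBaseline(kind=name, seed=seeds["baseline"])),
            ])
    else:
        raise ValueError(f"unknown model {name!r}")
    return recipe


def _load_dataset(config: RunConfig, seeds: dict[str, int]) -> LabeledImageSet:
    if config.synthetic:
        synth = SynthConfig(n_per_class=config.n_per_class, image_size=config.image_size,
                            separation=config.separation, noise_sd=config.noise_sd,
                            seed=seeds["data"])
        logger.info("generating synthetic dataset: %s", synth)
        return generate_dataset(synth)
    logger.info("loading manifest %s", config.manifest)
    return load_manifest(config.manifest, config.image_dir)


def run_benchmark(config: RunConfig, output_dir: str | Path) -> dict:
    """Execute the full benchmark and write report files.

    Writes into ``output_dir``: ``report.csv`` (one deterministic row of
    metric means per model), ``report.json`` (per-fold detail plus wall
    times), ``roc_<model>.csv`` (pooled held-out ROC points), ``config.json``
    (the resolved run configuration) and ``benchmark.log``.

    Returns ``{"report": DataFrame, "paths": {...}, "reports": {...}}``.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(output_dir / "benchmark.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    try:
        seeds = derive_seeds(config.seed)
        logger.info("stage seeds: %s", seeds)
        dataset = _load_dataset(config, seeds)
        plan = make_folds(dataset.labels, k=config.folds, seed=seeds["folds"],
                          stratified=config.stratified)
        augment_plan = PreprocessPlan(equalization_mode=config.equalization,
                                      color_space=config.input_space) if config.augment else None

        rows, reports, json_detail = [], {}, {}
        paths: dict[str, Path] = {}
        for name in config.models:
            logger.info("cross-validating model %s", name)
            report = cross_validate(build_recipe(name, config, seeds), dataset, plan,
                                    augment=augment_plan)
            reports[name] = report
            rows.append(report.summary_row(name))
            logger.info("model %s means: %s (%.1f s training)", name, report.means,
                        report.per_fold["train_seconds"].sum())
            pooled_scores = np.concatenate([d["scores"] for d in report.fold_details])
            pooled_y = np.concatenate([d["y_true"] for d in report.fold_details])
            curve, pooled_auc = roc_auc(pooled_scores, pooled_y)
            roc_path = output_dir / f"roc_{name}.csv"
            pd.DataFrame(curve, columns=["fpr", "tpr", "threshold"]).to_csv(
                roc_path, index=False, float_format="%.10g", lineterminator="\n")
            paths[f"roc_{name}"] = roc_path
            json_detail[name] = {
                "per_fold": report.per_fold.to_dict(orient="records"),
                "means": report.means,
                "pooled_auc": pooled_auc,
            }

        summary = pd.DataFrame(rows, columns=["model", *METRIC_COLUMNS, "train_seconds"])
        report_csv = output_dir / "report.csv"
        # the CSV is the determinism artifact: metric columns only, fixed format
        summary.drop(columns=["train_seconds"]).to_csv(
            report_csv, index=False, float_format="%.10g", lineterminator="\n")
        report_json = output_dir / "report.json"
        report_json.write_text(json.dumps(json_detail, indent=2))
        config_json = output_dir / "config.json"
        config_json.write_text(json.dumps(config.to_dict(), indent=2))
        paths.update(report_csv=report_csv, report_json=report_json, config_json=config_json)
        return {"report": summary, "paths": paths, "reports": reports}
    finally:
        logger.removeHandler(log_handler)
        log_handler.close()
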