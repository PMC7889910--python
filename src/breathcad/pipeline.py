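"""End-to-end run orchestration: simulate/load -> preprocess -> augment ->
featurize -> train -> evaluate, fully determined by (config, seed).

The resolved configuration is always written back next to the artifacts, and a
single JSON checkpoint stores layer shapes, all weights, the feature-scaling
constants and the preprocessing settings, so a saved model can be re-applied to
new spectrum directories.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .features import AugmentConfig, augment_cohort, featurize
from .preprocessing import PreprocessConfig, preprocess_cohort
from .spectra import (ClassLabel, LabeledSpectrumSet, SyntheticCohortConfig,
                      generate_cohort, read_cohort)
from .ssae import SSAEClassifier

logger = logging.getLogger(__name__)

CHECKPOINT_SCHEMA = 1

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "save_checkpoint", "load_checkpoint", "apply_checkpoint"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs; ``seed`` drives all randomness."""

    synthetic: bool = True
    input_dir: str | None = None
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    n_features: int = 50
    hidden_layer_sizes: tuple[int, ...] = (100, 40)
    sparsity_target: float = 0.05
    sparsity_weight: float = 4.0
    weight_decay: float = 1e-4
    learning_rate: float = 0.001
    pretrain_epochs: int = 1000
    softmax_learning_rate: float = 0.5
    softmax_epochs: int = 500
    finetune_learning_rate: float = 0.5
    finetune_epochs: int = 500
    split: ev.SplitSpec = field(default_factory=ev.SplitSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic == (self.input_dir is not None):
            raise ValueError("exactly one of synthetic / input_dir must be set")
        if self.synthetic:
            self.cohort.validate()
        self.preprocess.validate()
        self.augment.validate()
        self.split.validate()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(getattr(k, "name", k)): plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        return plain(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], dict):
            cohort = dict(data["cohort"])
            if "band_library" in cohort and isinstance(cohort["band_library"], dict):
                cohort["band_library"] = {
                    ClassLabel.from_name(k): [tuple(b) for b in v]
                    for k, v in cohort["band_library"].items()}
            for key in ("axis_range", "spike_amplitude_range"):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            data["cohort"] = SyntheticCohortConfig(**cohort)
        if "preprocess" in data and isinstance(data["preprocess"], dict):
            data["preprocess"] = PreprocessConfig(**data["preprocess"])
        if "augment" in data and isinstance(data["augment"], dict):
            aug = dict(data["augment"])
            if "directions" in aug:
                aug["directions"] = tuple(aug["directions"])
            data["augment"] = AugmentConfig(**aug)
        if "split" in data and isinstance(data["split"], dict):
            sp = dict(data["split"])
            if "fractions" in sp:
                sp["fractions"] = tuple(sp["fractions"])
            data["split"] = ev.SplitSpec(**sp)
        if "hidden_layer_sizes" in data:
            data["hidden_layer_sizes"] = tuple(data["hidden_layer_sizes"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: LabeledSpectrumSet
    features: "np.ndarray"
    labels: np.ndarray
    partitions: dict
    classifier: SSAEClassifier
    reports: dict
    scale_min: np.ndarray
    scale_max: np.ndarray


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31)
            for i in range(n)]


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Execute the full pipeline; optionally write all artifacts to ``out_dir``."""
    config.validate()
    cohort_seed, split_seed, train_seed = _child_seeds(config.seed, 3)

    if config.synthetic:
        cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)
        cohort = generate_cohort(cohort_cfg)
    else:
        cohort = read_cohort(config.input_dir)
    logger.info("cohort: %d spectra", len(cohort))

    clean = preprocess_cohort(cohort, config.preprocess)
    augmented = augment_cohort(clean, config.augment)
    logger.info("augmented: %d spectra", len(augmented))

    groups = [s.meta["source_id"] for s in augmented.spectra]
    labels = augmented.label_codes
    split = dataclasses.replace(config.split, seed=split_seed)
    train_idx, val_idx, test_idx = ev.split_data(labels, split, groups=groups)
    partitions = {"train": train_idx, "validation": val_idx, "test": test_idx}

    # feature scaling fitted on the training partition only
    train_set = augmented.subset(train_idx)
    train_features = featurize(train_set, k=config.n_features)
    scaling = (train_features.scale_min, train_features.scale_max)
    all_features = featurize(augmented, k=config.n_features, scaling=scaling)
    X = all_features.values
    y = labels

    clf = SSAEClassifier(hidden_layer_sizes=config.hidden_layer_sizes,
                         sparsity_target=config.sparsity_target,
                         sparsity_weight=config.sparsity_weight,
                         weight_decay=config.weight_decay,
                         learning_rate=config.learning_rate,
                         pretrain_epochs=config.pretrain_epochs,
                         softmax_learning_rate=config.softmax_learning_rate,
                         softmax_epochs=config.softmax_epochs,
                         finetune_learning_rate=config.finetune_learning_rate,
                         finetune_epochs=config.finetune_epochs,
                         random_state=train_seed)
    clf.fit(X[train_idx], y[train_idx])

    reports = ev.evaluate(clf, X, y, partitions)

    result = PipelineResult(config=config, cohort=cohort, features=X, labels=y,
                            partitions=partitions, classifier=clf,
                            reports=reports, scale_min=scaling[0],
                            scale_max=scaling[1])
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "resolved_config.yaml")
    metrics = {name: rep.to_dict() for name, rep in result.reports.items()}
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    save_checkpoint(result, out_dir / "checkpoint.json")
    trace = result.classifier.finetune_trace_
    pd.DataFrame({"epoch": range(len(trace.cross_entropy)),
                  "cross_entropy": trace.cross_entropy}).to_csv(
        out_dir / "finetune_trace.csv", index=False)
    for name, rep in result.reports.items():
        pd.DataFrame(rep.confusion.counts,
                     index=[c.name for c in ClassLabel],
                     columns=[c.name for c in ClassLabel]).to_csv(
            out_dir / f"confusion_{name}.csv")


def save_checkpoint(result: PipelineResult, path) -> None:
    clf = result.classifier
    model = clf.model_
    payload = {
        "schema_version": CHECKPOINT_SCHEMA,
        "layer_sizes": list(model.layer_sizes),
        "classes": [int(c) for c in clf.classes_],
        "n_features": int(clf.n_features_in_),
        "layers": [{"W": l.W.tolist(), "b": l.b.tolist(),
                    "W_dec": l.W_dec.tolist(), "b_dec": l.b_dec.tolist()}
                   for l in model.layers],
        "softmax": {"W": model.softmax.W.tolist(), "b": model.softmax.b.tolist()},
        "feature_scaling": {"min": result.scale_min.tolist(),
                            "max": result.scale_max.tolist()},
        "preprocess": dataclasses.asdict(result.config.preprocess),
        "crop_length": result.config.augment.crop_length,
        "seed": int(result.config.seed),
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> dict:
    payload = json.loads(Path(path).read_text())
    version = payload.get("schema_version")
    if version != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema version {version!r}; "
                         f"this build reads version {CHECKPOINT_SCHEMA}")
    return payload


def apply_checkpoint(payload: dict, data_dir) -> tuple[dict, np.ndarray, np.ndarray]:
    """Re-apply a saved model to a spectrum directory; returns (reports, y, pred)."""
    from .features import crop_spectrum
    from .preprocessing import preprocess
    from .ssae import AutoencoderParams, SSAEModel, SoftmaxParams, predict

    cohort = read_cohort(data_dir)
    pre_cfg = PreprocessConfig(**payload["preprocess"])
    crop = int(payload["crop_length"])
    spectra = [crop_spectrum(preprocess(s, pre_cfg), crop) for s in cohort.spectra]
    clean = LabeledSpectrumSet(spectra, list(cohort.labels))

    k = int(payload["n_features"])
    scaling = (np.asarray(payload["feature_scaling"]["min"], dtype=float),
               np.asarray(payload["feature_scaling"]["max"], dtype=float))
    feats = featurize(clean, k=k, scaling=scaling)
    X = feats.values
    expected = int(payload["n_features"])
    if X.shape[1] != expected:
        raise ValueError(f"feature dimension mismatch: checkpoint expects "
                         f"{expected}, data produced {X.shape[1]}")

    model = SSAEModel(
        [AutoencoderParams(np.array(l["W"]), np.array(l["b"]),
                           np.array(l["W_dec"]), np.array(l["b_dec"]))
         for l in payload["layers"]],
        SoftmaxParams(np.array(payload["softmax"]["W"]),
                      np.array(payload["softmax"]["b"])),
        list(payload["layer_sizes"]))
    pred_idx, probs = predict(model, X)
    classes = np.array(payload["classes"], dtype=int)
    y_pred = classes[pred_idx]
    y_true = clean.label_codes

    class _Wrapped:
        def predict(self, Xq):
            return classes[predict(model, Xq)[0]]
        def predict_proba(self, Xq):
            return predict(model, Xq)[1]

    reports = ev.evaluate(_Wrapped(), X, y_true,
                          {"evaluation": np.arange(X.shape[0])})
    return {name: rep.to_dict() for name, rep in reports.items()}, y_true, y_pred
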