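"""End-to-end orchestration: simulate -> denoise -> normalize -> features ->
(tune) -> train -> evaluate, with a manifest of checksummed artifacts.

A :class:`PipelineConfig` enables individual stages; the stage order is
fixed.  Each run writes its artifacts (feature CSV, PSO trace, model
checkpoint, metric JSON, log) into a run directory together with
``run_manifest.csv`` listing every artifact with its SHA-256 checksum, so a
re-run with the same configuration and seed can be verified bit for bit on
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from typing import Dict, Optional

import numpy as np

from . import denoise as dn
from . import evaluation, features, mlcnn, phantoms, preprocess, pso

logger = logging.getLogger("lungcad")

STAGE_ORDER = ("simulate", "denoise", "redundancy", "normalize", "features",
               "tune", "train", "evaluate")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    stages: tuple = ("simulate", "normalize", "features", "train", "evaluate")
    n_samples: int = 60
    image_size: int = 32
    noise_sigma: float = 15.0
    redundancy_threshold: float = 0.05
    classifier_input: str = "features"  # features | images | fused
    cnn: mlcnn.CnnConfig = dataclasses.field(default_factory=mlcnn.CnnConfig)
    denoise_config: dn.DenoiseConfig = dataclasses.field(
        default_factory=dn.DenoiseConfig)
    tune_particles: int = 10
    tune_iterations: int = 10
    input_manifest: Optional[str] = None

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("no stages enabled")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _feature_matrix(samples, include_sensor: bool) -> np.ndarray:
    cfg = features.FeatureConfig(include_sensor=include_sensor)
    X = np.asarray([features.extract_feature_vector(s, cfg).to_array()
                    for s in samples])
    X = np.nan_to_num(X, nan=0.0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the enabled stages in order; returns a summary dict.

    Stage failures propagate with the failing stage named; artifacts written
    before the failure are retained in the run directory.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_path = os.path.join(config.out_dir, "log.txt")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    enabled = [s for s in STAGE_ORDER if s in config.stages]
    artifacts: list[str] = []
    summary: Dict[str, object] = {"stages": enabled}
    samples = None
    best_params = None
    try:
        for stage in enabled:
            t0 = time.perf_counter()
            try:
                if stage == "simulate":
                    samples = phantoms.separable_dataset(
                        config.n_samples, image_size=config.image_size,
                        noise_sigma=config.noise_sigma, seed=config.seed)
                elif stage == "denoise":
                    for s in samples:
                        s.image = dn.denoise_volume(s.image,
                                                    config.denoise_config)
                elif stage == "redundancy":
                    frames = [s.image for s in samples]
                    kept = preprocess.eliminate_redundant_frames(
                        frames, config.redundancy_threshold)
                    samples = [samples[i] for i in kept]
                    summary["kept_frames"] = kept
                elif stage == "normalize":
                    for s in samples:
                        s.image = preprocess.zscore_normalize(s.image)
                elif stage == "features":
                    df = features.feature_table(samples)
                    path = os.path.join(config.out_dir, "features.csv")
                    df.to_csv(path, index=False)
                    artifacts.append(path)
                elif stage == "tune":
                    X, y, sensors = _classifier_inputs(samples, config)
                    split = mlcnn.split_dataset([s.label for s in samples],
                                                seed=config.seed)
                    tr, va = split.train_indices, split.test_indices
                    best_params, best_fit, trace = pso.optimize_hyperparameters(
                        pso.default_search_space(),
                        ([X[i] for i in tr], y[tr]),
                        ([X[i] for i in va], y[va]),
                        n_particles=config.tune_particles,
                        n_iterations=config.tune_iterations, seed=config.seed)
                    summary["tuned_params"] = best_params
                    summary["tuned_fitness"] = best_fit
                    import pandas as pd
                    path = os.path.join(config.out_dir, "trace.csv")
                    pd.DataFrame({"iteration": range(len(trace)),
                                  "gbest_fitness": trace}).to_csv(path,
                                                                  index=False)
                    artifacts.append(path)
                elif stage == "train":
                    X, y, sensors = _classifier_inputs(samples, config)
                    split = mlcnn.split_dataset([s.label for s in samples],
                                                seed=config.seed)
                    cnn_cfg = _tuned_cnn_config(config, best_params)
                    shape = np.asarray(X[0]).shape
                    sdim = len(sensors[0]) if sensors is not None else 0
                    model = mlcnn.build_model(cnn_cfg, shape, sensor_dim=sdim)
                    tr = split.train_indices
                    mlcnn.train_model(model, [X[i] for i in tr], y[tr],
                                      sensors=[sensors[i] for i in tr]
                                      if sensors is not None else None)
                    path = os.path.join(config.out_dir, "model.npz")
                    model.save(path)
                    artifacts.append(path)
                    summary["_model"] = model
                    summary["_split"] = split
                    summary["loss_history"] = model.loss_history
                elif stage == "evaluate":
                    model = summary.get("_model")
                    split = summary.get("_split")
                    if model is None:
                        raise RuntimeError("evaluate requires the train stage")
                    X, y, sensors = _classifier_inputs(samples, config)
                    classes = sorted({s.label for s in samples})
                    preds = []
                    for i in split.test_indices:
                        sv = sensors[i] if sensors is not None else None
                        p = mlcnn.predict(model, X[i], sensor=sv)
                        preds.append(classes[p.label_index])
                    truth = [samples[i].label for i in split.test_indices]
                    report = evaluation.evaluate_predictions(preds, truth)
                    path = os.path.join(config.out_dir, "metrics.json")
                    with open(path, "w") as fh:
                        fh.write(report.to_json())
                    artifacts.append(path)
                    summary["metrics"] = report.to_dict()
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.2fs", stage,
                        time.perf_counter() - t0)

        import pandas as pd
        manifest = pd.DataFrame([{"artifact": os.path.basename(p),
                                  "sha256": _sha256(p)} for p in artifacts])
        mpath = os.path.join(config.out_dir, "run_manifest.csv")
        manifest.to_csv(mpath, index=False)
        summary["artifacts"] = {os.path.basename(p): _sha256(p)
                                for p in artifacts}
    finally:
        logger.removeHandler(handler)
        handler.close()
    summary.pop("_model", None)
    summary.pop("_split", None)
    return summary


def _classifier_inputs(samples, config: PipelineConfig):
    labels = [s.label for s in samples]
    y, _ = mlcnn.encode_labels(labels)
    sensors = None
    if config.classifier_input == "features":
        X = list(_feature_matrix(samples, include_sensor=True))
    elif config.classifier_input == "images":
        X = [preprocess.zscore_normalize(s.image) for s in samples]
    elif config.classifier_input == "fused":
        X = [preprocess.zscore_normalize(s.image) for s in samples]
        if samples[0].sensor is not None:
            sensors = [np.asarray(s.sensor.values) for s in samples]
    else:
        raise ValueError("classifier_input must be features|images|fused")
    return X, y, sensors


def _tuned_cnn_config(config: PipelineConfig, best_params):
    if not best_params:
        return config.cnn
    f = int(best_params.get("filters", 8))
    hidden = int(best_params.get("hidden", 32))
    lr = 10.0 ** best_params["learning_rate"] \
        if "learning_rate" in best_params else config.cnn.learning_rate
    return dataclasses.replace(config.cnn, filters_per_layer=(f, 2 * f, 2 * f),
                               hidden_units=(hidden, max(hidden // 2, 2)),
                               learning_rate=lr)
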