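"""Compact multi-layer CNN classifier with manual backprop and Adam.

The network is the small stack the pipeline needs, not a general framework:
``n_conv_layers`` repetitions of (3x3 same-padding convolution, ReLU,
2x2 max-pool) followed by a flattening step, optional concatenation of the
per-sample sensor vector, and a fully-connected softmax output over the
classes.  Training is mini-batch (default batch size 1) gradient descent on
categorical cross-entropy with the Adam optimizer; everything is plain
NumPy, so a fixed seed gives bit-identical parameters, loss histories and
predictions.

A dense variant of the same depth handles 1-D feature-vector input (the
"features" path), so the classifier can consume raw image patches, extracted
feature vectors, or images fused with sensor data.

Prediction can optionally abstain: when the entropy (bits) of the predicted
class distribution exceeds a configured bound, the sample is flagged as
undecided rather than forced into a class.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CnnConfig",
    "DatasetSplit",
    "MLCNN",
    "split_dataset",
    "build_model",
    "train_model",
    "predict",
    "class_probability_components",
    "encode_labels",
]


@dataclasses.dataclass(frozen=True)
class CnnConfig:
    n_conv_layers: int = 3
    filters_per_layer: tuple = (8, 16, 16)
    kernel_size: int = 3
    pool_size: int = 2
    hidden_units: tuple = (32, 16)  # dense path only
    epochs: int = 5
    batch_size: int = 1
    learning_rate: float = 1e-3
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.filters_per_layer) < self.n_conv_layers:
            raise ValueError("filters_per_layer must cover n_conv_layers")


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int


def split_dataset(labels: Sequence, fraction: float = 0.8,
                  seed: int = 0) -> DatasetSplit:
    """Stratified train/test split; |train| = round(fraction * n).

    Per-class train counts are allocated by largest remainder so the overall
    count is exact; the within-class order is a seeded permutation.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    n_train = int(round(fraction * n))
    quota = fraction * counts
    floors = np.floor(quota).astype(int)
    remainder = n_train - floors.sum()
    order = np.argsort(-(quota - floors), kind="stable")
    take = floors.copy()
    for idx in order[:remainder]:
        take[idx] += 1
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, t in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        train.extend(idx[:t])
        test.extend(idx[t:])
    return DatasetSplit(train_indices=np.sort(np.asarray(train)),
                        test_indices=np.sort(np.asarray(test)),
                        fraction=fraction, seed=seed)


def encode_labels(labels: Sequence, classes: Optional[Sequence] = None):
    """Map class labels to integer indices; returns (indices, class list)."""
    if classes is None:
        classes = sorted(set(labels))
    lut = {c: i for i, c in enumerate(classes)}
    return np.asarray([lut[l] for l in labels]), list(classes)


def class_probability_components(labels: Sequence) -> Dict[object, float]:
    """Per-class prior probability components: count(class) / total."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    total = len(labels)
    out: Dict[object, float] = {}
    for l in labels:
        out[l] = out.get(l, 0) + 1
    return {k: v / total for k, v in out.items()}


# ---------------------------------------------------------------------------
# layers

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(c, h, w) -> (h*w, c*k*k) patch matrix for same-padding convolution."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    wins = sliding_window_view(xp, (k, k), axis=(1, 2))  # (c, h, w, k, k)
    return wins.transpose(1, 2, 0, 3, 4).reshape(h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    c, h, w = shape
    dxp = np.zeros((c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(h, w, c, k, k)
    for a in range(k):
        for b in range(k):
            dxp[:, a:a + h, b:b + w] += d[:, :, :, a, b].transpose(2, 0, 1)
    return dxp[:, pad:pad + h, pad:pad + w]


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


class MLCNN:
    """The trained/trainable model: parameters, config and loss history."""

    def __init__(self, config: CnnConfig, input_shape: tuple,
                 sensor_dim: int = 0):
        self.config = config
        self.input_shape = tuple(input_shape)
        self.sensor_dim = int(sensor_dim)
        self.mode = "image" if len(self.input_shape) == 2 else "features"
        self.loss_history: List[float] = []
        self._build()

    # -- construction -------------------------------------------------------
    def _build(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        if self.mode == "image":
            h, w = self.input_shape
            c_in = 1
            for i in range(cfg.n_conv_layers):
                if h < cfg.pool_size or w < cfg.pool_size:
                    raise ValueError("pooling would shrink below 1x1")
                if h % cfg.pool_size or w % cfg.pool_size:
                    raise ValueError("input size must be divisible by the "
                                     "pooling depth")
                f = cfg.filters_per_layer[i]
                fan_in = c_in * cfg.kernel_size ** 2
                self.weights.append(rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), size=(f, fan_in)))
                self.biases.append(np.zeros(f))
                c_in = f
                h //= cfg.pool_size
                w //= cfg.pool_size
            flat = c_in * h * w + self.sensor_dim
            self._flat_spatial = (c_in, h, w)
            self.weights.append(rng.normal(
                0.0, np.sqrt(2.0 / flat), size=(cfg.n_classes, flat)))
            self.biases.append(np.zeros(cfg.n_classes))
        else:
            d = self.input_shape[0] + self.sensor_dim
            dims = (d,) + tuple(cfg.hidden_units) + (cfg.n_classes,)
            for a, b in zip(dims[:-1], dims[1:]):
                self.weights.append(rng.normal(
                    0.0, np.sqrt(2.0 / a), size=(b, a)))
                self.biases.append(np.zeros(b))

    # -- forward / backward --------------------------------------------------
    def _forward(self, x: np.ndarray, sensor: Optional[np.ndarray]):
        cfg = self.config
        cache = {"acts": [], "cols": [], "masks": [], "argmax": []}
        if self.mode == "image":
            a = np.asarray(x, dtype=float)[None]  # (1, h, w)
            k, p = cfg.kernel_size, cfg.kernel_size // 2
            for i in range(cfg.n_conv_layers):
                cache["acts"].append(a)
                cols = _im2col(a, k, p)
                cache["cols"].append(cols)
                c, h, w = self.weights[i].shape[0], a.shape[1], a.shape[2]
                z = (cols @ self.weights[i].T + self.biases[i]
                     ).reshape(h, w, c).transpose(2, 0, 1)
                relu_mask = z > 0
                cache["masks"].append(relu_mask)
                z = z * relu_mask
                ps = cfg.pool_size
                zr = z.reshape(c, h // ps, ps, w // ps, ps)
                flat = zr.transpose(0, 1, 3, 2, 4).reshape(c, h // ps, w // ps,
                                                           ps * ps)
                arg = flat.argmax(axis=-1)
                cache["argmax"].append(arg)
                a = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
            feat = a.ravel()
        else:
            feat = np.asarray(x, dtype=float)
        if self.sensor_dim:
            if sensor is None:
                raise ValueError("model expects a sensor vector")
            feat = np.concatenate([feat, np.asarray(sensor, dtype=float)])
        cache["flat_in"] = feat
        if self.mode == "image":
            logits = self.weights[-1] @ feat + self.biases[-1]
            cache["dense_acts"] = []
        else:
            acts = []
            a = feat
            for i in range(len(self.weights) - 1):
                acts.append(a)
                a = self.weights[i] @ a + self.biases[i]
                a = np.maximum(a, 0.0)
            acts.append(a)
            cache["dense_acts"] = acts
            logits = self.weights[-1] @ a + self.biases[-1]
        return logits, cache

    def _backward(self, cache, dlogits: np.ndarray):
        cfg = self.config
        gW = [np.zeros_like(w) for w in self.weights]
        gb = [np.zeros_like(b) for b in self.biases]
        if self.mode == "image":
            feat = cache["flat_in"]
            gW[-1] = np.outer(dlogits, feat)
            gb[-1] = dlogits
            dfeat = self.weights[-1].T @ dlogits
            if self.sensor_dim:
                dfeat = dfeat[:-self.sensor_dim]
            da = dfeat.reshape(self._flat_spatial)
            ps, k, p = cfg.pool_size, cfg.kernel_size, cfg.kernel_size // 2
            for i in range(cfg.n_conv_layers - 1, -1, -1):
                c, hp, wp = da.shape
                h, w = hp * ps, wp * ps
                dflat = np.zeros((c, hp, wp, ps * ps))
                np.put_along_axis(dflat, cache["argmax"][i][..., None],
                                  da[..., None], axis=-1)
                dz = dflat.reshape(c, hp, wp, ps, ps).transpose(0, 1, 3, 2, 4
                                                                ).reshape(c, h, w)
                dz = dz * cache["masks"][i]
                dz_flat = dz.transpose(1, 2, 0).reshape(h * w, c)
                gW[i] = dz_flat.T @ cache["cols"][i]
                gb[i] = dz_flat.sum(axis=0)
                dcols = dz_flat @ self.weights[i]
                da = _col2im(dcols, cache["acts"][i].shape, k, p)
        else:
            acts = cache["dense_acts"]
            d = dlogits
            gW[-1] = np.outer(d, acts[-1])
            gb[-1] = d
            d = self.weights[-1].T @ d
            for i in range(len(self.weights) - 2, -1, -1):
                d = d * (acts[i + 1] > 0) if i + 1 < len(acts) else d
                gW[i] = np.outer(d, acts[i])
                gb[i] = d
                d = self.weights[i].T @ d
        return gW, gb

    def loss_and_grads(self, x, y_index: int, sensor=None):
        logits, cache = self._forward(x, sensor)
        probs = _softmax(logits)
        loss = -float(np.log(max(probs[y_index], 1e-300)))
        dlogits = probs.copy()
        dlogits[y_index] -= 1.0
        gW, gb = self._backward(cache, dlogits)
        return loss, gW, gb

    def predict_proba(self, x, sensor=None) -> np.ndarray:
        logits, _ = self._forward(x, sensor)
        return _softmax(logits)

    # -- serialization -------------------------------------------------------
    def save(self, path: str):
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        meta = {"config": dataclasses.asdict(self.config),
                "input_shape": self.input_shape,
                "sensor_dim": self.sensor_dim,
                "loss_history": self.loss_history}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "MLCNN":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        cfg_dict = meta["config"]
        for key in ("filters_per_layer", "hidden_units"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = cls(CnnConfig(**cfg_dict), tuple(meta["input_shape"]),
                    meta["sensor_dim"])
        model.weights = [data[f"W{i}"] for i in range(len(model.weights))]
        model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        model.loss_history = list(meta["loss_history"])
        return model


def build_model(config: CnnConfig, input_shape: tuple,
                sensor_dim: int = 0) -> MLCNN:
    """Untrained model with seeded parameter initialization."""
    return MLCNN(config, input_shape, sensor_dim)


def train_model(model: MLCNN, X: Sequence, y: Sequence[int],
                config: Optional[CnnConfig] = None,
                sensors: Optional[Sequence] = None) -> MLCNN:
    """Adam training on cross-entropy; records the mean loss per epoch.

    ``X`` is a sequence of images (2-D arrays) or feature vectors, ``y``
    integer class indices.  Deterministic for a fixed config seed.
    """
    cfg = config or model.config
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed + 1)
    mW = [np.zeros_like(w) for w in model.weights]
    vW = [np.zeros_like(w) for w in model.weights]
    mb = [np.zeros_like(b) for b in model.biases]
    vb = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            gW_acc = [np.zeros_like(w) for w in model.weights]
            gb_acc = [np.zeros_like(b) for b in model.biases]
            for idx in batch:
                sensor = sensors[idx] if sensors is not None else None
                loss, gW, gb = model.loss_and_grads(X[idx], int(y[idx]), sensor)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, sample {idx}")
                losses.append(loss)
                for i in range(len(gW_acc)):
                    gW_acc[i] += gW[i] / len(batch)
                    gb_acc[i] += gb[i] / len(batch)
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2 ** t) / (1 - beta1 ** t)
            for i in range(len(model.weights)):
                mW[i] = beta1 * mW[i] + (1 - beta1) * gW_acc[i]
                vW[i] = beta2 * vW[i] + (1 - beta2) * gW_acc[i] ** 2
                model.weights[i] -= lr_t * mW[i] / (np.sqrt(vW[i]) + eps)
                mb[i] = beta1 * mb[i] + (1 - beta1) * gb_acc[i]
                vb[i] = beta2 * vb[i] + (1 - beta2) * gb_acc[i] ** 2
                model.biases[i] -= lr_t * mb[i] / (np.sqrt(vb[i]) + eps)
        model.loss_history.append(float(np.mean(losses)))
    return model


@dataclasses.dataclass(frozen=True)
class Prediction:
    probs: np.ndarray
    label_index: int
    abstained: bool


def predict(model: MLCNN, x, sensor=None,
            entropy_threshold_bits: Optional[float] = None) -> Prediction:
    """Class probabilities and argmax label, with optional entropy abstention."""
    probs = model.predict_proba(x, sensor)
    nz = probs[probs > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    abstain = (entropy_threshold_bits is not None
               and entropy > entropy_threshold_bits)
    return Prediction(probs=probs, label_index=int(np.argmax(probs)),
                      abstained=abstain)
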