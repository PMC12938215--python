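"""8-class station classifier: patient-wise splitting, augmentation, training.

The training recipe mirrors the transfer-learning setup of the station
classification task: categorical cross-entropy, AdamW, dropout 0.5 on the
globally averaged features, early stopping on validation loss with a
patience window, and the checkpoint with the lowest validation loss kept.
Two backbones are supported: ``small`` — a compact trainable convnet whose
final conv map is exactly 7x7 (the desk-scale default) — and ``frozen`` —
the same architecture with fixed random convolutional filters acting as a
feature extractor, only the head training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from usgrad_audit._nn import AdamW, SmallConvNet, softmax
from usgrad_audit.phantom import STATIONS

CLASS_ORDER = STATIONS


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    patience: int = 20
    dropout_rate: float = 0.5
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    n_classes: int = 8
    input_size: int = 224
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")
        if self.n_classes != 8:
            raise ValueError("the station task has exactly 8 classes")


@dataclass
class DatasetSplit:
    train: list[str]
    val: list[str]
    test: list[str]
    patient_assignment: dict[str, str]  # patient_id -> partition name

    def partition_of(self, patient_id: str) -> str:
        return self.patient_assignment[patient_id]


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Allot n units to partitions by largest remainder (ties: earlier wins).

    Every partition with a positive fraction receives at least one unit
    (provided n allows it), so small cohorts still yield a usable split.
    """
    exact = [n * f for f in fractions]
    base = [math.floor(e) for e in exact]
    leftover = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    for i, f in enumerate(fractions):
        if f > 0 and base[i] == 0:
            donor = max(range(len(base)), key=lambda j: base[j])
            base[donor] -= 1
            base[i] += 1
    return base


def split_patientwise(manifest: pd.DataFrame, fractions=(0.70, 0.20, 0.10),
                      seed: int = 0) -> DatasetSplit:
    """Partition frames into train/val/test so no patient spans partitions.

    Patients are shuffled with `seed`, then allotted to partitions by
    largest remainder on patient counts.
    """
    patients = sorted(manifest["patient_id"].unique())
    n_nonempty = sum(1 for f in fractions if f > 0)
    if len(patients) < n_nonempty:
        raise ValueError(
            f"{len(patients)} patients cannot fill {n_nonempty} non-empty partitions"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(patients))
    counts = _largest_remainder(len(patients), fractions)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    idx = 0
    for name, k in zip(names, counts):
        for p in shuffled[idx:idx + k]:
            assignment[p] = name
        idx += k
    parts: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for _, row in manifest.iterrows():
        parts[assignment[row["patient_id"]]].append(row["image"])
    return DatasetSplit(train=parts["train"], val=parts["val"], test=parts["test"],
                        patient_assignment=assignment)


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentConfig:
    """Five stochastic transforms, each applied independently with `prob`.

    Magnitudes are package defaults (overridable); the underlying recipe
    names the transforms only.
    """

    gamma_prob: float = 0.5
    gamma_range: tuple[float, float] = (0.7, 1.5)
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    rotation_prob: float = 0.5
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    contrast_prob: float = 0.5
    contrast_range: tuple[float, float] = (0.8, 1.2)
    shadow_prob: float = 0.5
    shadow_depth_range: tuple[float, float] = (0.3, 0.7)


def augment_image(image: np.ndarray, rng: np.random.Generator,
                  params: AugmentConfig = AugmentConfig()) -> np.ndarray:
    """Gamma, blur, rotation, contrast scaling and a Gaussian shadow band.

    Output is clamped to [0, 1] and keeps the input shape. Degenerate
    parameters (probability 0, or identity magnitudes) reduce to identity.
    """
    img = np.asarray(image, dtype=np.float64)
    if rng.uniform() < params.gamma_prob:
        gamma = rng.uniform(*params.gamma_range)
        img = np.clip(img, 0.0, 1.0) ** gamma
    if rng.uniform() < params.blur_prob:
        sigma = rng.uniform(*params.blur_sigma_range)
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma)
    if rng.uniform() < params.rotation_prob:
        angle = rng.uniform(*params.rotation_range)
        if angle != 0.0:
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
    if rng.uniform() < params.contrast_prob:
        scale = rng.uniform(*params.contrast_range)
        mean = img.mean()
        img = mean + scale * (img - mean)
    if rng.uniform() < params.shadow_prob:
        depth = rng.uniform(*params.shadow_depth_range)
        w = img.shape[1]
        center = rng.uniform(0, w)
        sigma = rng.uniform(0.10, 0.30) * w
        profile = 1.0 - depth * np.exp(-0.5 * ((np.arange(w) - center) / sigma) ** 2)
        img = img * profile[None, :]
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# model wrapper

def resize_image(image: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize of a 2-D array to (out_size, out_size)."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    h, w = img.shape
    if (h, w) == (out_size, out_size):
        return img.copy()
    rows = np.linspace(0, h - 1, out_size)
    cols = np.linspace(0, w - 1, out_size)
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, grid, order=1, mode="nearest")


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi > lo:
        return (img - lo) / (hi - lo)
    return np.zeros_like(img)


@dataclass
class TrainedModel:
    """Predictor exposing class probabilities plus the designated conv layer.

    The feature map of the last convolution (post-ReLU, 7x7 spatial) and
    the gradient of any pre-softmax class score with respect to it are the
    hooks the Grad-CAM module needs.
    """

    net: SmallConvNet
    class_order: tuple[str, ...] = CLASS_ORDER
    input_size: int = 224
    selected_epoch: int = 0
    backbone: str = "small"

    @property
    def feature_hw(self) -> int:
        return SmallConvNet.FEATURE_HW

    def _prepare(self, image: np.ndarray) -> np.ndarray:
        img = _normalize(resize_image(image, SmallConvNet.INPUT_SIZE))
        return img[None, None, :, :]

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Length-8 probability vector over `class_order` (sums to 1)."""
        scores = self.net.forward(self._prepare(image))
        return softmax(scores)[0]

    def predict_proba_batch(self, images: Sequence[np.ndarray]) -> np.ndarray:
        x = np.stack([self._prepare(im)[0] for im in images])
        return softmax(self.net.forward(x))

    def predict(self, image: np.ndarray) -> str:
        return self.class_order[int(np.argmax(self.predict_proba(image)))]

    # Grad-CAM hooks -------------------------------------------------------

    def feature_map(self, image: np.ndarray) -> np.ndarray:
        """(C, 7, 7) post-ReLU feature map of the designated layer."""
        return self.net.features(self._prepare(image))[0]

    def class_score(self, features: np.ndarray, class_idx: int) -> float:
        """Pre-softmax score of one class from a feature map (C,H,W)."""
        return float(self.net.head_scores(features[None])[0, class_idx])

    def feature_gradient(self, features: np.ndarray, class_idx: int) -> np.ndarray:
        """Analytic d(score)/d(feature map), same shape as `features`."""
        return self.net.score_feature_gradient(features, class_idx)


# ---------------------------------------------------------------------------
# checkpoint serialization

def save_model(model: TrainedModel, out_dir) -> None:
    """Write weights (npz) plus a JSON sidecar with the model contract."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **model.net.get_weights())
    (out / "model.json").write_text(json.dumps({
        "class_order": list(model.class_order),
        "input_size": model.input_size,
        "feature_layer": "conv3",
        "feature_hw": model.feature_hw,
        "selected_epoch": model.selected_epoch,
        "backbone": model.backbone,
        "dropout_rate": model.net.dropout_rate,
    }, indent=1))


def load_model(model_dir) -> TrainedModel:
    import json
    from pathlib import Path

    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    weights = dict(np.load(d / "weights.npz"))
    channels = (weights["conv1.W"].shape[0], weights["conv2.W"].shape[0],
                weights["conv3.W"].shape[0])
    net = SmallConvNet(len(meta["class_order"]), np.random.default_rng(0),
                       dropout_rate=meta["dropout_rate"], channels=channels,
                       trainable_backbone=(meta["backbone"] == "small"))
    net.set_weights(weights)
    return TrainedModel(net=net, class_order=tuple(meta["class_order"]),
                        input_size=meta["input_size"],
                        selected_epoch=meta["selected_epoch"],
                        backbone=meta["backbone"])


# ---------------------------------------------------------------------------
# early stopping

def stopping_point(val_losses: Sequence[float], patience: int) -> tuple[int, int]:
    """(selected_epoch, stop_epoch), both 1-based, for a validation-loss trace.

    Training selects the epoch with the minimum loss (ties broken by the
    earliest epoch) and halts once `patience` consecutive epochs pass
    without strict improvement. The trace is scanned incrementally, exactly
    as the live loop experiences it.
    """
    best = math.inf
    best_epoch = 0
    since = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best, best_epoch, since = loss, epoch, 0
        else:
            since += 1
        if since >= patience:
            return best_epoch, epoch
    return best_epoch, len(val_losses)


# ---------------------------------------------------------------------------
# training

def _eval_net(net: SmallConvNet, x: np.ndarray, y: np.ndarray,
              batch: int = 64) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        scores = net.forward(x[i:i + batch])
        probs = softmax(scores)
        yb = y[i:i + batch]
        losses.append(-np.log(np.clip(probs[np.arange(len(yb)), yb], 1e-12, None)).sum())
        correct += int((np.argmax(probs, axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_model(split: DatasetSplit, config: TrainConfig, backbone: str = "small", *,
                images: Mapping[str, np.ndarray], labels: Mapping[str, str],
                augment: Optional[AugmentConfig] = AugmentConfig(),
                ) -> tuple[TrainedModel, pd.DataFrame]:
    """Train on the split's train partition, early-stop on validation loss.

    Returns the checkpoint from the epoch with minimum validation loss and
    a per-epoch history (loss/accuracy/precision/recall for train and val;
    precision and recall are micro-averaged, which for single-label
    multiclass prediction coincide with accuracy).
    """
    if backbone not in ("small", "frozen"):
        raise ValueError("backbone must be 'small' or 'frozen'")
    if not split.train:
        raise ValueError("training partition is empty")
    class_index = {c: i for i, c in enumerate(CLASS_ORDER)}
    rng = np.random.default_rng(config.seed)

    def stack(ids, normalize=True):
        xs = np.stack([
            _normalize(resize_image(images[i], SmallConvNet.INPUT_SIZE))
            for i in ids
        ])
        return xs[:, None, :, :], np.array([class_index[labels[i]] for i in ids])

    x_val, y_val = stack(split.val) if split.val else (None, None)

    net = SmallConvNet(config.n_classes, rng, dropout_rate=config.dropout_rate,
                       trainable_backbone=(backbone == "small"))
    opt = AdamW(lr=config.learning_rate, weight_decay=config.weight_decay)

    train_ids = list(split.train)
    history_rows = []
    val_losses: list[float] = []
    best_loss, best_epoch, best_weights, since = math.inf, 0, None, 0

    for epoch in range(1, config.epochs + 1):
        # cosine decay from the configured rate to a tenth of it
        opt.lr = config.learning_rate * (0.55 + 0.45 * math.cos(
            math.pi * (epoch - 1) / max(config.epochs - 1, 1)))
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch_ids = [train_ids[k] for k in order[start:start + config.batch_size]]
            xs = []
            for i in batch_ids:
                img = images[i]
                if augment is not None:
                    img = augment_image(img, rng, augment)
                xs.append(_normalize(resize_image(img, SmallConvNet.INPUT_SIZE)))
            xb = np.stack(xs)[:, None, :, :]
            yb = np.array([class_index[labels[i]] for i in batch_ids])
            epoch_losses.append(net.train_step(xb, yb, opt, rng))

        x_tr, y_tr = stack(train_ids)
        tr_loss, tr_acc = _eval_net(net, x_tr, y_tr)
        history_rows.append({"epoch": epoch, "split": "train", "loss": tr_loss,
                             "accuracy": tr_acc, "precision": tr_acc, "recall": tr_acc})
        if x_val is not None:
            va_loss, va_acc = _eval_net(net, x_val, y_val)
        else:
            va_loss, va_acc = tr_loss, tr_acc
        history_rows.append({"epoch": epoch, "split": "val", "loss": va_loss,
                             "accuracy": va_acc, "precision": va_acc, "recall": va_acc})
        val_losses.append(va_loss)

        if va_loss < best_loss:
            best_loss, best_epoch, since = va_loss, epoch, 0
            best_weights = net.get_weights()
        else:
            since += 1
        if since >= config.patience:
            break

    net.set_weights(best_weights)
    model = TrainedModel(net=net, class_order=CLASS_ORDER, input_size=config.input_size,
                         selected_epoch=best_epoch, backbone=backbone)
    return model, pd.DataFrame(history_rows)
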