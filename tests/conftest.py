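"""Shared fixtures: tiny phantom datasets, toy Grad-CAM models, and one
session-scoped end-to-end audit run reused by the acceptance checks."""

from __future__ import annotations

import numpy as np
import pytest

from usgrad_audit.io import RunConfig, TrainSection
from usgrad_audit.phantom import PhantomConfig, generate_dataset
from usgrad_audit.pipeline import run_pipeline


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 patients x 16 frames at 64 px — enough for schema/consensus tests."""
    cfg = PhantomConfig(image_size=64, n_patients=3, frames_per_patient=16, seed=123)
    frames, manifest = generate_dataset(cfg)
    return cfg, frames, manifest


@pytest.fixture(scope="session")
def audit_run(tmp_path_factory):
    """One full pipeline run at the end-to-end study scale (10 patients x 40
    frames, 64 px, small trainable backbone, 20 epochs) on the easy
    template configuration."""
    out = tmp_path_factory.mktemp("audit")
    cfg = RunConfig(
        phantom=PhantomConfig.easy(image_size=64, n_patients=10, frames_per_patient=40),
        train=TrainSection(epochs=20),
        seed=20260928,
        out_dir=str(out),
    )
    report = run_pipeline(cfg)
    return cfg, report, out


class LinearToyModel:
    """Single-channel model whose class score is the mean of its feature map.

    The feature map is the image itself (plus a positive offset), so the
    normalized Grad-CAM grid must equal featuremap / max(featuremap).
    """

    class_order = ("a", "b")

    def __init__(self, offset: float = 0.1):
        self.offset = offset

    def feature_map(self, image):
        return np.asarray(image, dtype=float)[None, :, :] + self.offset

    def class_score(self, features, class_idx):
        sign = 1.0 if class_idx == 0 else -1.0
        return float(sign * features.mean())

    def feature_gradient(self, features, class_idx):
        sign = 1.0 if class_idx == 0 else -1.0
        return np.full_like(features, sign / features.size)

    def predict_proba(self, image):
        f = self.feature_map(image)
        s = np.array([self.class_score(f, 0), self.class_score(f, 1)])
        e = np.exp(s - s.max())
        return e / e.sum()


class TanhHeadToyModel:
    """Three-stage toy network: fixed conv -> ReLU -> tanh-weighted head.

    Nonlinear in the feature map, so finite differences of the class score
    are a genuinely independent check of the analytic gradient.
    """

    class_order = ("a", "b", "c")

    def __init__(self, n_channels: int = 4, grid: int = 7, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.kernels = rng.normal(size=(n_channels, 3, 3))
        self.W = rng.normal(size=(len(self.class_order), n_channels))
        self.grid = grid

    def feature_map(self, image):
        from scipy import ndimage

        from usgrad_audit.classifier import resize_image

        img = resize_image(np.asarray(image, dtype=float), self.grid)
        feats = np.stack([ndimage.convolve(img, k, mode="constant") for k in self.kernels])
        return np.maximum(feats, 0.0)

    def class_score(self, features, class_idx):
        per_channel = np.tanh(features).mean(axis=(1, 2))
        return float(self.W[class_idx] @ per_channel)

    def feature_gradient(self, features, class_idx):
        c, h, w = features.shape
        return (self.W[class_idx][:, None, None] / (h * w)) * (1.0 - np.tanh(features) ** 2)

    def predict_proba(self, image):
        f = self.feature_map(image)
        s = np.array([self.class_score(f, i) for i in range(len(self.class_order))])
        e = np.exp(s - s.max())
        return e / e.sum()


def finite_difference_gradient(model, features, class_idx, eps=1e-5):
    """Central finite differences of the class score w.r.t. the feature map."""
    g = np.zeros_like(features)
    it = np.nditer(features, flags=["multi_index"])
    f = features.copy()
    while not it.finished:
        idx = it.multi_index
        orig = f[idx]
        f[idx] = orig + eps
        hi = model.class_score(f, class_idx)
        f[idx] = orig - eps
        lo = model.class_score(f, class_idx)
        f[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


@pytest.fixture
def linear_toy_model():
    return LinearToyModel()


@pytest.fixture
def tanh_toy_model():
    return TanhHeadToyModel()
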