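"""Grad-CAM on the designated convolutional layer, reduced to a 7x7 grid.

The saliency map is the classic construction: channel weights are the
spatial averages of the gradient of the pre-softmax class score with
respect to the layer's feature map; the weighted channel sum is rectified
(ReLU), resampled to 7x7 if the native layer is not already 7x7, and
divided by its maximum so the top cell is exactly 1.0. The activation
region is the set of grid cells at or above a threshold (default 0.9) and
the max-intensity cell is the single highest cell; because of the
normalization, every non-degenerate grid has at least one cell above any
threshold <= 1. An all-nonpositive pre-ReLU map is reported as degenerate
rather than normalized (no division by zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from usgrad_audit.classifier import resize_image

GRID_SIZE = 7


@dataclass
class ActivationGrid:
    values: np.ndarray           # (7, 7) floats in [0, 1]
    degenerate: bool
    target_class: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {self.values.shape}")


@dataclass
class ActivationRegion:
    cells: frozenset            # {(row, col)} with value >= threshold
    max_cell: Optional[tuple[int, int]]
    threshold: float = 0.9

    @property
    def empty(self) -> bool:
        return len(self.cells) == 0


def compute_cam(model, image: np.ndarray, target_class: Optional[int] = None) -> ActivationGrid:
    """Grad-CAM grid for `image`, targeting the predicted class by default.

    `model` must expose ``feature_map(image) -> (C,H,W)``,
    ``feature_gradient(features, class_idx) -> (C,H,W)`` and, for default
    targeting, ``predict_proba(image)``.
    """
    n_classes = len(getattr(model, "class_order", range(8)))
    if target_class is not None and not (0 <= target_class < n_classes):
        raise ValueError(f"target_class must lie in [0, {n_classes}), got {target_class}")
    features = model.feature_map(image)
    if target_class is None:
        target_class = int(np.argmax(model.predict_proba(image)))

    grads = model.feature_gradient(features, target_class)
    weights = grads.mean(axis=(1, 2))                      # alpha_k
    cam = np.einsum("c,chw->hw", weights, features)
    cam = np.maximum(cam, 0.0)                             # ReLU

    if cam.max() <= 0.0:
        return ActivationGrid(values=np.zeros((GRID_SIZE, GRID_SIZE)),
                              degenerate=True, target_class=target_class)
    if cam.shape != (GRID_SIZE, GRID_SIZE):
        cam = np.maximum(resize_image(cam, GRID_SIZE), 0.0)
    cam = cam / cam.max()
    return ActivationGrid(values=cam, degenerate=False, target_class=target_class)


def extract_region(grid: ActivationGrid, threshold: float = 0.9) -> ActivationRegion:
    """All cells with value >= threshold (inclusive), plus the max cell.

    Cells form a single collective region regardless of contiguity. The max
    cell breaks ties by the smallest row-major index. A degenerate grid
    yields an empty region (callers route these to 'not interpretable').
    """
    if grid.degenerate:
        return ActivationRegion(cells=frozenset(), max_cell=None, threshold=threshold)
    v = grid.values
    rows, cols = np.where(v >= threshold)
    cells = frozenset(zip(rows.tolist(), cols.tolist()))
    flat = int(np.argmax(v))                                # first max, row-major
    max_cell = (flat // GRID_SIZE, flat % GRID_SIZE)
    return ActivationRegion(cells=cells, max_cell=max_cell, threshold=threshold)


# ---------------------------------------------------------------------------
# rendering

_RED = np.array([0.85, 0.10, 0.10])
_GREEN = np.array([0.10, 0.75, 0.20])


def _heat_color(v: np.ndarray) -> np.ndarray:
    """Simple blue->red heat ramp for values in [0,1], shape (...,3)."""
    r = np.clip(1.5 * v - 0.25, 0, 1)
    g = np.clip(1.0 - np.abs(2 * v - 1.0), 0, 1)
    b = np.clip(1.0 - 1.5 * v, 0, 1)
    return np.stack([r, g, b], axis=-1)


def render_overlay(image: np.ndarray, region: ActivationRegion,
                   grid: ActivationGrid) -> np.ndarray:
    """RGB overlay: heat ramp + grid lines, region cells green, max cell red.

    The image is padded on the bottom/right to a multiple of 7 when needed;
    output is uint8 with shape (H', W', 3).
    """
    img = np.clip(np.asarray(image, dtype=np.float64), 0, 1)
    h, w = img.shape
    ph = (-h) % GRID_SIZE
    pw = (-w) % GRID_SIZE
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
        h, w = img.shape
    rgb = np.repeat(img[:, :, None], 3, axis=2)
    ch, cw = h // GRID_SIZE, w // GRID_SIZE

    if not grid.degenerate:
        heat = _heat_color(np.kron(grid.values, np.ones((ch, cw))))
        rgb = 0.75 * rgb + 0.25 * heat
        for (r, c) in region.cells:
            tint = _RED if (r, c) == region.max_cell else _GREEN
            sl = (slice(r * ch, (r + 1) * ch), slice(c * cw, (c + 1) * cw))
            rgb[sl] = 0.60 * rgb[sl] + 0.40 * tint

    # grid lines
    for k in range(GRID_SIZE + 1):
        rr = min(k * ch, h - 1)
        cc = min(k * cw, w - 1)
        rgb[rr, :] = 0.25
        rgb[:, cc] = 0.25
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)
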