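"""Minimal convolutional-network primitives (numpy, im2col).

Just enough machinery for the desk-scale station classifier: strided 2-D
convolutions with explicit backprop, ReLU, global average pooling, inverted
dropout, a dense head, softmax cross-entropy, and AdamW. Images are small
(56 x 56) and batches modest, so im2col with einsum is fast enough on one
CPU core.
"""

from __future__ import annotations

import numpy as np


def _conv_out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    oh = _conv_out_size(h, kh, stride, pad)
    ow = _conv_out_size(w, kw, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    col = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return col.reshape(n, c * kh * kw, oh * ow)


def _col2im(dcol: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh = _conv_out_size(h, kh, stride, pad)
    ow = _conv_out_size(w, kw, stride, pad)
    dcol = dcol.reshape(n, c, kh, kw, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcol[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Conv2D:
    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int,
                 pad: int, rng: np.random.Generator):
        fan_in = in_ch * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        cols = _im2col(x, self.ksize, self.ksize, self.stride, self.pad)
        wf = self.W.reshape(self.W.shape[0], -1)
        out = np.einsum("fk,nkp->nfp", wf, cols) + self.b[None, :, None]
        oh = _conv_out_size(x.shape[2], self.ksize, self.stride, self.pad)
        ow = _conv_out_size(x.shape[3], self.ksize, self.stride, self.pad)
        self._cache = (x.shape, cols)
        return out.reshape(n, -1, oh, ow)

    def backward(self, dout: np.ndarray):
        x_shape, cols = self._cache
        n, f = dout.shape[:2]
        d2 = dout.reshape(n, f, -1)
        self.dW = np.einsum("nfp,nkp->fk", d2, cols).reshape(self.W.shape)
        self.db = d2.sum(axis=(0, 2))
        wf = self.W.reshape(f, -1)
        dcols = np.einsum("fk,nfp->nkp", wf, d2)
        return _col2im(dcols, x_shape, self.ksize, self.ksize, self.stride, self.pad)

    def params(self):
        return [("W", self), ("b", self)]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class BatchNorm2D:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        """params: list of (value, gradient) pairs; values updated in place."""
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(params):
            if i not in self.state:
                self.state[i] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[i]
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


class SmallConvNet:
    """Three strided conv+BN+ReLU blocks -> 7x7 feature map -> GAP -> dropout -> dense.

    The classification head mirrors the transfer-learning head used for the
    station task (global average pooling, dropout 0.5, dense softmax over 8
    units); the designated Grad-CAM layer is the post-ReLU output of the
    last convolution, whose spatial size is exactly 7 x 7 for 56 x 56 input.
    Batch normalization before each ReLU keeps the short desk-scale
    training runs stable.
    """

    INPUT_SIZE = 56
    FEATURE_HW = 7

    def __init__(self, n_classes: int, rng: np.random.Generator,
                 dropout_rate: float = 0.5, channels=(16, 32, 64),
                 trainable_backbone: bool = True):
        c1, c2, c3 = channels
        self.conv1 = Conv2D(1, c1, 5, stride=2, pad=2, rng=rng)
        self.conv2 = Conv2D(c1, c2, 3, stride=2, pad=1, rng=rng)
        self.conv3 = Conv2D(c2, c3, 3, stride=2, pad=1, rng=rng)
        self.bn1 = BatchNorm2D(c1)
        self.bn2 = BatchNorm2D(c2)
        self.bn3 = BatchNorm2D(c3)
        self.W_head = rng.normal(0.0, np.sqrt(1.0 / c3), size=(n_classes, c3))
        self.b_head = np.zeros(n_classes)
        self.dropout_rate = dropout_rate
        self.n_classes = n_classes
        self.n_features = c3
        self.trainable_backbone = trainable_backbone

    # -- forward -----------------------------------------------------------

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N,1,56,56) -> post-ReLU feature map (N,C,7,7).

        Inputs arrive min-max normalized to [0,1]; the first layer sees them
        centered at zero for conditioning. Each convolution is batch
        normalized before its ReLU.
        """
        a1 = relu(self.bn1.forward(self.conv1.forward(x - 0.5), train))
        a2 = relu(self.bn2.forward(self.conv2.forward(a1), train))
        a3 = relu(self.bn3.forward(self.conv3.forward(a2), train))
        self._acts = (x, a1, a2, a3)
        return a3

    def head_scores(self, feats: np.ndarray) -> np.ndarray:
        """Pre-softmax class scores from a feature map (N,C,H,W)."""
        gap = feats.mean(axis=(2, 3))
        return gap @ self.W_head.T + self.b_head

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head_scores(self.features(x))

    # -- analytic feature-map gradient for Grad-CAM -------------------------

    def score_feature_gradient(self, feats: np.ndarray, class_idx: int) -> np.ndarray:
        """d(pre-softmax score of class)/d(feature map), shape (C,H,W).

        The head is linear in the globally averaged features, so the
        gradient is the head weight of each channel spread uniformly over
        the H*W spatial positions.
        """
        c, h, w = feats.shape
        g = np.repeat(self.W_head[class_idx] / (h * w), h * w).reshape(c, h, w)
        return g

    # -- training ----------------------------------------------------------

    def train_step(self, x: np.ndarray, y: np.ndarray, optimizer: AdamW,
                   rng: np.random.Generator) -> float:
        n = x.shape[0]
        feats = self.features(x, train=True)
        gap = feats.mean(axis=(2, 3))
        if self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(gap.shape) < keep) / keep
        else:
            mask = np.ones_like(gap)
        gap_d = gap * mask
        logits = gap_d @ self.W_head.T + self.b_head
        probs = softmax(logits)
        loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        dW_head = dlogits.T @ gap_d
        db_head = dlogits.sum(axis=0)
        params = [(self.W_head, dW_head), (self.b_head, db_head)]

        if self.trainable_backbone:
            dgap = (dlogits @ self.W_head) * mask
            c, h, w = feats.shape[1:]
            dfeats = np.repeat(dgap[:, :, None] / (h * w), h * w, axis=2).reshape(feats.shape)
            _, a1, a2, a3 = self._acts
            d3 = self.bn3.backward(dfeats * (a3 > 0))
            d2 = self.bn2.backward(self.conv3.backward(d3) * (a2 > 0))
            d1 = self.bn1.backward(self.conv2.backward(d2) * (a1 > 0))
            self.conv1.backward(d1)
            for conv, bn in [(self.conv3, self.bn3), (self.conv2, self.bn2),
                             (self.conv1, self.bn1)]:
                params += [(conv.W, conv.dW), (conv.b, conv.db),
                           (bn.gamma, bn.dgamma), (bn.beta, bn.dbeta)]

        optimizer.step(params)
        return float(loss)

    # -- checkpointing -----------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {"W_head": self.W_head.copy(), "b_head": self.b_head.copy()}
        for i, (conv, bn) in enumerate([(self.conv1, self.bn1), (self.conv2, self.bn2),
                                        (self.conv3, self.bn3)], start=1):
            out[f"conv{i}.W"] = conv.W.copy()
            out[f"conv{i}.b"] = conv.b.copy()
            out[f"bn{i}.gamma"] = bn.gamma.copy()
            out[f"bn{i}.beta"] = bn.beta.copy()
            out[f"bn{i}.mean"] = bn.running_mean.copy()
            out[f"bn{i}.var"] = bn.running_var.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.W_head[:] = weights["W_head"]
        self.b_head[:] = weights["b_head"]
        for i, (conv, bn) in enumerate([(self.conv1, self.bn1), (self.conv2, self.bn2),
                                        (self.conv3, self.bn3)], start=1):
            conv.W[:] = weights[f"conv{i}.W"]
            conv.b[:] = weights[f"conv{i}.b"]
            bn.gamma[:] = weights[f"bn{i}.gamma"]
            bn.beta[:] = weights[f"bn{i}.beta"]
            bn.running_mean[:] = weights[f"bn{i}.mean"]
            bn.running_var[:] = weights[f"bn{i}.var"]
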