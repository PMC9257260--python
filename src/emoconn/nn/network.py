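"""The domain-adaptive residual CNN graph and its loss functions.

The network has three parameter groups:

* ``theta_f`` — feature extractor: stem convolution followed by ``r``
  residual blocks, then flatten;
* ``theta_y`` — label predictor: two dense layers (sigmoid activation by
  default, with dropout) and a softmax class head;
* ``theta_d`` — domain discriminator: a dense/ReLU/dense softmax head fed
  through a gradient-reversal layer (GRL) from the flattened features.

The GRL is the identity in the forward pass; in the backward pass the
gradient flowing from the discriminator into the feature extractor is
multiplied by ``-lambda``, so a single Adam minimization step descends
the label loss L_y while ascending the discriminator loss L_d for
``theta_f`` (and descending it for ``theta_d``).
"""

from __future__ import annotations

import warnings

import numpy as np

from .layers import (F32, BatchNorm, Conv2d, Dense, Dropout, Flatten, Layer,
                     Param, ReLU, ResidualBlock, Sequential, Sigmoid, softmax)

_EPS = 1e-12


def classifier_loss(probs: np.ndarray, labels: np.ndarray,
                    reduction: str = "sum") -> float:
    """Cross-entropy of the true class: sum_i -log P(l_i | S_i).

    ``probs`` rows must sum to 1; zero probability on a true class is
    clamped at 1e-12 with a warning.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true <= 0):
        warnings.warn("zero probability on a true class; clamping at 1e-12")
        p_true = np.clip(p_true, _EPS, None)
    loss = -np.log(p_true)
    return float(loss.sum() if reduction == "sum" else loss.mean())


def discriminator_loss(domain_probs: np.ndarray, domain_labels: np.ndarray,
                       reduction: str = "sum") -> float:
    """Domain cross-entropy: -sum_src log P(0|S) - sum_tgt log P(1|S).

    Domains are coded source=0, target=1.  A batch containing only one
    domain is computed over the present terms and flagged with a warning.
    """
    domain_labels = np.asarray(domain_labels)
    if len(np.unique(domain_labels)) < 2:
        warnings.warn("discriminator batch contains a single domain")
    return classifier_loss(domain_probs, domain_labels, reduction=reduction)


class GradientReversal(Layer):
    """Identity forward; backward multiplies the gradient by -lambda."""

    def __init__(self, lam: float = 1.0):
        self.lam = lam

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return -self.lam * grad


class SoftmaxCrossEntropy:
    """Softmax + cross-entropy with a fused, numerically stable gradient."""

    def __init__(self, reduction: str = "mean"):
        self.reduction = reduction

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
        self._probs = softmax(logits.astype(np.float64))
        self._labels = np.asarray(labels)
        loss = classifier_loss(self._probs, self._labels, reduction=self.reduction)
        return self._probs, loss

    def backward(self) -> np.ndarray:
        g = self._probs.copy()
        g[np.arange(len(self._labels)), self._labels] -= 1.0
        if self.reduction == "mean":
            g /= len(self._labels)
        return g.astype(F32)


class DARCNN:
    """Residual CNN with optional gradient-reversal domain discriminator.

    Parameters mirror the published architecture: a stem convolution with
    ``stem_filters`` kernels, ``len(block_channels)`` residual blocks at
    stride 1 with same padding (1x1 projection shortcuts where the channel
    count grows), two dense layers with dropout, and a softmax class head.
    """

    def __init__(self, input_shape: tuple[int, int], n_classes: int = 2,
                 kernel: int = 5, stem_filters: int = 32,
                 block_channels: tuple[int, ...] = (32, 64, 128),
                 dense_sizes: tuple[int, ...] = (1024, 512),
                 dropout: float = 0.2, dense_activation: str = "sigmoid",
                 domain_adapt: bool = False, grl_lambda: float = 1.0,
                 disc_hidden: int = 256, disc_dropout: float = 0.0, seed: int = 0):
        h, w = input_shape
        if kernel >= min(h, w):
            raise ValueError(f"kernel {kernel} must be smaller than input side {min(h, w)}")
        if len(block_channels) < 1:
            raise ValueError("need at least one residual block")
        rng = np.random.default_rng(seed)
        act = {"sigmoid": Sigmoid, "relu": ReLU}[dense_activation]

        feat: list[Layer] = [Conv2d(1, stem_filters, kernel, rng),
                             BatchNorm(stem_filters), ReLU()]
        c = stem_filters
        for c_out in block_channels:
            feat.append(ResidualBlock(c, c_out, kernel, rng))
            c = c_out
        feat.append(Flatten())
        self.feature = Sequential(*feat)
        n_flat = c * h * w

        label: list[Layer] = []
        n_in = n_flat
        for n_out in dense_sizes:
            label += [Dense(n_in, n_out, rng), act(), Dropout(dropout, rng)]
            n_in = n_out
        label.append(Dense(n_in, n_classes, rng))
        self.label_head = Sequential(*label)

        self.domain_adapt = domain_adapt
        self.grl = GradientReversal(grl_lambda)
        if domain_adapt:
            # input dropout keeps the discriminator from memorizing
            # individual windows, so its loss stays informative and the
            # reversed gradient aligns distributions instead of noise
            disc: list[Layer] = []
            if disc_dropout > 0:
                disc.append(Dropout(disc_dropout, rng))
            disc += [Dense(n_flat, disc_hidden, rng), ReLU(),
                     Dense(disc_hidden, 2, rng)]
            self.domain_head = Sequential(*disc)
        else:
            self.domain_head = None
        self.n_classes = n_classes
        self.input_shape = input_shape

    # -- parameter groups ------------------------------------------------
    @property
    def theta_f(self) -> list[Param]:
        return self.feature.params()

    @property
    def theta_y(self) -> list[Param]:
        return self.label_head.params()

    @property
    def theta_d(self) -> list[Param]:
        return self.domain_head.params() if self.domain_head is not None else []

    def params(self) -> list[Param]:
        return self.theta_f + self.theta_y + self.theta_d

    def set_mode(self, train: bool) -> None:
        self.feature.set_mode(train)
        self.label_head.set_mode(train)
        if self.domain_head is not None:
            self.domain_head.set_mode(train)

    # -- inference -------------------------------------------------------
    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        """(n, H, W) or (n, H, W, C) float32, channels-last."""
        x = np.asarray(x, dtype=F32)
        if x.ndim == 3:
            x = x[:, :, :, None]
        return x

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.label_head.forward(self.feature.forward(self._as_batch(x)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.set_mode(False)
        return softmax(self.forward_logits(x).astype(np.float64))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """argmax_c P(c|S); exact ties resolve to the lower class index."""
        return np.argmax(self.predict_proba(x), axis=1)
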