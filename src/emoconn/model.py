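"""Scikit-learn estimator wrapping the domain-adaptive residual CNN.

The classifier minimizes the composite objective L = L_y - L_d, where
L_y is the label cross-entropy on labelled source windows and L_d is the
domain-discriminator cross-entropy on source-vs-target windows.  A
gradient-reversal layer lets one Adam pass descend L_y (and L_d for the
discriminator parameters) while ascending L_d for the shared feature
extractor, which pushes the learned features toward domain invariance.

Domain adaptation is transductive: the *unlabelled inputs* of the
evaluation domain may be passed as ``X_target``; their labels are never
seen (the API has no slot for them).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn.network import DARCNN, SoftmaxCrossEntropy
from .nn.optim import Adam

_DEFAULT_WIDTHS = (32, 64, 128)


def default_block_channels(n_blocks: int, stem_filters: int = 32) -> tuple[int, ...]:
    """Channel widths per residual block: 32, 64, 128, then capped at 128."""
    base = list(_DEFAULT_WIDTHS)
    if stem_filters != 32:  # scaled-down profiles keep a flat width
        return (stem_filters,) * n_blocks
    while len(base) < n_blocks:
        base.append(base[-1])
    return tuple(base[:n_blocks])


class DomainAdaptiveRCNN(ClassifierMixin, BaseEstimator):
    """Residual CNN classifier with optional adversarial domain adaptation.

    Parameters
    ----------
    n_blocks : number of residual blocks (r).
    kernel_size : square convolution kernel, one of 3, 5, 7.
    stem_filters : filters in the stem convolution.
    block_channels : per-block channel widths; None derives 32/64/128-style
        defaults from ``n_blocks``.
    dense_sizes : widths of the two fully connected layers.
    dropout : dropout rate after each dense layer.
    dense_activation : "sigmoid" (default) or "relu" on the dense layers.
    domain_adapt : enable the gradient-reversal domain discriminator.
    grl_lambda : gradient-reversal scale (lambda).
    grl_schedule : None for a fixed lambda, or "dann" for the warm-up
        lambda(p) = grl_lambda * (2/(1+exp(-10 p)) - 1) over training progress p.
    disc_hidden : hidden width of the domain discriminator.
    learning_rate, batch_size, epochs : Adam optimization settings.
    reduction : "mean" (batch-size-independent learning rate) or "sum"
        loss reduction inside the training loop.
    standardize : z-score inputs per feature cell using source statistics.
    random_state : seed controlling init, shuffling and dropout.

    Attributes
    ----------
    classes_ : sorted class labels.
    net_ : the underlying network.
    history_ : per-epoch records with keys epoch, L_y, L_d, L, acc.
    """

    def __init__(self, n_blocks: int = 3, kernel_size: int = 5,
                 stem_filters: int = 32, block_channels: tuple[int, ...] | None = None,
                 dense_sizes: tuple[int, ...] = (1024, 512), dropout: float = 0.2,
                 dense_activation: str = "sigmoid", domain_adapt: bool = False,
                 grl_lambda: float = 1.0, grl_schedule: str | None = None,
                 disc_hidden: int = 256, disc_dropout: float = 0.0,
                 target_batch_size: int | None = None,
                 avg_tail: float = 0.0, learning_rate: float = 1e-4,
                 batch_size: int = 40, epochs: int = 200, reduction: str = "mean",
                 standardize: bool = True, random_state: int = 0):
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.stem_filters = stem_filters
        self.block_channels = block_channels
        self.dense_sizes = dense_sizes
        self.dropout = dropout
        self.dense_activation = dense_activation
        self.domain_adapt = domain_adapt
        self.grl_lambda = grl_lambda
        self.grl_schedule = grl_schedule
        self.disc_hidden = disc_hidden
        self.disc_dropout = disc_dropout
        self.target_batch_size = target_batch_size
        self.avg_tail = avg_tail
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.reduction = reduction
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _prepare(self, X: np.ndarray, fit_stats: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, height, width)")
        if fit_stats:
            if self.standardize:
                self._mu = X.mean(axis=0)
                self._sd = np.maximum(X.std(axis=0), 1e-8)
            else:
                self._mu = np.zeros(X.shape[1:], dtype=np.float32)
                self._sd = np.ones(X.shape[1:], dtype=np.float32)
        return (X - self._mu) / self._sd

    def fit(self, X, y, X_target=None):
        """Train on labelled source windows, optionally adapting to X_target.

        ``X_target`` carries unlabelled feature matrices from the
        evaluation domain; it is required when ``domain_adapt`` is on.
        """
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(y) == 0:
            raise ValueError("empty training set")
        Xs = self._prepare(X, fit_stats=True)
        self.n_features_in_ = Xs.shape[1] * Xs.shape[2]
        bc = self.block_channels
        if bc is None:
            bc = default_block_channels(self.n_blocks, self.stem_filters)
        if len(bc) != self.n_blocks:
            raise ValueError(f"{self.n_blocks} blocks but {len(bc)} channel widths")
        net = DARCNN(input_shape=Xs.shape[1:3], n_classes=len(self.classes_),
                     kernel=self.kernel_size, stem_filters=self.stem_filters,
                     block_channels=tuple(bc), dense_sizes=tuple(self.dense_sizes),
                     dropout=self.dropout, dense_activation=self.dense_activation,
                     domain_adapt=self.domain_adapt, grl_lambda=self.grl_lambda,
                     disc_hidden=self.disc_hidden, disc_dropout=self.disc_dropout,
                     seed=self.random_state)
        if self.domain_adapt:
            if X_target is None:
                raise ValueError("domain_adapt=True requires X_target")
            Xt = self._prepare(X_target)
        else:
            Xt = None
        self.net_ = net
        self.history_ = self._train(net, Xs, y_idx, Xt)
        return self

    def _train(self, net: DARCNN, Xs, y, Xt) -> list[dict]:
        rng = np.random.default_rng(self.random_state)
        ce = SoftmaxCrossEntropy(self.reduction)
        dce = SoftmaxCrossEntropy(self.reduction)
        opt = Adam(net.params(), lr=self.learning_rate)
        n = len(Xs)
        bs = min(self.batch_size, n)
        steps = max(1, n // bs)
        history = []
        total_steps = self.epochs * steps
        step_no = 0
        # tail averaging: mean of the parameters over the last
        # ceil(avg_tail * epochs) epochs is used for prediction, damping
        # the jitter of the final optimization steps
        avg_from = self.epochs - max(1, int(np.ceil(self.avg_tail * self.epochs))) \
            if self.avg_tail > 0 else None
        avg_state = None
        avg_count = 0
        net.set_mode(True)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            if Xt is not None:
                t_order = rng.permutation(len(Xt))
            ep_ly = ep_ld = 0.0
            correct = 0
            seen = 0
            for b in range(steps):
                idx = order[b * bs:(b + 1) * bs]
                xb, yb = Xs[idx], y[idx]
                opt.zero_grad()
                if self.grl_schedule == "dann" and total_steps > 1:
                    p = step_no / (total_steps - 1)
                    net.grl.lam = self.grl_lambda * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)
                if Xt is None:
                    f = net.feature.forward(net._as_batch(xb))
                    logits = net.label_head.forward(f)
                    probs, ly = ce.forward(logits, yb)
                    net.feature.backward(net.label_head.backward(ce.backward()))
                    ld = 0.0
                else:
                    # one fused pass: source rows feed the label head, all
                    # rows feed the GRL + discriminator
                    tbs = min(self.target_batch_size or bs, len(Xt))
                    tidx = t_order[(b * tbs) % len(Xt):(b * tbs) % len(Xt) + tbs]
                    if len(tidx) < tbs:
                        tidx = np.concatenate([tidx, t_order[:tbs - len(tidx)]])
                    xall = np.concatenate([xb, Xt[tidx]])
                    f = net.feature.forward(net._as_batch(xall))
                    logits = net.label_head.forward(f[:len(xb)])
                    probs, ly = ce.forward(logits, yb)
                    g_label = net.label_head.backward(ce.backward())
                    dlab = np.r_[np.zeros(len(xb), dtype=int), np.ones(len(tidx), dtype=int)]
                    dlogits = net.domain_head.forward(f)
                    _, ld = dce.forward(dlogits, dlab)
                    g_dom = net.grl.backward(net.domain_head.backward(dce.backward()))
                    g_f = g_dom.copy()
                    g_f[:len(xb)] += g_label
                    net.feature.backward(g_f)
                opt.step()
                step_no += 1
                ep_ly += ly
                ep_ld += ld
                correct += int((np.argmax(probs, axis=1) == yb).sum())
                seen += len(yb)
                if not np.isfinite(ly):
                    raise FloatingPointError(f"non-finite classifier loss at epoch {epoch}")
            ly_m, ld_m = ep_ly / steps, ep_ld / steps
            history.append({"epoch": epoch, "L_y": ly_m, "L_d": ld_m,
                            "L": ly_m - ld_m, "acc": correct / seen})
            if avg_from is not None and epoch >= avg_from:
                vals = [p.value for p in net.params()]
                if avg_state is None:
                    avg_state = [v.copy() for v in vals]
                else:
                    for a, v in zip(avg_state, vals):
                        a += v
                avg_count += 1
        if avg_state is not None:
            for p, a in zip(net.params(), avg_state):
                p.value[...] = a / avg_count
        return history

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._prepare(X))

    def predict(self, X) -> np.ndarray:
        """argmax-probability class; exact ties resolve to the lower class."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
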