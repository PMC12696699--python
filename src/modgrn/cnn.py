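"""CNN pair classifier over 32x32 joint-expression histograms.

A compact convolutional network maps a pair histogram H to a regulatory
probability Y = phi(H) in (0, 1): repeated (3x3 convolution -> ReLU -> 2x2
max-pool) blocks, a flatten, inverted-scaling dropout, a ReLU dense layer
and a single sigmoid output unit, trained with binary cross-entropy and
Adam. Implemented directly on NumPy arrays with explicit forward/backward
passes; dropout is active only in training mode, and survivors are
upscaled by 1/(1-P) so that inference needs no rescaling.

The stack is deliberately small: the learnable object is a 32x32 count
grid, not a natural image, and the labeled pair sets the method sees are
in the hundreds to low thousands.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .pairdata import LabeledPairSet


# ---------------------------------------------------------------- layers


def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution. x: (N, C, H, Wd); W: (F, C, 3, 3)."""
    N, C, H, Wd = x.shape
    F = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((N, F, H, Wd), dtype=x.dtype)
    for dm in range(3):
        for dn in range(3):
            xs = xp[:, :, dm : dm + H, dn : dn + Wd]
            # (N,C,H,W) x (F,C) -> (N,F,H,W)
            out += np.tensordot(xs, W[:, :, dm, dn], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None]


def conv2d_backward(x, W, dout):
    """Gradients of the same-padding 3x3 convolution."""
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for dm in range(3):
        for dn in range(3):
            xs = xp[:, :, dm : dm + H, dn : dn + Wd]
            dW[:, :, dm, dn] = np.tensordot(dout, xs, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, dm : dm + H, dn : dn + Wd] += np.tensordot(
                dout, W[:, :, dm, dn], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


def maxpool2x2_forward(x: np.ndarray):
    """2x2 max-pool with stride 2; H, W must be even. Returns (out, argmax)."""
    N, C, H, Wd = x.shape
    xr = x.reshape(N, C, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(N, C, H // 2, Wd // 2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return out, arg


def maxpool2x2_backward(dout: np.ndarray, arg: np.ndarray, in_shape) -> np.ndarray:
    N, C, H, Wd = in_shape
    dxr = np.zeros((N, C, H // 2, Wd // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(N, C, H // 2, Wd // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(N, C, H, Wd)


def dropout_mask(shape, p: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-scaling dropout multiplier: 0 w.p. p, 1/(1-p) otherwise.

    E[mask * x] = x, so inference simply omits the mask.
    """
    if not 0 <= p < 1:
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    if p == 0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------- configs


@dataclass
class ModelConfig:
    """Architecture: (filters per conv block), dense width, dropout probability.

    Every conv kernel is 3x3 and every pool is 2x2; each block halves the
    spatial size, so the number of blocks is limited by the 32x32 input.
    """

    conv_blocks: tuple = (32, 64, 128)
    dense_units: int = 256
    dropout_p: float = 0.25
    input_size: int = 32

    def __post_init__(self):
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        size = self.input_size
        for _ in self.conv_blocks:
            if size < 2:
                raise ValueError("too many conv/pool blocks for the input size")
            size //= 2
        if size < 1:
            raise ValueError("non-positive spatial size after pooling")

    @classmethod
    def compact(cls) -> "ModelConfig":
        """Small variant sized for labeled sets of a few hundred pairs."""
        return cls(conv_blocks=(8, 16), dense_units=32)


@dataclass
class TrainConfig:
    """Optimization settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    k_folds: int = 5
    epochs: int = 50
    batch_size: int = 64
    lr: float = 1e-3

    def __post_init__(self):
        if not 2 <= self.k_folds <= 7:
            raise ValueError("k_folds must be in [2, 7]")


# ---------------------------------------------------------------- model


class CNNPairClassifier:
    """The histogram -> probability network with explicit backprop and Adam."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in, size = 1, cfg.input_size
        for i, f in enumerate(cfg.conv_blocks):
            fan_in = c_in * 9
            self.params[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), (f, c_in, 3, 3))
            self.params[f"bc{i}"] = np.zeros(f)
            c_in, size = f, size // 2
        flat = c_in * size * size
        self.params["Wd0"] = rng.normal(0, np.sqrt(2.0 / flat), (flat, cfg.dense_units))
        self.params["bd0"] = np.zeros(cfg.dense_units)
        self.params["Wd1"] = rng.normal(0, np.sqrt(2.0 / cfg.dense_units), (cfg.dense_units, 1))
        self.params["bd1"] = np.zeros(1)
        self._flat = flat
        # input standardization (set at fit time)
        self._mu, self._sd = 0.0, 1.0
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- plumbing

    @property
    def param_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _prep(self, H: np.ndarray) -> np.ndarray:
        H = np.asarray(H, dtype=float)
        if H.ndim == 2:
            H = H[None]
        if H.shape[-2:] != (self.cfg.input_size, self.cfg.input_size):
            raise ValueError(f"expected {self.cfg.input_size}x{self.cfg.input_size} histograms")
        return ((H - self._mu) / self._sd)[:, None, :, :]

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass returning logits and a cache for backprop.

        ``rng`` non-None means training mode (dropout active).
        """
        p = self.cfg.dropout_p
        cache = {"x0": x}
        h = x
        for i in range(len(self.cfg.conv_blocks)):
            z = conv2d_forward(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            r = np.maximum(z, 0.0)
            pooled, arg = maxpool2x2_forward(r)
            cache[f"conv_in{i}"], cache[f"relu{i}"] = h, r
            cache[f"arg{i}"], cache[f"pool_in_shape{i}"] = arg, r.shape
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        cache["pre_flat_shape"] = h.shape
        if rng is not None and p > 0:
            m0 = dropout_mask(flat.shape, p, rng)
            flat = flat * m0
            cache["m0"] = m0
        cache["flat"] = flat
        zd = flat @ self.params["Wd0"] + self.params["bd0"]
        rd = np.maximum(zd, 0.0)
        cache["zd"] = zd
        if rng is not None and p > 0:
            m1 = dropout_mask(rd.shape, p, rng)
            rd = rd * m1
            cache["m1"] = m1
        cache["rd"] = rd
        logits = (rd @ self.params["Wd1"] + self.params["bd1"]).ravel()
        return logits, cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict:
        g: dict[str, np.ndarray] = {}
        dl = dlogits[:, None]
        g["Wd1"] = cache["rd"].T @ dl
        g["bd1"] = dl.sum(axis=0)
        drd = dl @ self.params["Wd1"].T
        if "m1" in cache:
            drd = drd * cache["m1"]
        dzd = drd * (cache["zd"] > 0)
        g["Wd0"] = cache["flat"].T @ dzd
        g["bd0"] = dzd.sum(axis=0)
        dflat = dzd @ self.params["Wd0"].T
        if "m0" in cache:
            dflat = dflat * cache["m0"]
        dh = dflat.reshape(cache["pre_flat_shape"])
        for i in reversed(range(len(self.cfg.conv_blocks))):
            dr = maxpool2x2_backward(dh, cache[f"arg{i}"], cache[f"pool_in_shape{i}"])
            dz = dr * (cache[f"relu{i}"] > 0)
            dh, g[f"Wc{i}"], g[f"bc{i}"] = conv2d_backward(
                cache[f"conv_in{i}"], self.params[f"Wc{i}"], dz
            )
        return g

    def _adam_step(self, grads: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * gk
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * gk**2
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API

    def fit(self, H: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> list[float]:
        """Minimize binary cross-entropy; returns per-epoch mean loss."""
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2 and cfg.epochs > 0:
            raise ValueError("training data must contain both classes")
        Hf = np.asarray(H, dtype=float)
        self._mu = float(Hf.mean())
        self._sd = float(Hf.std()) or 1.0
        x = self._prep(Hf)
        rng = np.random.default_rng(cfg.seed)
        n = x.shape[0]
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                logits, cache = self._forward(xb, rng=rng)
                # stable BCE with logits: log(1+e^z) - y z
                loss = float(np.mean(np.logaddexp(0.0, logits) - yb * logits))
                dlogits = (sigmoid(logits) - yb) / len(yb)
                grads = self._backward(cache, dlogits)
                self._adam_step(grads, cfg.lr)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, H: np.ndarray) -> np.ndarray:
        """Deterministic inference probabilities in (0, 1); dropout inactive."""
        x = self._prep(H)
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], 256):
            logits, _ = self._forward(x[start : start + 256], rng=None)
            out[start : start + 256] = sigmoid(logits)
        return out

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {"cfg": self.cfg, "params": self.params, "mu": self._mu, "sd": self._sd}, fh
            )

    @classmethod
    def load(cls, path) -> "CNNPairClassifier":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        model = cls(blob["cfg"])
        model.params = blob["params"]
        model._mu, model._sd = blob["mu"], blob["sd"]
        return model


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> CNNPairClassifier:
    """Construct an untrained classifier; reports its parameter count via the handle."""
    return CNNPairClassifier(cfg or ModelConfig(), seed=seed)


def train(
    model: CNNPairClassifier, histograms: np.ndarray, labels: np.ndarray, cfg: TrainConfig
) -> tuple[CNNPairClassifier, list[float]]:
    """Train in place; with 0 epochs the model is returned unchanged."""
    history = model.fit(histograms, labels, cfg)
    return model, history


# ---------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    """Confusion metrics, ROC/AUC and the confidence histogram of one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    tpr: float
    fpr: float
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    confidence_bins: np.ndarray  # bin left edges
    confidence_correct: np.ndarray
    confidence_incorrect: np.ndarray
    scores: np.ndarray | None = None
    labels: np.ndarray | None = None
    per_fold: pd.DataFrame | None = None
    fold_ids: np.ndarray | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["TP", "FP", "TN", "FN", "accuracy", "TPR", "FPR", "AUC"],
                "value": [
                    self.tp, self.fp, self.tn, self.fn,
                    self.accuracy, self.tpr, self.fpr, self.auc,
                ],
            }
        )


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5, n_bins: int = 10
) -> EvalReport:
    """Confusion counts at a threshold plus full-sweep ROC/AUC.

    Accuracy = (TP+TN)/(TP+TN+FP+FN); TPR = TP/(TP+FN); FPR = FP/(FP+TN).
    The ROC sweeps all score thresholds and AUC is the trapezoid area.
    One-class label vectors leave the undefined rate(s) and AUC as NaN. The
    confidence histogram counts correct vs incorrect predictions per
    probability bin.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / len(labels)
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    if len(np.unique(labels)) == 2:
        r_fpr, r_tpr, _ = roc_curve(labels, scores)
        auc_val = float(_trapezoid_auc(r_fpr, r_tpr))
    else:
        warnings.warn("one-class labels: ROC/AUC undefined", stacklevel=2)
        r_fpr, r_tpr, auc_val = np.array([]), np.array([]), float("nan")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    correct = pred == labels
    conf_ok = np.bincount(bin_idx[correct], minlength=n_bins)
    conf_bad = np.bincount(bin_idx[~correct], minlength=n_bins)
    return EvalReport(
        tp, fp, tn, fn, acc, tpr, fpr, auc_val,
        r_fpr, r_tpr, edges[:-1], conf_ok, conf_bad,
        scores=scores, labels=labels,
    )


def cross_validate(
    histograms: np.ndarray,
    pairset: LabeledPairSet,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> EvalReport:
    """K-fold cross-validation: train on K-1 folds, score the held-out fold.

    Pooled held-out predictions (each pair scored exactly once) produce the
    headline ROC/AUC; a per-fold metric table is attached.
    """
    if pairset.folds is None:
        raise ValueError("pairset has no fold assignment; call kfold_split first")
    folds = np.unique(pairset.folds)
    scores = np.full(len(pairset), np.nan)
    rows = []
    for f in folds:
        test = pairset.folds == f
        if not test.any() or test.all():
            raise ValueError(f"fold {f} is empty or covers the whole set")
        model = CNNPairClassifier(model_cfg, seed=train_cfg.seed + int(f))
        model.fit(histograms[~test], pairset.labels[~test], train_cfg)
        scores[test] = model.predict_proba(histograms[test])
        rep = evaluate(scores[test], pairset.labels[test])
        rows.append(
            {"fold": int(f), "n": int(test.sum()), "accuracy": rep.accuracy,
             "tpr": rep.tpr, "fpr": rep.fpr, "auc": rep.auc}
        )
    pooled = evaluate(scores, pairset.labels)
    pooled.per_fold = pd.DataFrame(rows)
    pooled.fold_ids = pairset.folds.copy()
    return pooled
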