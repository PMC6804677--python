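"""Training, decision-threshold tuning and classification.

The training protocol: Adam, cross-entropy, random mirror/rotation
augmentation (applied per video so temporal coherence is preserved),
truncated-normal convolution init and zero-initialized fully connected
weights.  Because a rare-cell counter must make essentially no false
calls, the decision threshold is tuned after training: starting from 0.5
it is raised along a decade grid (0.9, 0.99, ...) until the pooled
training+validation scores contain zero false positives, then raised one
more decade as a safety margin against overfitting of the score
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers import Dropout, SoftmaxCrossEntropy
from .network import Network

__all__ = [
    "TrainConfig", "DecisionThreshold", "Adam", "train",
    "tune_decision_threshold", "classify", "sensitivity_specificity",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The full-scale protocol uses learning rate 1e-4, batch size 240 and
    800-1000 epochs; the desk-scale profile shrinks all three so that the
    two-class synthetic benchmark trains in minutes on one CPU.
    """

    learning_rate: float = 1e-4
    batch_size: int = 240
    epochs: int = 800
    augment: bool = True
    init_std: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        return cls(learning_rate=2e-3, batch_size=50, epochs=30, seed=seed)


@dataclass(frozen=True)
class DecisionThreshold:
    """Probability cutoff for calling a positive (>= convention)."""

    value: float
    safety_applied: bool = False

    def __post_init__(self):
        if not (0.5 <= self.value < 1.0):
            raise ValueError("decision threshold must lie in [0.5, 1)")


class Adam:
    """Adaptive-moment estimation optimizer."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[:] = 0.0


def _augment_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal mirror and 90/180/270 degree rotation, per video
    (identical transform for every frame of a video)."""
    x = x.copy()
    for i in range(len(x)):
        if rng.random() < 0.5:
            x[i] = x[i, :, :, :, ::-1]
        rot = rng.integers(0, 4)
        if rot:
            x[i] = np.rot90(x[i], k=int(rot), axes=(2, 3))
    return x


def sensitivity_specificity(labels_true: np.ndarray, labels_pred: np.ndarray):
    t = np.asarray(labels_true).astype(bool)
    p = np.asarray(labels_pred).astype(bool)
    pos, neg = t.sum(), (~t).sum()
    sens = (p & t).sum() / pos if pos else np.nan
    spec = (~p & ~t).sum() / neg if neg else np.nan
    return float(sens), float(spec)


def train(model: Network, videos: np.ndarray, labels: np.ndarray,
          config: TrainConfig | None = None,
          val_videos: np.ndarray | None = None,
          val_labels: np.ndarray | None = None) -> pd.DataFrame:
    """Train the classifier in place; returns per-epoch metrics.

    ``videos`` is (n, c, t, h, w); ``labels`` holds class indices with 1 =
    positive (target cell).  Deterministic for a fixed config seed.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    if len(videos) != len(labels):
        raise ValueError("videos and labels length mismatch")
    rng = np.random.default_rng(config.seed)
    model.initialize(rng, std=config.init_std)
    for layer in model.layers:
        if isinstance(layer, Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31 - 1))
    opt = Adam(model.params(), lr=config.learning_rate)
    loss_fn = SoftmaxCrossEntropy()
    history = []
    n = len(videos)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        preds = np.empty(n, dtype=bool)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = videos[idx].astype(np.float32)
            yb = labels[idx]
            if config.augment:
                xb = _augment_batch(xb, rng)
            logits = model.forward(xb, train=True)
            loss, probs = loss_fn.forward(logits, yb)
            opt.zero_grad()
            model.backward(loss_fn.backward())
            opt.step()
            epoch_loss += loss * len(idx)
            preds[idx] = probs[:, 1] >= 0.5
        sens, spec = sensitivity_specificity(labels == 1, preds)
        row = dict(epoch=epoch, loss=epoch_loss / n, train_sensitivity=sens,
                   train_specificity=spec)
        if val_videos is not None:
            vp = model.predict_proba(val_videos)[:, 1] >= 0.5
            vs, vsp = sensitivity_specificity(val_labels == 1, vp)
            row.update(val_sensitivity=vs, val_specificity=vsp)
        history.append(row)
    return pd.DataFrame(history)


def threshold_grid(max_decades: int = 12) -> np.ndarray:
    """The decade grid 0.5, 0.9, 0.99, ... used for threshold tuning."""
    return np.array([0.5] + [1.0 - 10.0**-d for d in range(1, max_decades + 1)])


def tune_decision_threshold(scores: np.ndarray, labels: np.ndarray,
                            safety_steps: int = 1) -> DecisionThreshold:
    """Smallest decade-grid threshold with zero false positives on the
    pooled score set, then ``safety_steps`` decades higher (0.99999 ->
    0.999999 style safety margin).

    Raises ``ValueError`` if some negative example scores exactly 1.0 (no
    threshold below 1 can exclude it).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (~labels).any():
        raise ValueError("need at least one negative example")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    neg_max = scores[~labels].max()
    if neg_max >= 1.0:
        raise ValueError("a negative example scored 1.0; no valid threshold")
    grid = threshold_grid()
    ok = np.nonzero(grid > neg_max)[0]  # positive call iff score >= threshold
    if ok.size == 0:
        raise ValueError("no grid threshold excludes all negatives")
    j = min(ok[0] + safety_steps, len(grid) - 1)
    return DecisionThreshold(value=float(grid[j]), safety_applied=safety_steps > 0)


def classify(model: Network, videos: np.ndarray,
             threshold: DecisionThreshold | float | None = None):
    """Labels (positive iff p >= threshold) and probabilities for videos."""
    if len(videos) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    thr = 0.5 if threshold is None else (
        threshold.value if isinstance(threshold, DecisionThreshold) else float(threshold))
    expected = (model.config.in_channels, model.config.n_frames,
                model.config.height, model.config.width)
    if tuple(np.asarray(videos).shape[1:]) != expected:
        raise ValueError(
            f"video shape {np.asarray(videos).shape[1:]} does not match the "
            f"model input {expected}")
    probs = model.predict_proba(videos)[:, 1]
    return probs >= thr, probs
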