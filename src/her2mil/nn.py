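"""A small, fully seeded feed-forward network trainer.

This is the training engine behind the two tile classifiers and the tabular
learner: a plain multi-layer perceptron (ReLU hidden layers, softmax output,
cross-entropy loss) optimized with Adam under a one-cycle learning-rate
schedule — the rate ramps linearly from ``lr_max / div`` up to ``lr_max``
over the first 30% of steps, then anneals linearly down to
``lr_max / final_div``.

Two-phase fine-tuning is supported by freezing all layers except the output
layer ("head-only" epochs) before unfreezing the whole network, mirroring the
usual transfer-learning recipe. All randomness (weight init, batch shuffling)
flows through a single integer seed; inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np


def one_cycle_schedule(
    n_steps: int, lr_max: float, pct_ramp: float = 0.3, div: float = 10.0,
    final_div: float = 100.0,
) -> np.ndarray:
    """Per-step learning rates: linear warm-up then linear anneal."""
    if n_steps <= 0:
        return np.empty(0)
    n_up = max(1, int(round(n_steps * pct_ramp)))
    n_down = max(1, n_steps - n_up)
    up = np.linspace(lr_max / div, lr_max, n_up)
    down = np.linspace(lr_max, lr_max / final_div, n_down + 1)[1:]
    return np.concatenate([up, down])[:n_steps]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLPConfig:
    hidden_layers: Tuple[int, ...] = (64, 32)
    lr_max: float = 1e-2
    batch_size: int = 32
    weight_decay: float = 1e-4
    seed: int = 0


class MLPClassifier:
    """Minimal dense softmax classifier with Adam and one-cycle scheduling."""

    def __init__(self, n_features: int, n_classes: int, config: MLPConfig):
        self.config = config
        self.n_features = n_features
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        sizes = [n_features, *config.hidden_layers, n_classes]
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._rng = rng
        self._adam_state: Optional[dict] = None
        self.history: List[Dict[str, float]] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray) -> Tuple[np.ndarray, List[np.ndarray]]:
        acts = [X]
        h = X
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        logits = h @ self.W[-1] + self.b[-1]
        return logits, acts

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=float))
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def _grads(
        self, X: np.ndarray, y: np.ndarray
    ) -> Tuple[List[np.ndarray], List[np.ndarray], float]:
        n = X.shape[0]
        logits, acts = self._forward(X)
        probs = _softmax(logits)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for layer in range(len(self.W) - 1, -1, -1):
            gW[layer] = acts[layer].T @ delta + self.config.weight_decay * self.W[layer]
            gb[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.W[layer].T) * (acts[layer] > 0)
        return gW, gb, loss

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        trainable_layers: Optional[Sequence[int]] = None,
        metric: Optional[Callable[[np.ndarray, np.ndarray], float]] = None,
        metric_name: str = "metric",
    ) -> "MLPClassifier":
        """Run ``epochs`` passes of mini-batch Adam with a one-cycle schedule.

        ``trainable_layers`` restricts updates to the given layer indices
        (e.g. ``[-1]`` for head-only fine-tuning); None trains every layer.
        ``metric`` is evaluated on the full training set after each epoch and
        recorded in ``self.history`` — it monitors training, it is not the
        optimized loss (the loss is always cross-entropy).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if epochs <= 0:
            return self
        n = X.shape[0]
        bs = min(self.config.batch_size, n)
        steps_per_epoch = max(1, n // bs)
        lrs = one_cycle_schedule(epochs * steps_per_epoch, self.config.lr_max)
        if trainable_layers is None:
            train_idx = set(range(len(self.W)))
        else:
            train_idx = {i % len(self.W) for i in trainable_layers}
        # fresh Adam moments per fit call (each phase is its own cycle)
        m_W = [np.zeros_like(W) for W in self.W]
        v_W = [np.zeros_like(W) for W in self.W]
        m_b = [np.zeros_like(b) for b in self.b]
        v_b = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for s in range(steps_per_epoch):
                idx = order[s * bs : (s + 1) * bs]
                gW, gb, loss = self._grads(X[idx], y[idx])
                epoch_loss += loss
                lr = lrs[step]
                step += 1
                t = step
                for layer in train_idx:
                    for g, p, m, v in (
                        (gW[layer], self.W[layer], m_W[layer], v_W[layer]),
                        (gb[layer], self.b[layer], m_b[layer], v_b[layer]),
                    ):
                        m[:] = beta1 * m + (1 - beta1) * g
                        v[:] = beta2 * v + (1 - beta2) * g * g
                        m_hat = m / (1 - beta1**t)
                        v_hat = v / (1 - beta2**t)
                        p -= lr * m_hat / (np.sqrt(v_hat) + eps)
            record = {"epoch": float(epoch), "loss": epoch_loss / steps_per_epoch}
            if metric is not None:
                record[metric_name] = float(metric(y, self.predict(X)))
            self.history.append(record)
        return self

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_classes": self.n_classes,
            "hidden_layers": list(self.config.hidden_layers),
            "W": [W.tolist() for W in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLPClassifier":
        cfg = MLPConfig(hidden_layers=tuple(state["hidden_layers"]))
        model = cls(state["n_features"], state["n_classes"], cfg)
        model.W = [np.asarray(W, dtype=float) for W in state["W"]]
        model.b = [np.asarray(b, dtype=float) for b in state["b"]]
        return model
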