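"""A small fully-connected regressor with seeded, bit-reproducible training.

Stack: dense 256 (ReLU) -> dense 256 (ReLU) -> dropout 0.5 -> dense 64 (ReLU)
-> linear output. Trained by mini-batch stochastic gradient descent on the
mean-squared error, with optional classical momentum. Dropout uses inverted
scaling and is active only during training, so inference is deterministic.

Everything is plain float64 numpy: given a seed, training is reproducible to
the bit on a fixed BLAS backend.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    def __init__(
        self,
        n_in: int,
        n_out: int,
        hidden: tuple[int, ...] = (256, 256, 64),
        dropout_after: int = 1,
        dropout_rate: float = 0.5,
        seed: int = 0,
    ):
        self.hidden = tuple(hidden)
        self.dropout_after = dropout_after  # index of hidden layer followed by dropout
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)
        sizes = [n_in, *hidden, n_out]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU layers
            self.weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.loss_history: list[float] = []

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Deterministic inference pass (dropout inactive)."""
        h = x
        for i in range(self.n_layers - 1):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
        return h @ self.weights[-1] + self.biases[-1]

    def _forward_train(self, x: np.ndarray, rng: np.random.Generator):
        acts = [x]
        masks: dict[int, np.ndarray] = {}
        h = x
        for i in range(self.n_layers - 1):
            h = np.maximum(h @ self.weights[i] + self.biases[i], 0.0)
            if i == self.dropout_after and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks[i] = mask
            acts.append(h)
        out = h @ self.weights[-1] + self.biases[-1]
        return out, acts, masks

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        learning_rate: float,
        momentum: float | None = None,
        batch_size: int = 64,
        seed: int = 0,
        lr_decay: float = 1.0,
    ) -> "MLP":
        """Mini-batch SGD on the MSE with an optional geometric learning-rate
        schedule (epoch ``e`` uses ``learning_rate * lr_decay**e``). Raises on
        a non-finite loss."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n = x.shape[0]
        rng = np.random.default_rng(seed)
        vel_w = [np.zeros_like(w) for w in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        mu = momentum or 0.0

        for epoch in range(epochs):
            lr = learning_rate * lr_decay**epoch
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                out, acts, masks = self._forward_train(xb, rng)
                err = out - yb
                loss = float(np.mean(err**2))
                epoch_loss += loss * len(idx)

                # backprop: d(mean sq err)/d out
                grad = 2.0 * err / err.size
                grads_w = [None] * self.n_layers
                grads_b = [None] * self.n_layers
                for i in range(self.n_layers - 1, -1, -1):
                    grads_w[i] = acts[i].T @ grad
                    grads_b[i] = grad.sum(axis=0)
                    if i > 0:
                        grad = grad @ self.weights[i].T
                        if (i - 1) in masks:
                            grad = grad * masks[i - 1]  # inverted-dropout scaling
                        grad = grad * (acts[i] > 0)  # ReLU gate
                for i in range(self.n_layers):
                    vel_w[i] = mu * vel_w[i] - lr * grads_w[i]
                    vel_b[i] = mu * vel_b[i] - lr * grads_b[i]
                    self.weights[i] += vel_w[i]
                    self.biases[i] += vel_b[i]
            epoch_loss /= n
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch} with "
                    f"learning_rate={learning_rate}, momentum={momentum}"
                )
            self.loss_history.append(epoch_loss)
        return self

    # -- (de)serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "hidden": list(self.hidden),
            "dropout_after": self.dropout_after,
            "dropout_rate": self.dropout_rate,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "loss_history": self.loss_history,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        weights = [np.array(w, dtype=float) for w in d["weights"]]
        obj = cls(
            n_in=weights[0].shape[0],
            n_out=weights[-1].shape[1],
            hidden=tuple(d["hidden"]),
            dropout_after=d["dropout_after"],
            dropout_rate=d["dropout_rate"],
        )
        obj.weights = weights
        obj.biases = [np.array(b, dtype=float) for b in d["biases"]]
        obj.loss_history = list(d.get("loss_history", []))
        return obj
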