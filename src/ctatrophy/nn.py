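"""Minimal fully-connected network trainer used by the image modules.

The per-slice key-slice scorers, the measurement regressors and the sulci
classifier are all small multi-layer perceptrons trained on downsampled,
windowed slice images.  Two training recipes are provided, matching the
optimization settings of the pipeline's image modules:

* classification — softmax output, cross-entropy loss, SGD with momentum,
  one warm-up epoch followed by piecewise learning-rate decay (x0.1 at 50%
  and 75% of the epoch budget);
* regression — linear output, mean-squared-error loss, Adam with a
  multiplicative decay of the learning rate (0.8 every 10,000 steps).

Everything is plain float32 numpy; training is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "momentum_schedule", "adam_step_decay"]


def momentum_schedule(epoch: int, n_epochs: int) -> float:
    """Warm-up + piecewise decay multiplier for SGD-momentum training.

    Epoch 0 ramps the rate from 10% to 100%; the rate then drops by x0.1
    at 50% and again at 75% of the epoch budget.
    """
    if n_epochs <= 1:
        return 1.0
    if epoch == 0:
        return 0.55  # mean of the within-epoch linear ramp 0.1 -> 1.0
    mult = 1.0
    if epoch >= int(np.ceil(0.5 * n_epochs)):
        mult *= 0.1
    if epoch >= int(np.ceil(0.75 * n_epochs)):
        mult *= 0.1
    return mult


def adam_step_decay(step: int, decay: float = 0.8, decay_step: int = 10_000) -> float:
    return float(decay ** (step // decay_step))


@dataclass
class MLP:
    """Fully-connected net with one or more hidden ReLU layers.

    Parameters
    ----------
    layer_sizes:
        ``[n_in, hidden..., n_out]``.
    task:
        ``"softmax"`` (cross-entropy) or ``"linear"`` (MSE).
    seed:
        Seed for weight initialization and batch shuffling.
    l2:
        L2 penalty on the weights (not the biases).
    """

    layer_sizes: list[int]
    task: str = "softmax"
    seed: int = 0
    l2: float = 1e-4
    weights: list[np.ndarray] = field(default_factory=list, repr=False)
    biases: list[np.ndarray] = field(default_factory=list, repr=False)
    # per-feature input standardization, estimated on the training set
    x_mean: np.ndarray | None = field(default=None, repr=False)
    x_std: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.task not in ("softmax", "linear"):
            raise ValueError(f"unknown task {self.task!r}")
        if not self.weights:
            rng = np.random.default_rng(self.seed)
            for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
                # He initialization, suited to the ReLU hidden layers
                w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
                self.weights.append(w.astype(np.float32))
                self.biases.append(np.zeros(n_out, dtype=np.float32))

    # ------------------------------------------------------------------ forward
    def _forward(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = np.maximum(h, 0.0)
            acts.append(h)
        if self.task == "softmax":
            h = h - h.max(axis=1, keepdims=True)
            e = np.exp(h)
            out = e / e.sum(axis=1, keepdims=True)
        else:
            out = h
        return acts, out

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (softmax task) or raw outputs (linear task)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None, :]
        if self.x_mean is not None:
            x = (x - self.x_mean) / self.x_std
        return self._forward(x)[1]

    # ----------------------------------------------------------------- training
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        lr: float,
        optimizer: str = "momentum",
        momentum: float = 0.9,
        adam_decay: float = 0.8,
        adam_decay_step: int = 10_000,
        shuffle_seed: int = 0,
        standardize: bool = True,
        callback=None,
    ) -> "MLP":
        """Train in place; returns self.

        ``y`` is an integer label vector for the softmax task or a float
        target matrix for the linear task.  With ``standardize`` (default)
        inputs are z-scored per feature using training-set statistics that
        are stored with the model.  With ``epochs=0`` the network is left at
        its initialization (callers flag this degenerate case).
        """
        x = np.asarray(x, dtype=np.float32)
        if standardize:
            self.x_mean = x.mean(axis=0)
            self.x_std = x.std(axis=0) + np.float32(1e-3)
            x = (x - self.x_mean) / self.x_std
        n = x.shape[0]
        if self.task == "softmax":
            y = np.asarray(y, dtype=np.int64)
            n_cls = self.layer_sizes[-1]
            onehot = np.zeros((n, n_cls), dtype=np.float32)
            onehot[np.arange(n), y] = 1.0
            targets = onehot
        else:
            targets = np.asarray(y, dtype=np.float32)
            if targets.ndim == 1:
                targets = targets[:, None]

        if self.task == "linear":
            # start from the constant predictor at the target mean so the
            # small Adam steps refine residuals instead of hunting the scale
            # (with zero epochs this leaves exactly the constant-bias model)
            self.weights[-1] = self.weights[-1] * np.float32(0.1 if epochs > 0 else 0.0)
            self.biases[-1] = targets.mean(axis=0).astype(np.float32)

        rng = np.random.default_rng(shuffle_seed)
        vel_w = [np.zeros_like(w) for w in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        if optimizer == "adam":
            m_w = [np.zeros_like(w) for w in self.weights]
            v_w = [np.zeros_like(w) for w in self.weights]
            m_b = [np.zeros_like(b) for b in self.biases]
            v_b = [np.zeros_like(b) for b in self.biases]
            beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            n_batches = int(np.ceil(n / batch_size))
            for bi in range(n_batches):
                idx = order[bi * batch_size : (bi + 1) * batch_size]
                xb, tb = x[idx], targets[idx]
                acts, out = self._forward(xb)
                m = xb.shape[0]
                if self.task == "softmax":
                    delta = (out - tb) / m  # d(mean CE)/d(logits)
                else:
                    delta = 2.0 * (out - tb) / m  # d(mean SE)/d(output)
                grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore
                grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore
                for li in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[li]
                    grads_w[li] = a_prev.T @ delta + self.l2 * self.weights[li]
                    grads_b[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = (delta @ self.weights[li].T) * (acts[li] > 0)

                if optimizer == "momentum":
                    mult = momentum_schedule(epoch, epochs)
                    if epoch == 0 and n_batches > 1:
                        # linear warm-up within the first epoch
                        mult = 0.1 + 0.9 * bi / (n_batches - 1)
                    rate = lr * mult
                    for li in range(len(self.weights)):
                        vel_w[li] = momentum * vel_w[li] - rate * grads_w[li]
                        vel_b[li] = momentum * vel_b[li] - rate * grads_b[li]
                        self.weights[li] += vel_w[li]
                        self.biases[li] += vel_b[li]
                elif optimizer == "adam":
                    rate = lr * adam_step_decay(step, adam_decay, adam_decay_step)
                    t = step + 1
                    for li in range(len(self.weights)):
                        m_w[li] = beta1 * m_w[li] + (1 - beta1) * grads_w[li]
                        v_w[li] = beta2 * v_w[li] + (1 - beta2) * grads_w[li] ** 2
                        m_b[li] = beta1 * m_b[li] + (1 - beta1) * grads_b[li]
                        v_b[li] = beta2 * v_b[li] + (1 - beta2) * grads_b[li] ** 2
                        mw_hat = m_w[li] / (1 - beta1**t)
                        vw_hat = v_w[li] / (1 - beta2**t)
                        mb_hat = m_b[li] / (1 - beta1**t)
                        vb_hat = v_b[li] / (1 - beta2**t)
                        self.weights[li] -= rate * mw_hat / (np.sqrt(vw_hat) + eps)
                        self.biases[li] -= rate * mb_hat / (np.sqrt(vb_hat) + eps)
                else:
                    raise ValueError(f"unknown optimizer {optimizer!r}")
                step += 1
            if callback is not None:
                callback(epoch, self)
        return self

    # ------------------------------------------------------------- persistence
    def to_arrays(self) -> dict:
        out = {"layer_sizes": np.asarray(self.layer_sizes), "task": np.asarray(self.task)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"w{i}"] = w
            out[f"b{i}"] = b
        if self.x_mean is not None:
            out["x_mean"] = self.x_mean
            out["x_std"] = self.x_std
        return out

    @classmethod
    def from_arrays(cls, arrays: dict) -> "MLP":
        sizes = [int(v) for v in arrays["layer_sizes"]]
        net = cls(sizes, task=str(arrays["task"]))
        net.weights = [np.asarray(arrays[f"w{i}"]) for i in range(len(sizes) - 1)]
        net.biases = [np.asarray(arrays[f"b{i}"]) for i in range(len(sizes) - 1)]
        if "x_mean" in arrays:
            net.x_mean = np.asarray(arrays["x_mean"])
            net.x_std = np.asarray(arrays["x_std"])
        return net
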