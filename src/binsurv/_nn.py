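"""Minimal dense feed-forward network with analytic backprop.

The two survival networks in this package are small (a single linear layer,
or an MLP with one or two modest hidden layers), so forward/backward passes
are written directly in numpy and optimised with full-batch Adam.  The loss
is supplied as a callable returning ``(value, d_loss/d_output)`` so the same
machinery trains both the RMSE and the partial-likelihood heads.
"""

from __future__ import annotations

import numpy as np


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DenseNet:
    """Fully connected network: ReLU hidden layers, optional sigmoid head."""

    def __init__(self, n_inputs: int, hidden_sizes, n_outputs: int,
                 sigmoid_head: bool = False, seed: int = 0):
        self.sizes = [int(n_inputs), *map(int, hidden_sizes), int(n_outputs)]
        self.sigmoid_head = bool(sigmoid_head)
        rng = np.random.default_rng(seed)
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            # He-style scaling keeps pre-activations O(1) under ReLU
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- passes ------------------------------------------------------------

    def forward(self, x: np.ndarray):
        """Return the output and the per-layer cache needed for backward."""
        activations = [x]
        pre = []
        a = x
        last = len(self.weights) - 1
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            pre.append(z)
            if layer < last:
                a = np.maximum(z, 0.0)
            else:
                a = _sigmoid(z) if self.sigmoid_head else z
            activations.append(a)
        return activations[-1], (activations, pre)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=float))[0]

    def backward(self, cache, d_out: np.ndarray):
        """Gradients of the loss w.r.t. every weight and bias."""
        activations, pre = cache
        last = len(self.weights) - 1
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        if self.sigmoid_head:
            out = activations[-1]
            delta = d_out * out * (1.0 - out)
        else:
            delta = d_out
        for layer in range(last, -1, -1):
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (pre[layer - 1] > 0.0)
        return grads_w, grads_b

    # -- parameter vector helpers -----------------------------------------

    def get_params(self):
        return [w.copy() for w in self.weights], [b.copy() for b in self.biases]

    def set_params(self, weights, biases):
        self.weights = [np.asarray(w, dtype=float).copy() for w in weights]
        self.biases = [np.asarray(b, dtype=float).copy() for b in biases]


def train_adam(net: DenseNet, x: np.ndarray, loss_grad_fn, epochs: int = 1000,
               learning_rate: float = 1e-3, l2_penalty: float = 0.0,
               batch_size: int | None = None, seed: int = 0):
    """Train ``net`` with (full- or mini-batch) Adam; returns the loss history.

    ``loss_grad_fn(outputs, index)`` must return the scalar loss for the rows
    in ``index`` and its gradient w.r.t. those outputs.  A non-finite loss
    aborts with a :class:`TrainingError` naming the epoch.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in net.weights]
    v_w = [np.zeros_like(w) for w in net.weights]
    m_b = [np.zeros_like(b) for b in net.biases]
    v_b = [np.zeros_like(b) for b in net.biases]
    step = 0
    history = []
    all_idx = np.arange(n)
    for epoch in range(epochs):
        if batch_size is None or batch_size >= n:
            batches = [all_idx]
        else:
            order = rng.permutation(n)
            batches = [order[i:i + batch_size] for i in range(0, n, batch_size)]
        epoch_loss = 0.0
        for index in batches:
            out, cache = net.forward(x[index])
            loss, d_out = loss_grad_fn(out, index)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += float(loss) * len(index)
            grads_w, grads_b = net.backward(cache, d_out)
            step += 1
            for layer in range(len(net.weights)):
                g_w = grads_w[layer] + l2_penalty * net.weights[layer]
                g_b = grads_b[layer]
                m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * g_w
                v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * g_w**2
                m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * g_b
                v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * g_b**2
                corr1 = 1 - beta1**step
                corr2 = 1 - beta2**step
                net.weights[layer] -= learning_rate * (m_w[layer] / corr1) / (
                    np.sqrt(v_w[layer] / corr2) + eps
                )
                net.biases[layer] -= learning_rate * (m_b[layer] / corr1) / (
                    np.sqrt(v_b[layer] / corr2) + eps
                )
        history.append(epoch_loss / n)
    return history
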