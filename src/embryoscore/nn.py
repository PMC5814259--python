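"""Minimal dense feed-forward networks trained with Adam.

Supports the architectures used here: 1+ hidden layers with ReLU / sigmoid
/ tanh activation, inverted dropout after each hidden activation, L2 weight
decay, and either a single sigmoid output unit (binary pairwise networks)
or a softmax output (multiclass).  Pure numpy; deterministic for a fixed
seed.  Weight matrices are exposed for importance propagation.
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, h: (z > 0).astype(z.dtype)),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
        lambda z, h: h * (1.0 - h),
    ),
    "tanh": (np.tanh, lambda z, h: 1.0 - h * h),
}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class DenseNetwork:
    """Feed-forward network; ``output`` is ``"sigmoid"`` or ``"softmax"``.

    Parameters mirror the hyperparameters tuned for the classifiers:
    ``hidden_layers`` x ``neurons_per_layer`` architecture, hidden
    ``activation``, ``dropout`` rate in [0, 1), L2 strength, epoch count,
    Adam learning rate and minibatch size.
    """

    def __init__(
        self,
        n_inputs: int,
        n_outputs: int,
        hidden_layers: int = 2,
        neurons_per_layer: int = 200,
        activation: str = "relu",
        dropout: float = 0.2,
        l2_strength: float = 0.03,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        output: str = "sigmoid",
        seed: int = 0,
    ):
        if hidden_layers < 1:
            raise ValueError("hidden_layers must be >= 1")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        if activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {sorted(_ACTIVATIONS)}")
        if output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.activation = activation
        self.dropout = dropout
        self.l2_strength = l2_strength
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.output = output
        self.seed = seed
        self._init_weights()

    def _init_weights(self) -> None:
        rng = np.random.default_rng(self.seed)
        sizes = [self.n_inputs] + [self.neurons_per_layer] * self.hidden_layers + [self.n_outputs]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization; appropriate for ReLU and harmless otherwise
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self._rng = rng

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool = False):
        act, _ = _ACTIVATIONS[self.activation]
        a = X
        zs, acts, masks = [], [a], []
        for layer in range(self.hidden_layers):
            z = a @ self.weights[layer] + self.biases[layer]
            h = act(z)
            if train and self.dropout > 0:
                mask = (self._rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            else:
                mask = None
            zs.append(z)
            acts.append(h)
            masks.append(mask)
            a = h
        z_out = a @ self.weights[-1] + self.biases[-1]
        p = _sigmoid(z_out) if self.output == "sigmoid" else _softmax(z_out)
        return p, zs, acts, masks

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Inference pass (dropout off)."""
        return self._forward(self._standardize(np.asarray(X, dtype=float)), train=False)[0]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if getattr(self, "input_mean_", None) is None:
            return X
        return (X - self.input_mean_) / self.input_scale_

    # ------------------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "DenseNetwork":
        """Minimize cross-entropy + L2 with Adam minibatches.

        ``y`` is a 0/1 vector for sigmoid output or integer class indices
        for softmax output.
        """
        X = np.asarray(X, dtype=float)
        # standardize inputs once per fit: expression scales (log2 intensities
        # around 8) otherwise saturate the sigmoid/softmax at initialization
        self.input_mean_ = X.mean(axis=0)
        self.input_scale_ = np.maximum(X.std(axis=0), 1e-8)
        X = self._standardize(X)
        n = X.shape[0]
        if self.output == "softmax":
            Y = np.zeros((n, self.n_outputs))
            Y[np.arange(n), np.asarray(y, dtype=int)] = 1.0
        else:
            Y = np.asarray(y, dtype=float).reshape(n, self.n_outputs)

        _, dact = _ACTIVATIONS[self.activation]
        m_w = [np.zeros_like(w) for w in self.weights]
        v_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        v_b = [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _epoch in range(self.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], Y[idx]
                p, zs, acts, masks = self._forward(xb, train=True)
                # cross-entropy gradient at the output pre-activation
                delta = (p - yb) / len(idx)
                grads_w, grads_b = [None] * len(self.weights), [None] * len(self.biases)
                for layer in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[layer]
                    grads_w[layer] = a_prev.T @ delta + self.l2_strength * self.weights[layer]
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights[layer].T
                        if masks[layer - 1] is not None:
                            delta = delta * masks[layer - 1]
                        delta = delta * dact(zs[layer - 1], _ACTIVATIONS[self.activation][0](zs[layer - 1]))
                t += 1
                lr_t = self.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                for layer in range(len(self.weights)):
                    m_w[layer] = beta1 * m_w[layer] + (1 - beta1) * grads_w[layer]
                    v_w[layer] = beta2 * v_w[layer] + (1 - beta2) * grads_w[layer] ** 2
                    self.weights[layer] -= lr_t * m_w[layer] / (np.sqrt(v_w[layer]) + eps)
                    m_b[layer] = beta1 * m_b[layer] + (1 - beta1) * grads_b[layer]
                    v_b[layer] = beta2 * v_b[layer] + (1 - beta2) * grads_b[layer] ** 2
                    self.biases[layer] -= lr_t * m_b[layer] / (np.sqrt(v_b[layer]) + eps)
        return self

    # ------------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.weights]

    def state_dict(self) -> dict:
        state = {"config": {
            "n_inputs": self.n_inputs, "n_outputs": self.n_outputs,
            "hidden_layers": self.hidden_layers, "neurons_per_layer": self.neurons_per_layer,
            "activation": self.activation, "dropout": self.dropout,
            "l2_strength": self.l2_strength, "epochs": self.epochs,
            "learning_rate": self.learning_rate, "batch_size": self.batch_size,
            "output": self.output, "seed": self.seed,
        }}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            state[f"W{i}"] = w
            state[f"b{i}"] = b
        if getattr(self, "input_mean_", None) is not None:
            state["input_mean"] = self.input_mean_
            state["input_scale"] = self.input_scale_
        return state

    @classmethod
    def from_state_dict(cls, state: dict) -> "DenseNetwork":
        net = cls(**state["config"])
        i = 0
        while f"W{i}" in state:
            net.weights[i] = np.asarray(state[f"W{i}"], dtype=float)
            net.biases[i] = np.asarray(state[f"b{i}"], dtype=float)
            i += 1
        if "input_mean" in state:
            net.input_mean_ = np.asarray(state["input_mean"], dtype=float)
            net.input_scale_ = np.asarray(state["input_scale"], dtype=float)
        return net
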