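"""Feedforward DNN speaker verifier (target vs non-target) in NumPy.

Architecture: 60-d LFCC input -> repeated [affine -> batch norm -> ReLU]
blocks (default widths 128, 64, 32) -> affine -> softmax over the two
classes (target, non_target). Trained with mini-batch backpropagation,
cross-entropy loss and Adam; batch normalization uses batch statistics
during fitting and frozen running statistics at inference. Every model
is a pure function of (data, config): the config seed drives weight
initialization and batch shuffling and nothing else is stochastic.

The network is written out explicitly (forward, backward, Adam) so the
analytic gradients are available for verification against finite
differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

INPUT_DIM = 60
CLASSES = ("target", "non_target")
BN_EPS = 1e-5
BN_MOMENTUM = 0.1  # fraction of the batch statistic folded into running


@dataclass(frozen=True)
class VerifierConfig:
    """Training hyperparameters.

    ``iterations`` counts full passes over the training set (epochs);
    Adam runs with its standard defaults.
    """

    hidden_layout: tuple[int, ...] = (128, 64, 32)
    iterations: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class Prediction:
    p_target: float
    p_non_target: float


@dataclass
class VerificationModel:
    """Trained weights plus frozen batch-norm statistics."""

    weights: list[np.ndarray]  # per affine layer
    biases: list[np.ndarray]
    bn_gamma: list[np.ndarray]  # per hidden block
    bn_beta: list[np.ndarray]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    classes: tuple[str, str] = CLASSES
    final_loss: float = float("nan")

    @property
    def n_hidden(self) -> int:
        return len(self.bn_gamma)

    def save(self, path: str) -> None:
        blob = {"classes": list(self.classes),
                "final_loss": self.final_loss,
                "arrays": {}}
        for name in ("weights", "biases", "bn_gamma", "bn_beta",
                     "bn_mean", "bn_var"):
            blob["arrays"][name] = [a.tolist() for a in getattr(self, name)]
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "VerificationModel":
        with open(path) as fh:
            blob = json.load(fh)
        kw = {name: [np.asarray(a, dtype=np.float64) for a in arrs]
              for name, arrs in blob["arrays"].items()}
        return cls(classes=tuple(blob["classes"]),
                   final_loss=blob["final_loss"], **kw)


def _init_params(layout: tuple[int, ...],
                 rng: np.random.Generator) -> VerificationModel:
    dims = (INPUT_DIM, *layout, len(CLASSES))
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return VerificationModel(
        weights=weights, biases=biases,
        bn_gamma=[np.ones(w) for w in layout],
        bn_beta=[np.zeros(w) for w in layout],
        bn_mean=[np.zeros(w) for w in layout],
        bn_var=[np.ones(w) for w in layout])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _labels_to_onehot(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        is_target = labels
    else:
        is_target = labels == CLASSES[0]
    onehot = np.zeros((labels.size, 2))
    onehot[np.arange(labels.size), np.where(is_target, 0, 1)] = 1.0
    return onehot


def loss_and_grads(model: VerificationModel, X: np.ndarray,
                   onehot: np.ndarray,
                   update_running: bool = False):
    """Train-mode forward pass + analytic backward pass.

    Returns ``(loss, grads)`` where ``grads`` mirrors the trainable
    arrays: ``dict(weights=[...], biases=[...], bn_gamma=[...],
    bn_beta=[...])``. Batch statistics are computed from ``X``; when
    ``update_running`` the model's running mean/var are updated in place
    (the only mutation, used during fitting).
    """
    n = X.shape[0]
    h = X
    cache = []
    for k in range(model.n_hidden):
        z = h @ model.weights[k] + model.biases[k]
        mu = z.mean(axis=0)
        var = z.var(axis=0)
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        zhat = (z - mu) * inv_std
        a = model.bn_gamma[k] * zhat + model.bn_beta[k]
        r = np.maximum(a, 0.0)
        cache.append((h, z, zhat, inv_std, a, r))
        if update_running:
            model.bn_mean[k] *= 1.0 - BN_MOMENTUM
            model.bn_mean[k] += BN_MOMENTUM * mu
            model.bn_var[k] *= 1.0 - BN_MOMENTUM
            model.bn_var[k] += BN_MOMENTUM * var
        h = r
    logits = h @ model.weights[-1] + model.biases[-1]
    probs = _softmax(logits)
    loss = -np.mean(np.sum(onehot * np.log(np.maximum(probs, 1e-300)),
                           axis=1))

    grads = {"weights": [None] * len(model.weights),
             "biases": [None] * len(model.biases),
             "bn_gamma": [None] * model.n_hidden,
             "bn_beta": [None] * model.n_hidden}
    dlogits = (probs - onehot) / n
    grads["weights"][-1] = cache[-1][5].T @ dlogits if cache else X.T @ dlogits
    grads["biases"][-1] = dlogits.sum(axis=0)
    dh = dlogits @ model.weights[-1].T
    for k in range(model.n_hidden - 1, -1, -1):
        h_in, z, zhat, inv_std, a, _ = cache[k]
        da = dh * (a > 0)
        grads["bn_gamma"][k] = np.sum(da * zhat, axis=0)
        grads["bn_beta"][k] = np.sum(da, axis=0)
        dzhat = da * model.bn_gamma[k]
        # batch-norm backward (batch statistics are functions of z)
        dz = (inv_std / n) * (n * dzhat - dzhat.sum(axis=0)
                              - zhat * np.sum(dzhat * zhat, axis=0))
        grads["weights"][k] = h_in.T @ dz
        grads["biases"][k] = dz.sum(axis=0)
        dh = dz @ model.weights[k].T
    return loss, grads


def train(X: np.ndarray, labels, config: VerifierConfig) -> VerificationModel:
    """Fit the verifier by mini-batch Adam for ``config.iterations`` epochs.

    ``labels`` is either a boolean array (True = target) or an array of
    the strings "target"/"non_target"; both classes must be present.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != INPUT_DIM:
        raise ValueError(f"features must be (n, {INPUT_DIM}), got {X.shape}")
    onehot = _labels_to_onehot(labels)
    if onehot[:, 0].sum() == 0 or onehot[:, 1].sum() == 0:
        raise ValueError("training data must contain both classes")

    rng = np.random.default_rng(config.seed)
    model = _init_params(config.hidden_layout, rng)
    trainable = ("weights", "biases", "bn_gamma", "bn_beta")
    m_state = {t: [np.zeros_like(a) for a in getattr(model, t)]
               for t in trainable}
    v_state = {t: [np.zeros_like(a) for a in getattr(model, t)]
               for t in trainable}
    t_step = 0
    n = X.shape[0]
    loss = float("nan")
    for _ in range(config.iterations):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            loss, grads = loss_and_grads(model, X[batch], onehot[batch],
                                         update_running=True)
            t_step += 1
            bc1 = 1.0 - config.beta1**t_step
            bc2 = 1.0 - config.beta2**t_step
            for t in trainable:
                params = getattr(model, t)
                for i, g in enumerate(grads[t]):
                    m_state[t][i] = (config.beta1 * m_state[t][i]
                                     + (1 - config.beta1) * g)
                    v_state[t][i] = (config.beta2 * v_state[t][i]
                                     + (1 - config.beta2) * g * g)
                    params[i] -= (config.learning_rate
                                  * (m_state[t][i] / bc1)
                                  / (np.sqrt(v_state[t][i] / bc2)
                                     + config.adam_eps))
    model.final_loss = float(loss)
    return model


def predict_proba(model: VerificationModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities ``(n, 2)`` in the model's class order.

    Inference mode: batch norm uses the frozen running statistics, so
    predicting is a pure function and never mutates the model.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != INPUT_DIM:
        raise ValueError(f"features must be (n, {INPUT_DIM}), got {X.shape}")
    h = X
    for k in range(model.n_hidden):
        z = h @ model.weights[k] + model.biases[k]
        zhat = (z - model.bn_mean[k]) / np.sqrt(model.bn_var[k] + BN_EPS)
        h = np.maximum(model.bn_gamma[k] * zhat + model.bn_beta[k], 0.0)
    return _softmax(h @ model.weights[-1] + model.biases[-1])


def predict(model: VerificationModel, X: np.ndarray) -> list[Prediction]:
    probs = predict_proba(model, X)
    return [Prediction(p_target=float(p[0]), p_non_target=float(p[1]))
            for p in probs]


def ensemble_seeds(master_seed: int, n_models: int) -> list[int]:
    """Distinct, reproducible per-model seeds derived from a master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_models)
    return [int(s % (2**31 - 1)) for s in state]


def train_ensemble(X: np.ndarray, labels, base_config: VerifierConfig,
                   n_models: int = 5) -> list[VerificationModel]:
    """Train ``n_models`` verifiers differing only in their derived seeds.

    Mirrors the protocol of averaging verification accuracy over several
    models that differ in weight initialization and mini-batch sampling.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return [train(X, labels, replace(base_config, seed=s))
            for s in ensemble_seeds(base_config.seed, n_models)]
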