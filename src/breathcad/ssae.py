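"""Stacked sparse autoencoder with KL sparsity penalty, softmax head, fine-tuning.

The objective of one sparse autoencoder over a batch X (n samples, d inputs,
h hidden units, logistic activations everywhere) is

    J(W, b, W', b') = (1/n) sum_i 1/2 ||x_i - x̂_i||^2
                    + alpha * sum_j KL(p || rho_j)
                    + beta * (||W||_F^2 + ||W'||_F^2)

where rho_j is the mean activation of hidden unit j over the batch,
KL(p||rho) = p log(p/rho) + (1-p) log((1-p)/(1-rho)) is the Bernoulli
Kullback-Leibler divergence pulling mean activations toward the small sparsity
target p, and beta is the weight-decay coefficient (biases excluded).
Gradients are analytic (backpropagation, including the KL term's dependence on
rho through every sample) and are verified against finite differences in the
test suite.

Layers are pretrained greedily on unlabeled data, a softmax head is trained on
the top codes, and the assembled encoder stack plus head is fine-tuned jointly
on labeled data with cross-entropy (decoders discarded).  Optimization is plain
full-batch gradient descent throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

logger = logging.getLogger(__name__)

__all__ = [
    "AutoencoderParams",
    "SAEHyperparams",
    "SoftmaxParams",
    "SoftmaxHyperparams",
    "FineTuneHyperparams",
    "SSAEModel",
    "TrainingTrace",
    "encode",
    "decode",
    "reconstruct",
    "average_activation",
    "kl_divergence",
    "weight_decay_term",
    "sae_cost",
    "sae_gradient",
    "train_sae",
    "stack_train",
    "softmax_predict",
    "softmax_cost_grad",
    "train_softmax",
    "finetune_cost_grad",
    "fine_tune",
    "predict",
    "SSAEClassifier",
]

_EPS = 1e-8


# ---------------------------------------------------------------------------
# Parameter containers.
# ---------------------------------------------------------------------------

@dataclass
class AutoencoderParams:
    """Encoder (W: h x d, b: h) and decoder (W_dec: d x h, b_dec: d) weights."""

    W: np.ndarray
    b: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.W_dec = np.asarray(self.W_dec, dtype=float)
        self.b_dec = np.asarray(self.b_dec, dtype=float)
        h, d = self.W.shape
        if self.b.shape != (h,) or self.W_dec.shape != (d, h) or self.b_dec.shape != (d,):
            raise ValueError("inconsistent autoencoder parameter shapes")
        for arr in (self.W, self.b, self.W_dec, self.b_dec):
            if not np.all(np.isfinite(arr)):
                raise ValueError("autoencoder parameters must be finite")

    @property
    def d(self) -> int:
        return self.W.shape[1]

    @property
    def h(self) -> int:
        return self.W.shape[0]

    def copy(self) -> "AutoencoderParams":
        return AutoencoderParams(self.W.copy(), self.b.copy(),
                                 self.W_dec.copy(), self.b_dec.copy())


@dataclass
class SAEHyperparams:
    """Pretraining hyperparameters (sparsity target 0.05, weight 4, lr 0.001)."""

    hidden_size: int = 100
    sparsity_target: float = 0.05
    sparsity_weight: float = 4.0
    weight_decay: float = 1e-4
    learning_rate: float = 0.001
    epochs: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must be in (0, 1)")
        if self.sparsity_weight < 0 or self.weight_decay < 0:
            raise ValueError("sparsity_weight and weight_decay must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


@dataclass
class SoftmaxParams:
    """Softmax head weights: W (C x h) and bias b (C,)."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("inconsistent softmax parameter shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("softmax parameters must be finite")

    def copy(self) -> "SoftmaxParams":
        return SoftmaxParams(self.W.copy(), self.b.copy())


@dataclass
class SoftmaxHyperparams:
    learning_rate: float = 0.5
    epochs: int = 500
    l2: float = 1e-4
    seed: int = 0


@dataclass
class FineTuneHyperparams:
    learning_rate: float = 0.5
    epochs: int = 500
    weight_decay: float = 0.0


@dataclass
class TrainingTrace:
    """Per-epoch cost decomposition (pretraining) or cross-entropy (fine-tuning)."""

    total: list[float] = field(default_factory=list)
    reconstruction: list[float] = field(default_factory=list)
    sparsity: list[float] = field(default_factory=list)
    weight_decay: list[float] = field(default_factory=list)
    cross_entropy: list[float] = field(default_factory=list)


@dataclass
class SSAEModel:
    """Encoder stack + softmax head; layer i's output width feeds layer i+1."""

    layers: list[AutoencoderParams]
    softmax: SoftmaxParams
    layer_sizes: list[int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if prev.h != nxt.d:
                raise ValueError("layer output/input widths do not chain")
        if self.layers and self.softmax.W.shape[1] != self.layers[-1].h:
            raise ValueError("softmax input width must equal last hidden size")

    def copy(self) -> "SSAEModel":
        return SSAEModel([l.copy() for l in self.layers], self.softmax.copy(),
                         list(self.layer_sizes), dict(self.meta))


# ---------------------------------------------------------------------------
# Forward maps and cost terms.
# ---------------------------------------------------------------------------

def encode(x: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """z = sigmoid(W x + b); accepts a single vector or an (n, d) batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != params.d:
        raise ValueError(f"input dimension {x.shape[-1]} != encoder dimension {params.d}")
    return expit(x @ params.W.T + params.b)


def decode(z: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """x̂ = sigmoid(W' z + b')."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.h:
        raise ValueError(f"code dimension {z.shape[-1]} != decoder dimension {params.h}")
    return expit(z @ params.W_dec.T + params.b_dec)


def reconstruct(x: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    return decode(encode(x, params), params)


def average_activation(X: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """rho_j: mean activation of each hidden unit over the batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    return encode(X, params).mean(axis=0)


def kl_divergence(p, rho_hat, eps: float = _EPS):
    """Bernoulli KL(p || rho_hat), natural log; arguments clamped to [eps, 1-eps]."""
    p_arr = np.asarray(p, dtype=float)
    r_arr = np.asarray(rho_hat, dtype=float)
    if np.any((r_arr <= 0) | (r_arr >= 1)) or np.any((p_arr <= 0) | (p_arr >= 1)):
        logger.warning("kl_divergence: arguments clamped to [%g, %g]", eps, 1 - eps)
    p_c = np.clip(p_arr, eps, 1 - eps)
    r_c = np.clip(r_arr, eps, 1 - eps)
    out = p_c * np.log(p_c / r_c) + (1 - p_c) * np.log((1 - p_c) / (1 - r_c))
    return float(out) if np.isscalar(p) and np.isscalar(rho_hat) else out


def weight_decay_term(*weights: np.ndarray) -> float:
    """Sum of squared entries, tr(W^T W), over the given weight matrices."""
    return float(sum(np.sum(np.square(np.asarray(W, dtype=float))) for W in weights))


def sae_cost(X: np.ndarray, params: AutoencoderParams,
             hyper: SAEHyperparams) -> tuple[float, tuple[float, float, float]]:
    """Total cost and its (reconstruction, sparsity, weight-decay) components."""
    hyper.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    A = encode(X, params)
    Xhat = decode(A, params)
    recon = 0.5 * float(np.sum((X - Xhat) ** 2)) / n
    rho = A.mean(axis=0)
    sparsity = hyper.sparsity_weight * float(
        np.sum(kl_divergence(hyper.sparsity_target, rho)))
    decay = hyper.weight_decay * weight_decay_term(params.W, params.W_dec)
    return recon + sparsity + decay, (recon, sparsity, decay)


def sae_gradient(X: np.ndarray, params: AutoencoderParams,
                 hyper: SAEHyperparams) -> AutoencoderParams:
    """Analytic gradients of :func:`sae_cost`, same shapes as ``params``."""
    hyper.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    A = encode(X, params)                       # (n, h)
    Xhat = decode(A, params)                    # (n, d)

    delta_out = (Xhat - X) * Xhat * (1.0 - Xhat) / n
    gW_dec = delta_out.T @ A + 2.0 * hyper.weight_decay * params.W_dec
    gb_dec = delta_out.sum(axis=0)

    rho = np.clip(A.mean(axis=0), _EPS, 1.0 - _EPS)
    p = hyper.sparsity_target
    # d(sparsity)/d(a_ij) routed through rho_j = mean_i a_ij
    sparse_back = hyper.sparsity_weight * (-p / rho + (1.0 - p) / (1.0 - rho)) / n
    delta_hid = (delta_out @ params.W_dec + sparse_back) * A * (1.0 - A)
    gW = delta_hid.T @ X + 2.0 * hyper.weight_decay * params.W
    gb = delta_hid.sum(axis=0)
    return AutoencoderParams(gW, gb, gW_dec, gb_dec)


# ---------------------------------------------------------------------------
# Training.
# ---------------------------------------------------------------------------

def _glorot_init(d: int, h: int, rng: np.random.Generator) -> AutoencoderParams:
    r = np.sqrt(6.0 / (d + h))
    return AutoencoderParams(W=rng.uniform(-r, r, size=(h, d)),
                             b=np.zeros(h),
                             W_dec=rng.uniform(-r, r, size=(d, h)),
                             b_dec=np.zeros(d))


def train_sae(X: np.ndarray, hyper: SAEHyperparams) -> tuple[AutoencoderParams, TrainingTrace]:
    """Full-batch gradient descent on the sparse-autoencoder objective."""
    hyper.validate()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    rng = np.random.default_rng(hyper.seed)
    params = _glorot_init(X.shape[1], hyper.hidden_size, rng)
    trace = TrainingTrace()
    lr = hyper.learning_rate
    for epoch in range(hyper.epochs):
        total, (recon, sparsity, decay) = sae_cost(X, params, hyper)
        if not np.isfinite(total):
            raise RuntimeError(
                f"non-finite cost at epoch {epoch}: recon={recon}, "
                f"sparsity={sparsity}, decay={decay}")
        trace.total.append(total)
        trace.reconstruction.append(recon)
        trace.sparsity.append(sparsity)
        trace.weight_decay.append(decay)
        if lr == 0.0:
            continue
        g = sae_gradient(X, params, hyper)
        params = AutoencoderParams(params.W - lr * g.W, params.b - lr * g.b,
                                   params.W_dec - lr * g.W_dec,
                                   params.b_dec - lr * g.b_dec)
    return params, trace


def stack_train(X: np.ndarray, layer_sizes: Sequence[int],
                hyper: SAEHyperparams | Sequence[SAEHyperparams]) -> list[AutoencoderParams]:
    """Greedy layer-wise pretraining: each layer trains on the previous codes.

    Unsupervised throughout — labels are never consulted.  Per-layer seeds are
    derived deterministically from the base hyperparameter seed.
    """
    if not layer_sizes:
        raise ValueError("layer_sizes must be nonempty")
    if isinstance(hyper, SAEHyperparams):
        hypers = []
        for i, h in enumerate(layer_sizes):
            child = int(np.random.SeedSequence([hyper.seed, i]).generate_state(1)[0] % 2**31)
            hypers.append(SAEHyperparams(hidden_size=h,
                                         sparsity_target=hyper.sparsity_target,
                                         sparsity_weight=hyper.sparsity_weight,
                                         weight_decay=hyper.weight_decay,
                                         learning_rate=hyper.learning_rate,
                                         epochs=hyper.epochs, seed=child))
    else:
        hypers = list(hyper)
        if len(hypers) != len(layer_sizes):
            raise ValueError("one SAEHyperparams per layer required")
        for hp, size in zip(hypers, layer_sizes):
            hp.hidden_size = size
    layers: list[AutoencoderParams] = []
    codes = np.atleast_2d(np.asarray(X, dtype=float))
    for hp in hypers:
        params, _trace = train_sae(codes, hp)
        layers.append(params)
        codes = encode(codes, params)
    return layers


# ---------------------------------------------------------------------------
# Softmax head.
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_predict(z: np.ndarray, params: SoftmaxParams) -> np.ndarray:
    """Class probabilities softmax(W z + b); rows sum to 1."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != params.W.shape[1]:
        raise ValueError(f"code dimension {z.shape[-1]} != softmax input "
                         f"{params.W.shape[1]}")
    return _softmax(z @ params.W.T + params.b)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    Y = np.zeros((labels.size, n_classes))
    Y[np.arange(labels.size), labels] = 1.0
    return Y


def softmax_cost_grad(Z: np.ndarray, labels: np.ndarray, params: SoftmaxParams,
                      l2: float) -> tuple[float, SoftmaxParams]:
    """Mean cross-entropy + l2*||W||^2 and its analytic gradient."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n, C = Z.shape[0], params.W.shape[0]
    P = softmax_predict(Z, params)
    ce = -float(np.mean(np.log(np.clip(P[np.arange(n), labels], _EPS, None))))
    cost = ce + l2 * weight_decay_term(params.W)
    G = (P - _one_hot(labels, C)) / n
    return cost, SoftmaxParams(G.T @ Z + 2.0 * l2 * params.W, G.sum(axis=0))


def train_softmax(Z: np.ndarray, labels: np.ndarray,
                  hyper: SoftmaxHyperparams | None = None,
                  n_classes: int = 3) -> SoftmaxParams:
    """Gradient descent on L2-penalized multiclass cross-entropy (zero init)."""
    hyper = hyper or SoftmaxHyperparams()
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("softmax training needs at least two represented classes")
    params = SoftmaxParams(np.zeros((n_classes, Z.shape[1])), np.zeros(n_classes))
    for _ in range(hyper.epochs):
        _cost, grad = softmax_cost_grad(Z, labels, params, hyper.l2)
        params = SoftmaxParams(params.W - hyper.learning_rate * grad.W,
                               params.b - hyper.learning_rate * grad.b)
    return params


# ---------------------------------------------------------------------------
# Fine-tuning (supervised backprop through the whole encoder stack + head).
# ---------------------------------------------------------------------------

def finetune_cost_grad(model: SSAEModel, X: np.ndarray, labels: np.ndarray,
                       weight_decay: float = 0.0):
    """Cross-entropy (+ optional decay on all weight matrices) and gradients.

    Returns ``(cost, layer_grads, softmax_grad)`` where ``layer_grads`` holds
    encoder-weight gradients (decoder entries zero — decoders are frozen out).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels, dtype=int)
    n = X.shape[0]
    C = model.softmax.W.shape[0]

    activations = [X]
    for layer in model.layers:
        activations.append(encode(activations[-1], layer))
    P = softmax_predict(activations[-1], model.softmax)
    ce = -float(np.mean(np.log(np.clip(P[np.arange(n), labels], _EPS, None))))
    cost = ce + weight_decay * weight_decay_term(
        model.softmax.W, *(l.W for l in model.layers))

    delta = (P - _one_hot(labels, C)) / n
    softmax_grad = SoftmaxParams(
        delta.T @ activations[-1] + 2.0 * weight_decay * model.softmax.W,
        delta.sum(axis=0))
    back = delta @ model.softmax.W
    layer_grads: list[AutoencoderParams] = [None] * len(model.layers)  # type: ignore
    for i in range(len(model.layers) - 1, -1, -1):
        A = activations[i + 1]
        delta_i = back * A * (1.0 - A)
        layer = model.layers[i]
        layer_grads[i] = AutoencoderParams(
            delta_i.T @ activations[i] + 2.0 * weight_decay * layer.W,
            delta_i.sum(axis=0),
            np.zeros_like(layer.W_dec), np.zeros_like(layer.b_dec))
        back = delta_i @ layer.W
    return cost, layer_grads, softmax_grad


def fine_tune(model: SSAEModel, X: np.ndarray, labels: np.ndarray,
              hyper: FineTuneHyperparams | None = None) -> tuple[SSAEModel, TrainingTrace]:
    """Joint supervised training of encoder stack + softmax head."""
    hyper = hyper or FineTuneHyperparams()
    model = model.copy()
    trace = TrainingTrace()
    lr = hyper.learning_rate
    for epoch in range(hyper.epochs):
        cost, layer_grads, softmax_grad = finetune_cost_grad(
            model, X, labels, hyper.weight_decay)
        if not np.isfinite(cost):
            raise RuntimeError(f"non-finite fine-tuning cost at epoch {epoch}")
        trace.cross_entropy.append(cost)
        if lr == 0.0:
            continue
        for layer, g in zip(model.layers, layer_grads):
            layer.W -= lr * g.W
            layer.b -= lr * g.b
        model.softmax.W -= lr * softmax_grad.W
        model.softmax.b -= lr * softmax_grad.b
    return model, trace


def predict(model: SSAEModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities); argmax with ties broken toward the lowest code."""
    H = np.atleast_2d(np.asarray(X, dtype=float))
    if H.shape[1] != model.layers[0].d:
        raise ValueError(f"feature dimension {H.shape[1]} != model input "
                         f"{model.layers[0].d}")
    for layer in model.layers:
        H = encode(H, layer)
    probs = softmax_predict(H, model.softmax)
    return np.argmax(probs, axis=1), probs


# ---------------------------------------------------------------------------
# sklearn estimator wrapper.
# ---------------------------------------------------------------------------

class SSAEClassifier(BaseEstimator, ClassifierMixin):
    """Deep stacked sparse autoencoder classifier with greedy pretraining.

    ``fit`` pretrains one sparse autoencoder per entry of ``hidden_layer_sizes``
    on the (unlabeled) training features, trains a softmax head on the top-layer
    codes, then fine-tunes the assembled network with labels.  Defaults mirror
    the published configuration: hidden sizes (100, 40), sparsity target 0.05,
    sparsity weight 4, pretraining learning rate 0.001 for 1000 epochs.
    """

    def __init__(self,
                 hidden_layer_sizes: tuple[int, ...] = (100, 40),
                 sparsity_target: float = 0.05,
                 sparsity_weight: float = 4.0,
                 weight_decay: float = 1e-4,
                 learning_rate: float = 0.001,
                 pretrain_epochs: int = 1000,
                 softmax_learning_rate: float = 0.5,
                 softmax_epochs: int = 500,
                 finetune_learning_rate: float = 0.5,
                 finetune_epochs: int = 500,
                 random_state: int = 0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.sparsity_target = sparsity_target
        self.sparsity_weight = sparsity_weight
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.pretrain_epochs = pretrain_epochs
        self.softmax_learning_rate = softmax_learning_rate
        self.softmax_epochs = softmax_epochs
        self.finetune_learning_rate = finetune_learning_rate
        self.finetune_epochs = finetune_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        base = SAEHyperparams(sparsity_target=self.sparsity_target,
                              sparsity_weight=self.sparsity_weight,
                              weight_decay=self.weight_decay,
                              learning_rate=self.learning_rate,
                              epochs=self.pretrain_epochs,
                              seed=int(self.random_state))
        layers = stack_train(X, list(self.hidden_layer_sizes), base)
        codes = X
        for layer in layers:
            codes = encode(codes, layer)
        softmax = train_softmax(
            codes, y_idx,
            SoftmaxHyperparams(learning_rate=self.softmax_learning_rate,
                               epochs=self.softmax_epochs,
                               seed=int(self.random_state)),
            n_classes=self.classes_.size)
        model = SSAEModel(layers, softmax, list(self.hidden_layer_sizes))
        pre_ce, _, _ = finetune_cost_grad(model, X, y_idx)
        self.model_, self.finetune_trace_ = fine_tune(
            model, X, y_idx,
            FineTuneHyperparams(learning_rate=self.finetune_learning_rate,
                                epochs=self.finetune_epochs))
        self.pre_finetune_cross_entropy_ = pre_ce
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, "
                             f"got {X.shape[1]}")
        _, probs = predict(self.model_, X)
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]
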