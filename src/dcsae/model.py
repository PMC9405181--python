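"""Deep canonically correlated sparse autoencoder (DCSAE).

Two encoder/decoder networks f and g embed two views of the data; a CCA
layer on top of the encoders maximizes the canonical correlation between the
embeddings while each autoencoder keeps its embedding reconstructive and
sparse.  The training objective combines four terms:

    minimize  -(1/N) tr(U^T f(X) g(Y)^T V)                (canonical correlation)
              + (lambda/N) sum_i ||x_i_hat - x_i||^2
                          + ||y_i_hat - y_i||^2           (reconstruction)
              + alpha_s KL(rho || rho_hat)
              + beta_s  KL(sigma || sigma_hat)            (Bernoulli sparsity)

subject to the whitening constraints U^T (Sigma_11 + r_x I) U = I and
V^T (Sigma_22 + r_y I) V = I.  The correlation term and its gradient with
respect to the encoder outputs are computed in closed form from the singular
value decomposition of the whitened cross-covariance (the deep-CCA gradient);
everything else is plain backpropagation through small dense networks.

For classification the second view is, by default, the one-hot label matrix,
which makes the canonical projection U^T f(x) a discriminative embedding;
prediction assigns the nearest class centroid in that space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "DcsaeConfig",
    "DcsaeModel",
    "TwoViewBatch",
    "Mlp",
    "cca_layer",
    "kl_sparsity",
    "kl_sparsity_grad",
    "dcsae_loss",
    "train_dcsae",
    "predict",
    "make_views",
    "TrainingError",
]

_EPS = 1e-12
_ACT_CLAMP = 1e-6


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class DcsaeConfig:
    """DCSAE architecture and training settings.

    The last entry of each ``hidden_sizes_*`` list is the encoder output
    (code) dimension; ``canonical_dims`` must not exceed either code size.
    ``view_mode`` chooses the second view: ``"labels"`` pairs the features
    with one-hot class labels (supervised canonical correlation), ``"split"``
    halves the feature vector into two views.  Sparse code layers are
    sigmoid so the Bernoulli KL penalty is well defined; decoder hidden
    layers are ReLU.  ``activation="linear"`` removes all nonlinearities
    (single linear maps when the size lists have one entry), under which the
    correlation objective reduces to classical CCA.
    """

    hidden_sizes_f: tuple[int, ...] = (32, 16)
    hidden_sizes_g: tuple[int, ...] = (8,)
    canonical_dims: int | None = None
    reg_x: float = 1e-4
    reg_y: float = 1e-4
    recon_weight: float = 1.0
    sparsity_weight_f: float = 0.1
    sparsity_weight_g: float = 0.1
    sparsity_target_f: float = 0.05
    sparsity_target_g: float = 0.05
    learning_rate: float = 0.01
    epochs: int = 50
    batch_size: int | None = None
    dropout_rate: float = 0.5
    rng_seed: int = 0
    view_mode: Literal["labels", "split"] = "labels"
    activation: Literal["sigmoid", "linear"] = "sigmoid"

    def __post_init__(self) -> None:
        self.hidden_sizes_f = tuple(int(h) for h in self.hidden_sizes_f)
        self.hidden_sizes_g = tuple(int(h) for h in self.hidden_sizes_g)
        if not self.hidden_sizes_f or not self.hidden_sizes_g:
            raise ValueError("encoders need at least one layer")
        if any(h < 1 for h in self.hidden_sizes_f + self.hidden_sizes_g):
            raise ValueError("layer sizes must be positive")
        if self.canonical_dims is not None and self.canonical_dims > min(
            self.hidden_sizes_f[-1], self.hidden_sizes_g[-1]
        ):
            raise ValueError("canonical_dims exceeds an encoder code size")
        if self.reg_x <= 0 or self.reg_y <= 0:
            raise ValueError("covariance regularizers must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for t in (self.sparsity_target_f, self.sparsity_target_g):
            if not 0.0 < t < 1.0:
                raise ValueError("sparsity targets must be in (0, 1)")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")

    def resolve_canonical_dims(self, n_classes: int | None = None) -> int:
        cap = min(self.hidden_sizes_f[-1], self.hidden_sizes_g[-1])
        if self.canonical_dims is not None:
            return min(self.canonical_dims, cap)
        if n_classes is not None:
            return min(10, 2 * n_classes, cap)
        return min(10, cap)


@dataclass
class TwoViewBatch:
    """Two row-aligned views of the same samples."""

    view_x: np.ndarray
    view_y: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.view_x = np.asarray(self.view_x, dtype=float)
        self.view_y = np.asarray(self.view_y, dtype=float)
        if self.view_x.shape[0] != self.view_y.shape[0]:
            raise ValueError("views must share the sample count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != self.view_x.shape[0]:
                raise ValueError("labels must match the sample count")

    @property
    def n_samples(self) -> int:
        return self.view_x.shape[0]


def make_views(
    values: np.ndarray, labels: np.ndarray, mode: str = "labels"
) -> TwoViewBatch:
    """Build the two training views from a labelled feature matrix."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if mode == "labels":
        classes = np.unique(labels)
        onehot = (labels[:, None] == classes[None, :]).astype(float)
        return TwoViewBatch(values, onehot, labels)
    if mode == "split":
        half = values.shape[1] // 2
        if half == 0:
            raise ValueError("split view mode needs at least 2 features")
        return TwoViewBatch(values[:, :half], values[:, half:], labels)
    raise ValueError(f"unknown view mode {mode!r}")


# ---------------------------------------------------------------------------
# Dense network with manual backpropagation


class Mlp:
    """Small dense network with cached forward pass and manual backprop.

    ``activations`` is one name per layer among {"sigmoid", "relu",
    "linear"}.  Weights use scaled-uniform initialization; all randomness
    (init, dropout masks) comes from the generator handed in.
    """

    def __init__(
        self,
        sizes: tuple[int, ...],
        activations: tuple[str, ...],
        rng: np.random.Generator,
    ) -> None:
        if len(sizes) < 2 or len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        self.activations = tuple(activations)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache: dict | None = None

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Forward pass; inverted dropout on hidden layers when training."""
        inputs, pre, masks = [], [], []
        a = np.asarray(x, dtype=float)
        n_layers = len(self.weights)
        for i, (w, b, act) in enumerate(zip(self.weights, self.biases, self.activations)):
            inputs.append(a)
            z = a @ w + b
            pre.append(z)
            a = _activate(z, act)
            if train and dropout_rate > 0.0 and i < n_layers - 1:
                mask = (rng.uniform(size=a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
        if train:
            self._cache = {"inputs": inputs, "pre": pre, "masks": masks}
        return a

    def backward(self, d_out: np.ndarray) -> np.ndarray:
        """Backprop from the last cached forward; returns grad w.r.t. input."""
        if self._cache is None:
            raise RuntimeError("backward called without a training forward pass")
        self.grad_w = [np.zeros_like(w) for w in self.weights]
        self.grad_b = [np.zeros_like(b) for b in self.biases]
        da = np.asarray(d_out, dtype=float)
        for i in reversed(range(len(self.weights))):
            if self._cache["masks"][i] is not None:
                da = da * self._cache["masks"][i]
            dz = da * _activate_grad(self._cache["pre"][i], self.activations[i])
            self.grad_w[i] = self._cache["inputs"][i].T @ dz
            self.grad_b[i] = dz.sum(axis=0)
            da = dz @ self.weights[i].T
        return da

    def step(self, lr: float) -> None:
        for w, b, gw, gb in zip(self.weights, self.biases, self.grad_w, self.grad_b):
            w -= lr * gw
            b -= lr * gb


def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _activate_grad(z: np.ndarray, name: str) -> np.ndarray:
    if name == "sigmoid":
        s = _activate(z, "sigmoid")
        return s * (1.0 - s)
    if name == "relu":
        return (z > 0).astype(float)
    if name == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# CCA layer


def _inv_sqrt_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, _EPS, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def cca_layer(
    h1: np.ndarray,
    h2: np.ndarray,
    r_x: float,
    r_y: float,
    n_components: int,
    with_grad: bool = False,
) -> tuple:
    """Regularized CCA on two embedding matrices.

    Centers both N x o matrices, forms ridge-regularized covariances
    Sigma_11 = H1c^T H1c / N + r_x I (same for Sigma_22) and the
    cross-covariance Sigma_12, and takes the SVD of the whitened
    cross-covariance T = Sigma_11^{-1/2} Sigma_12 Sigma_22^{-1/2}.  The
    returned correlation is the sum of the top ``n_components`` singular
    values (in [0, n_components]); U and V are the whitened direction
    matrices satisfying U^T Sigma_11 U = I, V^T Sigma_22 V = I.

    With ``with_grad`` the closed-form gradients of the correlation with
    respect to h1 and h2 are appended to the return tuple.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    n = h1.shape[0]
    if h2.shape[0] != n:
        raise ValueError("views must share the sample count")
    if n <= n_components:
        raise ValueError(
            f"need more than n_components={n_components} samples, got {n}"
        )
    if not (np.isfinite(h1).all() and np.isfinite(h2).all()):
        raise FloatingPointError("non-finite embeddings passed to the CCA layer")
    h1c = h1 - h1.mean(axis=0)
    h2c = h2 - h2.mean(axis=0)
    s11 = h1c.T @ h1c / n + r_x * np.eye(h1.shape[1])
    s22 = h2c.T @ h2c / n + r_y * np.eye(h2.shape[1])
    s12 = h1c.T @ h2c / n
    if not (np.isfinite(s11).all() and np.isfinite(s22).all()):
        raise FloatingPointError("non-finite covariance in the CCA layer")
    s11_isq = _inv_sqrt_psd(s11)
    s22_isq = _inv_sqrt_psd(s22)
    t = s11_isq @ s12 @ s22_isq
    a, sing, bt = np.linalg.svd(t, full_matrices=False)
    k = min(n_components, sing.shape[0])
    corr = float(sing[:k].sum())
    u = s11_isq @ a[:, :k]
    v = s22_isq @ bt[:k].T
    if not with_grad:
        return corr, u, v
    # d corr / d h1 for corr = sum of top-k singular values of T
    nabla12 = u @ v.T
    nabla11 = -0.5 * u @ np.diag(sing[:k]) @ u.T
    nabla22 = -0.5 * v @ np.diag(sing[:k]) @ v.T
    g1 = (h1c @ (2.0 * nabla11) + h2c @ nabla12.T) / n
    g2 = (h2c @ (2.0 * nabla22) + h1c @ nabla12) / n
    return corr, u, v, g1, g2


# ---------------------------------------------------------------------------
# Sparsity penalty


def kl_sparsity(target: float, mean_activations: np.ndarray) -> float:
    """Bernoulli KL divergence sum_j KL(target || rho_hat_j).

    Mean activations are clamped away from {0, 1} so the logarithms stay
    finite; the result is non-negative and zero iff every unit matches the
    target.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("sparsity target must be in (0, 1)")
    rho_hat = np.clip(np.asarray(mean_activations, dtype=float), _ACT_CLAMP, 1 - _ACT_CLAMP)
    return float(
        np.sum(
            target * np.log(target / rho_hat)
            + (1.0 - target) * np.log((1.0 - target) / (1.0 - rho_hat))
        )
    )


def kl_sparsity_grad(target: float, activations: np.ndarray) -> np.ndarray:
    """Gradient of the KL penalty with respect to each activation."""
    n = activations.shape[0]
    rho_hat = np.clip(activations.mean(axis=0), _ACT_CLAMP, 1 - _ACT_CLAMP)
    d_rho = -target / rho_hat + (1.0 - target) / (1.0 - rho_hat)
    return np.broadcast_to(d_rho / n, activations.shape).copy()


# ---------------------------------------------------------------------------
# Model, loss, training, prediction


@dataclass
class DcsaeModel:
    """Trained DCSAE: networks, canonical directions, class centroids."""

    encoder_f: Mlp
    decoder_f: Mlp
    encoder_g: Mlp
    decoder_g: Mlp
    config: DcsaeConfig
    n_components: int
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    class_labels: np.ndarray | None = None
    class_centroids: np.ndarray | None = None
    training_log: list[dict] = field(default_factory=list)

    def embed(self, features: np.ndarray) -> np.ndarray:
        """Canonical-space projection U^T f(x) for each row."""
        if self.u is None:
            raise RuntimeError("model has no canonical directions; train it first")
        return self.encoder_f.forward(np.asarray(features, dtype=float)) @ self.u


def _build_networks(
    config: DcsaeConfig, d_x: int, d_y: int, rng: np.random.Generator
) -> tuple[Mlp, Mlp, Mlp, Mlp]:
    if config.activation == "linear":
        enc_act = lambda n: ("linear",) * n  # noqa: E731
        dec_hidden = "linear"
    else:
        enc_act = lambda n: ("sigmoid",) * n  # noqa: E731
        dec_hidden = "relu"
    f_sizes = (d_x, *config.hidden_sizes_f)
    g_sizes = (d_y, *config.hidden_sizes_g)
    enc_f = Mlp(f_sizes, enc_act(len(config.hidden_sizes_f)), rng)
    enc_g = Mlp(g_sizes, enc_act(len(config.hidden_sizes_g)), rng)
    df_sizes = tuple(reversed(f_sizes))
    dg_sizes = tuple(reversed(g_sizes))
    dec_f = Mlp(df_sizes, (dec_hidden,) * (len(df_sizes) - 2) + ("linear",), rng)
    dec_g = Mlp(dg_sizes, (dec_hidden,) * (len(dg_sizes) - 2) + ("linear",), rng)
    return enc_f, dec_f, enc_g, dec_g


def dcsae_loss(
    batch: TwoViewBatch, model: DcsaeModel, config: DcsaeConfig
) -> tuple[float, dict]:
    """Evaluate the combined objective and its components (no gradients)."""
    n = batch.n_samples
    h1 = model.encoder_f.forward(batch.view_x)
    h2 = model.encoder_g.forward(batch.view_y)
    corr, _, _ = cca_layer(h1, h2, config.reg_x, config.reg_y, model.n_components)
    xhat = model.decoder_f.forward(h1)
    yhat = model.decoder_g.forward(h2)
    recon_x = float(np.sum((xhat - batch.view_x) ** 2)) / n
    recon_y = float(np.sum((yhat - batch.view_y) ** 2)) / n
    sp_f = kl_sparsity(config.sparsity_target_f, h1.mean(axis=0))
    sp_g = kl_sparsity(config.sparsity_target_g, h2.mean(axis=0))
    components = {
        "correlation": corr,
        "reconstruction_x": recon_x,
        "reconstruction_y": recon_y,
        "sparsity_f": sp_f,
        "sparsity_g": sp_g,
    }
    total = (
        -corr
        + config.recon_weight * (recon_x + recon_y)
        + config.sparsity_weight_f * sp_f
        + config.sparsity_weight_g * sp_g
    )
    return total, components


def train_dcsae(train: TwoViewBatch, config: DcsaeConfig) -> DcsaeModel:
    """Full-batch gradient descent on the DCSAE objective.

    Each epoch performs one combined forward/backward pass: the deep-CCA
    correlation gradient flows into both encoders together with the
    reconstruction gradient routed back through the decoders and the KL
    sparsity gradient on the (sigmoid) code activations.  Canonical
    directions and class centroids are recomputed from the final encoder on
    the full training set.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = train.n_samples
    d_x = train.view_x.shape[1]
    d_y = train.view_y.shape[1]
    n_classes = None if train.labels is None else len(np.unique(train.labels))
    n_comp = config.resolve_canonical_dims(n_classes)
    if n <= n_comp:
        raise ValueError("need more samples than canonical dimensions")
    enc_f, dec_f, enc_g, dec_g = _build_networks(config, d_x, d_y, rng)
    model = DcsaeModel(enc_f, dec_f, enc_g, dec_g, config, n_comp)
    lam = config.recon_weight
    for epoch in range(config.epochs):
        h1 = enc_f.forward(train.view_x, train=True, dropout_rate=config.dropout_rate, rng=rng)
        h2 = enc_g.forward(train.view_y, train=True, dropout_rate=config.dropout_rate, rng=rng)
        corr, _, _, g1, g2 = cca_layer(
            h1, h2, config.reg_x, config.reg_y, n_comp, with_grad=True
        )
        xhat = dec_f.forward(h1, train=True)
        yhat = dec_g.forward(h2, train=True)
        recon_x = float(np.sum((xhat - train.view_x) ** 2)) / n
        recon_y = float(np.sum((yhat - train.view_y) ** 2)) / n
        sp_f = kl_sparsity(config.sparsity_target_f, h1.mean(axis=0))
        sp_g = kl_sparsity(config.sparsity_target_g, h2.mean(axis=0))
        total = (
            -corr
            + lam * (recon_x + recon_y)
            + config.sparsity_weight_f * sp_f
            + config.sparsity_weight_g * sp_g
        )
        if not np.isfinite(total):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        d_h1 = -g1
        d_h2 = -g2
        if lam > 0:
            d_h1 = d_h1 + dec_f.backward(2.0 * lam / n * (xhat - train.view_x))
            d_h2 = d_h2 + dec_g.backward(2.0 * lam / n * (yhat - train.view_y))
        if config.sparsity_weight_f > 0:
            d_h1 = d_h1 + config.sparsity_weight_f * kl_sparsity_grad(
                config.sparsity_target_f, h1
            )
        if config.sparsity_weight_g > 0:
            d_h2 = d_h2 + config.sparsity_weight_g * kl_sparsity_grad(
                config.sparsity_target_g, h2
            )
        enc_f.backward(d_h1)
        enc_g.backward(d_h2)
        for net in (enc_f, enc_g):
            net.step(config.learning_rate)
        if lam > 0:
            for net in (dec_f, dec_g):
                net.step(config.learning_rate)
        model.training_log.append(
            {
                "epoch": epoch,
                "total": total,
                "correlation": corr,
                "reconstruction_x": recon_x,
                "reconstruction_y": recon_y,
                "sparsity_f": sp_f,
                "sparsity_g": sp_g,
            }
        )
    # Final canonical directions and class centroids from the trained encoders.
    h1 = enc_f.forward(train.view_x)
    h2 = enc_g.forward(train.view_y)
    _, model.u, model.v = cca_layer(h1, h2, config.reg_x, config.reg_y, n_comp)
    if train.labels is not None:
        classes = np.unique(train.labels)
        z = h1 @ model.u
        model.class_labels = classes
        model.class_centroids = np.vstack(
            [z[train.labels == c].mean(axis=0) for c in classes]
        )
    return model


def predict(
    model: DcsaeModel, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid classification in canonical space.

    Returns (labels, scores); scores are negated Euclidean distances to each
    class centroid (higher = more likely), usable for ROC analysis.  Ties go
    to the lower class index.
    """
    if model.class_centroids is None:
        raise RuntimeError("model has no class centroids; train with labels first")
    z = model.embed(features)
    dists = np.linalg.norm(z[:, None, :] - model.class_centroids[None, :, :], axis=2)
    idx = dists.argmin(axis=1)
    return model.class_labels[idx], -dists
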