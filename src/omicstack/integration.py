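"""Nonlinear integration of the stacked matrix via an autoencoder, plus PCA.

The autoencoder is a symmetric feed-forward network (tanh hidden layers,
linear output) trained with Adam on mean-squared reconstruction error. A
random 90/10 sample split provides a validation set; training stops early
when the validation loss has not improved for ``patience`` consecutive
epochs, and the weights from the best-validation epoch are kept. Among a
grid of candidate architectures, the model with the smallest
|train loss - validation loss| gap is selected (an overfitting guard), with
ties broken by lower validation loss, then fewer parameters.

Before either reduction, `normalize` applies log2(x+1) to the count-like
F1/F2 columns and z-scales every feature, so the mixed-scale concatenation
trains on comparable magnitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import LatentRepresentation, MultiOmicsMatrix


@dataclass
class AEArchitecture:
    """Encoder widths (ending at the bottleneck) and training hyperparameters."""

    encoder_widths: tuple[int, ...] = (512, 100)
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 10
    batch_size: int = 64
    val_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        if not self.encoder_widths or min(self.encoder_widths) < 1:
            raise ValueError("encoder widths must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")

    @property
    def bottleneck(self) -> int:
        return self.encoder_widths[-1]


@dataclass
class TrainedAE:
    """A fitted autoencoder: losses at the kept (best-validation) weights."""

    architecture: AEArchitecture
    train_loss: float
    val_loss: float
    n_epochs: int
    weights: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)
    feature_ids: list[str] | None = field(default=None, repr=False)
    loss_trace: list[tuple[float, float]] = field(default_factory=list, repr=False)

    @property
    def loss_gap(self) -> float:
        return abs(self.train_loss - self.val_loss)

    @property
    def n_params(self) -> int:
        return int(sum(w.size + b.size for w, b in self.weights))

    @property
    def n_encoder_layers(self) -> int:
        return len(self.architecture.encoder_widths)

    def encode_array(self, x: np.ndarray) -> np.ndarray:
        """Forward pass through the encoder half (tanh at every encoder layer)."""
        h = np.asarray(x, dtype=float)
        for w, b in self.weights[: self.n_encoder_layers]:
            h = np.tanh(h @ w + b)
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(x, dtype=float)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(self.weights):
            h = h @ w + b
            if i != last:
                h = np.tanh(h)
        return h


def normalize(X: MultiOmicsMatrix) -> MultiOmicsMatrix:
    """log2(x+1)-transform F1/F2 columns, then z-scale every feature.

    Constant features are left at zero after centering.
    """
    values = X.values.astype(float).copy()
    for tag in ("F1", "F2"):
        cols = X.columns_for(tag)
        if cols.size:
            values[:, cols] = np.log2(values[:, cols] + 1.0)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    values = (values - mu) / sd_safe
    return MultiOmicsMatrix(
        list(X.sample_ids), list(X.feature_ids), values, dict(X.provenance)
    )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _forward(weights, x, n_layers):
    h = x
    last = n_layers - 1
    acts = [x]
    for i, (w, b) in enumerate(weights):
        z = h @ w + b
        h = z if i == last else np.tanh(z)
        acts.append(h)
    return acts


def _mse(weights, x, n_layers):
    recon = _forward(weights, x, n_layers)[-1]
    return float(np.mean((recon - x) ** 2))


def train_autoencoder(
    X: MultiOmicsMatrix | np.ndarray, arch: AEArchitecture
) -> TrainedAE:
    """Fit one autoencoder architecture on the (normalized) stacked matrix."""
    if isinstance(X, MultiOmicsMatrix):
        data = X.values
        feature_ids = list(X.feature_ids)
    else:
        data = np.asarray(X, dtype=float)
        feature_ids = None
    n, p = data.shape
    if n < 20:
        raise ValueError("autoencoder training requires at least 20 samples")
    if arch.bottleneck >= p:
        raise ValueError("bottleneck must be narrower than the input")

    widths = [p, *arch.encoder_widths, *arch.encoder_widths[-2::-1], p]
    n_layers = len(widths) - 1
    rng = np.random.default_rng(arch.seed)
    weights = [
        (_glorot(rng, widths[i], widths[i + 1]), np.zeros(widths[i + 1]))
        for i in range(n_layers)
    ]

    # 90/10 train/validation split of samples
    perm = rng.permutation(n)
    n_val = max(1, int(round(arch.val_fraction * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    x_train, x_val = data[train_idx], data[val_idx]

    # Adam state
    m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    best_val = np.inf
    best_weights = [(w.copy(), b.copy()) for w, b in weights]
    best_epoch = 0
    stall = 0
    trace: list[tuple[float, float]] = []
    n_train = x_train.shape[0]
    batch = min(arch.batch_size, n_train)

    epoch = 0
    for epoch in range(1, arch.max_epochs + 1):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch):
            xb = x_train[order[start : start + batch]]
            acts = _forward(weights, xb, n_layers)
            # backprop of mean squared error
            delta = 2.0 * (acts[-1] - xb) / xb.size
            grads = [None] * n_layers
            for i in range(n_layers - 1, -1, -1):
                gw = acts[i].T @ delta
                gb = delta.sum(axis=0)
                grads[i] = (gw, gb)
                if i > 0:
                    delta = (delta @ weights[i][0].T) * (1.0 - acts[i] ** 2)
            t += 1
            corr1 = 1.0 - beta1**t
            corr2 = 1.0 - beta2**t
            for i in range(n_layers):
                w, b = weights[i]
                for j, (param, grad) in enumerate(((w, grads[i][0]), (b, grads[i][1]))):
                    mi = m[i][j]
                    vi = v[i][j]
                    mi *= beta1
                    mi += (1 - beta1) * grad
                    vi *= beta2
                    vi += (1 - beta2) * grad**2
                    param -= arch.learning_rate * (mi / corr1) / (np.sqrt(vi / corr2) + eps)

        tr_loss = _mse(weights, x_train, n_layers)
        val_loss = _mse(weights, x_val, n_layers)
        if not (np.isfinite(tr_loss) and np.isfinite(val_loss)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch} "
                f"(train={tr_loss}, val={val_loss}, lr={arch.learning_rate})"
            )
        trace.append((tr_loss, val_loss))
        if val_loss < best_val:
            best_val = val_loss
            best_weights = [(w.copy(), b.copy()) for w, b in weights]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= arch.patience:
                break

    final_train = _mse(best_weights, x_train, n_layers)
    return TrainedAE(
        architecture=arch,
        train_loss=final_train,
        val_loss=best_val,
        n_epochs=epoch,
        weights=best_weights,
        feature_ids=feature_ids,
        loss_trace=trace,
    )


def select_autoencoder(candidates: list[TrainedAE]) -> TrainedAE:
    """Pick the fit with the least |train - validation| loss gap.

    Ties break toward lower validation loss, then fewer parameters.
    """
    if not candidates:
        raise ValueError("no candidate autoencoders")
    return min(candidates, key=lambda c: (c.loss_gap, c.val_loss, c.n_params))


def default_grid(
    bottleneck: int = 100,
    hidden_options: tuple[tuple[int, ...], ...] = ((2048,), (1024,), (512,), (2048, 1024), (1024, 512)),
    learning_rates: tuple[float, ...] = (1e-3, 1e-4, 1e-5),
    **kwargs,
) -> list[AEArchitecture]:
    """Candidate architectures: 1-2 hidden layers ending in the bottleneck."""
    return [
        AEArchitecture(encoder_widths=(*hidden, bottleneck), learning_rate=lr, **kwargs)
        for hidden, lr in itertools.product(hidden_options, learning_rates)
    ]


def encode(X: MultiOmicsMatrix | np.ndarray, model: TrainedAE) -> LatentRepresentation:
    """Project samples into the bottleneck space of a trained autoencoder."""
    if isinstance(X, MultiOmicsMatrix):
        if model.feature_ids is not None and list(X.feature_ids) != model.feature_ids:
            raise ValueError("feature set/order differs from the training input")
        data, ids = X.values, list(X.sample_ids)
    else:
        data = np.asarray(X, dtype=float)
        ids = [f"S{i + 1}" for i in range(data.shape[0])]
    if data.shape[1] != model.weights[0][0].shape[0]:
        raise ValueError("feature dimension differs from the training input")
    return LatentRepresentation(ids, model.encode_array(data), source="F_AE")


def pca_reduce(
    X: MultiOmicsMatrix | np.ndarray, variance_fraction: float = 0.99
) -> LatentRepresentation:
    """Centered PCA scores keeping the fewest leading components reaching
    the requested cumulative explained-variance fraction."""
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance_fraction must lie in (0, 1]")
    if isinstance(X, MultiOmicsMatrix):
        data, ids = X.values, list(X.sample_ids)
    else:
        data = np.asarray(X, dtype=float)
        ids = [f"S{i + 1}" for i in range(data.shape[0])]
    pca = PCA(svd_solver="full").fit(data)
    ratios = pca.explained_variance_ratio_
    nonzero = int((pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]).sum())
    if variance_fraction >= 1.0:
        d = max(1, nonzero)
    else:
        cum = np.cumsum(ratios)
        d = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        d = min(max(d, 1), len(ratios))
    scores = pca.transform(data)[:, :d]
    return LatentRepresentation(ids, scores, source="F_PCA")
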