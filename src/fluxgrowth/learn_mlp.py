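"""Feedforward network on flux features, interpreted by Shapley attribution.

The regressor is a fully connected ReLU network trained with mean-squared
error, RMSprop updates, inverted dropout on hidden activations and a
per-unit max-norm constraint on incoming weights — implemented here in numpy
so every training control is explicit and seeded.

Attribution uses permutation-sampling Shapley values: for an instance x and
feature j, the attribution is the average marginal contribution of revealing
x_j over random feature orderings, with unrevealed features taking values
from a background (training) sample.  When the requested number of samples
covers all p! orderings the estimator enumerates them and averages over the
full background, making it exact.  Per run, the median attribution over
mutants summarizes each reaction; runs (different seeds) are averaged, and
the same sign + one-tenth-SD rule as the elastic net turns importances into
beneficial/detrimental calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dataset import TrainingDataset
from .learn_en import PredictionSet, select_by_sign_sd
from .model_io import MetabolicModel

__all__ = [
    "MLPConfig",
    "MLPRegressorNet",
    "train_mlp",
    "shapley_attribution",
    "aggregate_attributions",
    "mlp_predictions",
]


@dataclass(frozen=True)
class MLPConfig:
    """Network architecture and training controls.

    The default mirrors the published optimum for genome-scale data (four
    hidden layers of 1000 ReLU units, dropout 0.6, max-norm 4, RMSprop, ten
    seeded runs); ``toy()`` is the desk-scale preset used on synthetic
    fixtures.
    """

    hidden_layers: tuple[int, ...] = (1000, 1000, 1000, 1000)
    dropout_rate: float = 0.6
    max_weight_norm: float = 4.0
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    validation_split: float = 0.1
    seeds: tuple[int, ...] = tuple(range(10))
    shap_samples: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if len(self.seeds) == 0:
            raise ValueError("at least one seed (run) is required")

    @property
    def runs(self) -> int:
        return len(self.seeds)

    @classmethod
    def toy(cls, seeds: tuple[int, ...] = tuple(range(10))) -> "MLPConfig":
        """Desk-scale preset: two 32-unit layers, lighter dropout."""
        return cls(
            hidden_layers=(32, 32),
            dropout_rate=0.2,
            epochs=300,
            batch_size=16,
            seeds=seeds,
            shap_samples=200,
        )


class MLPRegressorNet:
    """ReLU multilayer perceptron with a single linear output node."""

    def __init__(self, n_features: int, config: MLPConfig, seed: int):
        self.config = config
        self.rng = np.random.default_rng(seed)
        sizes = [n_features, *config.hidden_layers, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = math.sqrt(2.0 / fan_in)  # He initialization for ReLU
            self.weights.append(self.rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._mean = np.zeros(n_features)
        self._scale = np.ones(n_features)

    # -- forward ----------------------------------------------------------
    def _forward(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """Returns activations per layer; applies inverted dropout when
        ``train_rng`` is given."""
        keep = 1.0 - self.config.dropout_rate
        acts = [X]
        masks = []
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < last:
                h = np.maximum(z, 0.0)
                if train_rng is not None and self.config.dropout_rate > 0:
                    mask = (train_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = z
            acts.append(h)
        return acts, masks

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self._mean) / self._scale
        acts, _ = self._forward(Xs)
        return acts[-1][:, 0]

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> dict:
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self._scale = scale
        Xs = (X - self._mean) / self._scale
        n = Xs.shape[0]
        n_val = int(round(cfg.validation_split * n))
        perm = self.rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xt, yt = Xs[train_idx], y[train_idx]
        Xv, yv = Xs[val_idx], y[val_idx]
        caches_W = [np.zeros_like(W) for W in self.weights]
        caches_b = [np.zeros_like(b) for b in self.biases]
        rho, eps = 0.9, 1e-8
        history = {"loss": [], "val_loss": []}
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(len(Xt))
            for start in range(0, len(Xt), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xt[idx], yt[idx]
                acts, masks = self._forward(xb, train_rng=self.rng)
                pred = acts[-1][:, 0]
                # backprop of mean-squared error
                delta = (2.0 / len(xb)) * (pred - yb)[:, None]
                grads_W = [None] * len(self.weights)
                grads_b = [None] * len(self.biases)
                for i in range(len(self.weights) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.weights[i].T
                        delta = delta * (acts[i] > 0)
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                for i in range(len(self.weights)):
                    caches_W[i] = rho * caches_W[i] + (1 - rho) * grads_W[i] ** 2
                    caches_b[i] = rho * caches_b[i] + (1 - rho) * grads_b[i] ** 2
                    self.weights[i] -= cfg.learning_rate * grads_W[i] / (
                        np.sqrt(caches_W[i]) + eps
                    )
                    self.biases[i] -= cfg.learning_rate * grads_b[i] / (
                        np.sqrt(caches_b[i]) + eps
                    )
                    # max-norm constraint on each unit's incoming weights
                    norms = np.linalg.norm(self.weights[i], axis=0, keepdims=True)
                    over = norms > cfg.max_weight_norm
                    if over.any():
                        factor = np.where(over, cfg.max_weight_norm / norms, 1.0)
                        self.weights[i] *= factor
            train_pred = self._forward(Xt)[0][-1][:, 0]
            loss = float(np.mean((train_pred - yt) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"training loss diverged (non-finite) at epoch {epoch}")
            history["loss"].append(loss)
            if len(Xv):
                val_pred = self._forward(Xv)[0][-1][:, 0]
                history["val_loss"].append(float(np.mean((val_pred - yv) ** 2)))
        return history


def train_mlp(dataset: TrainingDataset, config: MLPConfig, seed: int) -> MLPRegressorNet:
    """Train one seeded network on a dataset; deterministic given the seed."""
    if dataset.y is None:
        raise ValueError("dataset has no output vector; assemble y first")
    net = MLPRegressorNet(dataset.X.shape[1], config, seed)
    net.history = net.fit(dataset.X.values, dataset.y.values)
    return net


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

def _perm_contributions(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    background: np.ndarray,
    perms: np.ndarray,
) -> np.ndarray:
    """Marginal contributions of each feature for a batch of orderings.

    ``perms`` is (n_perm, p); ``background`` is (n_perm, p) — one background
    row per ordering.  Returns (n_perm, p) attributions: walking along each
    ordering, features switch from background to instance values and the
    change in prediction is credited to the switched feature.
    """
    n_perm, p = perms.shape
    # composites[k, s] = x masked with the first s features of permutation k
    composites = np.repeat(background[:, None, :], p + 1, axis=1)  # (n_perm, p+1, p)
    for s in range(1, p + 1):
        composites[:, s, :] = composites[:, s - 1, :]
        js = perms[:, s - 1]
        composites[np.arange(n_perm), s, js] = x[js]
    preds = predict(composites.reshape(-1, p)).reshape(n_perm, p + 1)
    deltas = np.diff(preds, axis=1)  # (n_perm, p): credit for step s -> feature perms[:, s]
    phi = np.zeros((n_perm, p))
    np.add.at(phi, (np.repeat(np.arange(n_perm), p), perms.ravel()), deltas.ravel())
    return phi


def shapley_attribution(
    network,
    dataset: TrainingDataset,
    n_samples: int = 200,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-mutant, per-reaction Shapley values of the network output.

    ``network`` is anything with a ``predict(X) -> (n,)`` method.  The
    background defaults to the full training feature matrix.  With
    ``n_samples >= p!`` all orderings are enumerated against every background
    row (exact Shapley values); otherwise ``n_samples`` random orderings are
    drawn per instance, each paired with one sampled background row.

    Satisfies local accuracy in expectation:
    sum_j phi_j(x) ~= f(x) - mean_b f(b).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    X = dataset.X.values
    p = X.shape[1]
    if background is None:
        background = X
    background = np.atleast_2d(np.asarray(background, dtype=float))
    rng = np.random.default_rng(seed)
    exact = p <= 20 and n_samples >= math.factorial(p)
    rows = []
    for i in range(X.shape[0]):
        x = X[i]
        if exact:
            all_perms = np.array(list(iter_permutations(range(p))), dtype=int)
            phi = np.zeros(p)
            for b in background:
                bg = np.repeat(b[None, :], len(all_perms), axis=0)
                phi += _perm_contributions(network.predict, x, bg, all_perms).mean(axis=0)
            phi /= len(background)
        else:
            perms = np.argsort(rng.random((n_samples, p)), axis=1)
            bg_idx = rng.integers(0, len(background), size=n_samples)
            phi = _perm_contributions(
                network.predict, x, background[bg_idx], perms
            ).mean(axis=0)
        rows.append(phi)
    return pd.DataFrame(rows, index=dataset.X.index, columns=dataset.X.columns)


def aggregate_attributions(per_run: Sequence[pd.DataFrame]) -> dict[str, float]:
    """Reaction importances: per-run median over mutants, then mean over runs."""
    if len(per_run) == 0:
        raise ValueError("at least one attribution matrix is required")
    shapes = {m.shape for m in per_run}
    if len(shapes) != 1:
        raise ValueError(f"attribution matrices differ in shape: {shapes}")
    cols = list(per_run[0].columns)
    for m in per_run[1:]:
        if list(m.columns) != cols:
            raise ValueError("attribution matrices differ in feature columns")
    medians = np.vstack([m.median(axis=0).values for m in per_run])
    means = medians.mean(axis=0)
    return {r: float(v) for r, v in zip(cols, means)}


def mlp_predictions(
    dataset: TrainingDataset,
    model: MetabolicModel,
    config: MLPConfig = MLPConfig(),
    selection_fraction: float = 0.1,
) -> PredictionSet:
    """Train/attribute over all seeds and select reactions by sign + SD."""
    if dataset.y is None:
        raise ValueError("dataset has no output vector; assemble y first")
    y = dataset.y.values
    if np.allclose(y, y[0]):
        # a constant target carries no attributable signal
        return PredictionSet(dataset.condition_id, {}, {}, "mlp", set())
    per_run = []
    for seed in config.seeds:
        net = train_mlp(dataset, config, seed)
        per_run.append(
            shapley_attribution(net, dataset, n_samples=config.shap_samples, seed=seed)
        )
    importances = aggregate_attributions(per_run)
    return select_by_sign_sd(
        importances,
        model,
        fraction=selection_fraction,
        condition_id=dataset.condition_id,
        model_tag="mlp",
    )
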