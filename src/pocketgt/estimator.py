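"""Scikit-learn style estimator wrapping the graph transformer.

``X`` is a list of :class:`~pocketgt.graphs.PocketGraph`; ``y`` is optional
when the graphs carry labels.  Optimization is Adam with an epoch-level
linear-warmup / cosine-decay schedule (maximum learning rate 2e-4, 25 warmup
epochs by default).  When a validation split is available, the parameters
with the best validation PR-AUC are kept (ties keep the earlier epoch);
validation data are never balanced or augmented.
"""

from __future__ import annotations

import copy
import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import average_precision_score, roc_auc_score

from .augment import AugmentConfig, augment_pocket, balance_labels
from .errors import ConfigError
from .model import (
    ModelConfig,
    bce_loss_from_logits,
    count_parameters,
    forward,
    init_model,
    predict_scores,
    wrap_parameters,
)


def lr_schedule(epoch: int, max_lr: float, warmup_epochs: int, total_epochs: int) -> float:
    """Linear warmup to ``max_lr`` then half-cosine decay to 0.

    ``lr(0) = max_lr / warmup_epochs``, ``lr(warmup_epochs) = max_lr``, then
    ``max_lr * 0.5 * (1 + cos(pi * t))`` with ``t`` the post-warmup fraction.
    """
    if not (0 <= epoch < total_epochs):
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    if epoch < warmup_epochs:
        return max_lr * (warmup_epochs + epoch * (warmup_epochs - 1)) / warmup_epochs**2
    t = (epoch - warmup_epochs) / (total_epochs - warmup_epochs)
    return max_lr * 0.5 * (1.0 + math.cos(math.pi * t))


class _Adam:
    """Adam over a dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        self.t += 1
        c1 = 1.0 - self.beta1**self.t
        c2 = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


class GraphTransformerSiteClassifier(BaseEstimator, ClassifierMixin):
    """Binary pocket-candidate classifier (true vs. false binding site).

    Parameters mirror the model and training hyperparameters; the defaults
    are the reference recipe (L=8, d=128, balanced and augmented training,
    batch 128, 300 epochs).  ``validation_fraction`` carves a stratified
    holdout from the training graphs for checkpoint selection unless
    ``fit`` receives an explicit ``validation_data``.
    """

    def __init__(
        self,
        n_layers: int = 8,
        hidden_dim: int = 128,
        n_heads: int = 8,
        ffn_hidden: int | None = None,
        dropout: float = 0.1,
        clamp_bound: float = 5.0,
        use_sasa: bool = True,
        max_lr: float = 2e-4,
        warmup_epochs: int = 25,
        n_epochs: int = 300,
        batch_size: int = 128,
        balance: bool = True,
        augment: bool = True,
        sigma_pos: float = 0.5,
        sigma_node: float = 0.03,
        sigma_sasa: float = 0.3,
        validation_fraction: float = 0.2,
        random_state: int | None = 0,
        verbose: int = 0,
    ):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.n_heads = n_heads
        self.ffn_hidden = ffn_hidden
        self.dropout = dropout
        self.clamp_bound = clamp_bound
        self.use_sasa = use_sasa
        self.max_lr = max_lr
        self.warmup_epochs = warmup_epochs
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.balance = balance
        self.augment = augment
        self.sigma_pos = sigma_pos
        self.sigma_node = sigma_node
        self.sigma_sasa = sigma_sasa
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # -- configuration -------------------------------------------------------

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers,
            hidden_dim=self.hidden_dim,
            n_heads=self.n_heads,
            ffn_hidden=self.ffn_hidden,
            dropout=self.dropout,
            clamp_bound=self.clamp_bound,
            use_sasa=self.use_sasa,
        )

    def _augment_config(self) -> AugmentConfig:
        return AugmentConfig(
            sigma_pos=self.sigma_pos,
            sigma_node=self.sigma_node,
            sigma_sasa=self.sigma_sasa,
            balance=self.balance,
            enabled=self.augment,
        )

    @staticmethod
    def _labels_from(X, y) -> np.ndarray:
        if y is not None:
            return np.asarray([int(v) for v in y])
        labels = [g.label for g in X]
        if any(l is None for l in labels):
            raise ValueError("graphs without labels; pass y explicitly")
        return np.asarray([int(l) for l in labels])

    # -- training --------------------------------------------------------------

    def fit(self, X, y=None, validation_data=None):
        """Train on a list of pocket graphs.

        ``validation_data`` is an optional ``(graphs, labels)`` pair (labels
        may be ``None`` when the graphs carry them); otherwise a stratified
        fraction of ``X`` is held out when ``validation_fraction > 0``.
        """
        if self.warmup_epochs >= self.n_epochs:
            raise ConfigError("warmup_epochs must be smaller than n_epochs")
        X = list(X)
        labels = self._labels_from(X, y)
        if len(X) != len(labels):
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)

        if validation_data is not None:
            val_graphs = list(validation_data[0])
            val_labels = self._labels_from(val_graphs, validation_data[1])
            train_graphs, train_labels = X, labels
        elif self.validation_fraction > 0:
            # stratified split: positives are rare, so proportional sampling
            # keeps the validation PR-AUC resolvable
            val_idx, tr_idx = [], []
            for cls in np.unique(labels):
                members = rng.permutation(np.flatnonzero(labels == cls))
                n_val = max(1, int(round(self.validation_fraction * len(members))))
                if n_val >= len(members):  # keep at least one in training
                    n_val = len(members) - 1
                val_idx.extend(members[:n_val])
                tr_idx.extend(members[n_val:])
            val_idx = np.asarray(sorted(val_idx), dtype=int)
            tr_idx = np.asarray(sorted(tr_idx), dtype=int)
            train_graphs = [X[i] for i in tr_idx]
            train_labels = labels[tr_idx]
            val_graphs = [X[i] for i in val_idx]
            val_labels = labels[val_idx]
        else:
            train_graphs, train_labels = X, labels
            val_graphs, val_labels = [], np.empty(0, int)

        cfg = self._model_config()
        aug = self._augment_config()
        params = init_model(cfg, seed=int(rng.integers(2**31 - 1)))
        optimizer = _Adam(params)
        best = {"pr_auc": -np.inf, "epoch": -1, "params": None}
        history = {"epoch": [], "lr": [], "train_loss": [], "val_pr_auc": [], "val_roc_auc": []}

        for epoch in range(self.n_epochs):
            lr = lr_schedule(epoch, self.max_lr, self.warmup_epochs, self.n_epochs)
            if self.balance:
                epoch_idx = balance_labels(train_labels, rng)
            else:
                epoch_idx = np.arange(len(train_graphs))
            rng.shuffle(epoch_idx)
            losses = []
            for start in range(0, len(epoch_idx), self.batch_size):
                batch_idx = epoch_idx[start:start + self.batch_size]
                batch = [train_graphs[i] for i in batch_idx]
                if self.augment:
                    batch = [augment_pocket(g, aug, rng) for g in batch]
                batch_labels = train_labels[batch_idx]
                tparams = wrap_parameters(params)
                _, logits = forward(batch, tparams, cfg, training=True, rng=rng)
                loss = bce_loss_from_logits(logits, batch_labels)
                loss.backward()
                grads = {k: t.grad for k, t in tparams.items()}
                optimizer.step(params, grads, lr)
                losses.append(float(loss.data))
            history["epoch"].append(epoch)
            history["lr"].append(lr)
            history["train_loss"].append(float(np.mean(losses)) if losses else np.nan)
            if val_graphs and len(set(val_labels)) == 2:
                scores = predict_scores(params, val_graphs, cfg)
                pr = float(average_precision_score(val_labels, scores))
                roc = float(roc_auc_score(val_labels, scores))
                history["val_pr_auc"].append(pr)
                history["val_roc_auc"].append(roc)
                if pr > best["pr_auc"]:
                    best = {"pr_auc": pr, "epoch": epoch,
                            "params": copy.deepcopy(params)}
            else:
                history["val_pr_auc"].append(np.nan)
                history["val_roc_auc"].append(np.nan)
            if self.verbose:
                print(
                    f"epoch {epoch:3d} lr {lr:.2e} loss {history['train_loss'][-1]:.4f}"
                    f" val_pr {history['val_pr_auc'][-1]:.4f}"
                )

        if best["params"] is not None:
            self.params_ = best["params"]
            self.best_epoch_ = best["epoch"]
            self.best_val_pr_auc_ = best["pr_auc"]
        else:
            self.params_ = params
            self.best_epoch_ = self.n_epochs - 1
            self.best_val_pr_auc_ = None
        self.config_ = cfg
        self.history_ = history
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = count_parameters(self.params_)
        return self

    # -- inference ----------------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Sigmoid scores in (0, 1), one per graph."""
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        X = [X] if not isinstance(X, (list, tuple)) else list(X)
        return predict_scores(self.params_, X, self.config_)

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_function(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)
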