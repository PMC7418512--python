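"""Optimization protocol, early stopping and cross-validation orchestration.

Training uses adaptive-moment (Adam) gradient descent on minibatches,
with a learning-rate schedule that multiplies the rate by a reduction
factor whenever the validation loss has not improved for ``patience``
epochs.  Training stops at ``max_epochs`` or once the validation loss has
not improved for ``2 × patience`` epochs; the returned parameters are the
checkpoint with the lowest validation loss within the terminal window of
``window_n`` epochs.  Classification heads are fit on cross-entropy,
count heads on mean squared logarithmic error of the exponentiated
outputs.  Everything is seeded: initialization, data order, and splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dataset import ArrayDataset, build_screen_datasets
from .metrics import (
    EvalReport,
    MetricUndefinedError,
    auc_roc,
    classification_rates,
    multiclass_auc,
    r2_log,
)
from .nn.autograd import Tensor, softplus
from .nn.model import Model, ModelSpec
from .pipeline import Part, split_by_clonotype, split_leave_one_donor_out

__all__ = [
    "TrainConfig",
    "TrainResult",
    "Adam",
    "train_model",
    "evaluate_classifier",
    "evaluate_count_model",
    "run_cross_validation",
    "aggregate_reports",
]


@dataclass
class TrainConfig:
    initial_learning_rate: float = 1e-2
    batch_size: int = 128
    max_epochs: int = 40
    patience: int = 5
    window_n: int = 5
    lr_reduce_factor: float = 0.5
    steps_per_epoch: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0:
            raise ValueError("initial_learning_rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ValueError("batch_size, max_epochs and patience must be positive")
        if not 0 < self.lr_reduce_factor < 1:
            raise ValueError("lr_reduce_factor must lie in (0, 1)")
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        # the selection window cannot exceed the training history
        if self.window_n > self.max_epochs:
            self.window_n = self.max_epochs

    def to_dict(self) -> dict:
        return {
            "initial_learning_rate": self.initial_learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "window_n": self.window_n,
            "lr_reduce_factor": self.lr_reduce_factor,
            "steps_per_epoch": self.steps_per_epoch,
            "seed": self.seed,
        }


@dataclass
class TrainResult:
    history: list
    selected_epoch: int
    final_params: dict
    config: TrainConfig

    def history_rows(self) -> list:
        """TSV-ready rows: epoch, train loss, val loss, learning rate."""
        return [
            (h["epoch"], h["train_loss"], h["val_loss"], h["lr"]) for h in self.history
        ]


class Adam:
    """Adaptive-moment estimation over a parameter store."""

    def __init__(self, store, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.store = store
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for name, p in self.store.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self.m.setdefault(name, np.zeros_like(p.data))
            v = self.v.setdefault(name, np.zeros_like(p.data))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Tensor-space losses (numerically stable logit forms)


def _ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy from pre-activation outputs."""
    z = logits - np.max(logits.data, axis=1, keepdims=True)
    lse = z.exp().sum(axis=1).log()
    onehot = np.zeros(z.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1)
    return (lse - picked).mean()


def _bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean sigmoid cross-entropy from a single pre-activation column."""
    z = logits.reshape(logits.shape[0])
    y = np.asarray(labels, dtype=np.float64)
    # log(1+e^z) - y z, stable via softplus
    return (softplus(z) - z * Tensor(y)).mean()


def _msle_loss(activations: Tensor, counts: np.ndarray) -> Tensor:
    """msle of exponentiated activations: (log1p(exp(a)) − log1p(y))²."""
    target = np.log1p(np.asarray(counts, dtype=np.float64))
    diff = softplus(activations) - Tensor(target)
    return (diff * diff).mean()


def loss_for_head(head: str, out: Tensor, y: np.ndarray) -> Tensor:
    if head == "categorical":
        return _ce_loss(out, y)
    if head == "binary":
        return _bce_loss(out, y)
    return _msle_loss(out, y)


# ---------------------------------------------------------------------------
# Training loop


def _batched_loss(model: Model, data: ArrayDataset, batch_size: int) -> float:
    """Mean loss over a dataset without gradient bookkeeping overhead."""
    total, n = 0.0, len(data)
    for lo in range(0, n, batch_size):
        sub = data.subset(np.arange(lo, min(lo + batch_size, n)))
        out = model.forward(sub.x, sub.cov)
        loss = loss_for_head(model.spec.head, out, sub.y)
        total += float(loss.data) * len(sub)
    return total / n


def train_model(
    model: Model,
    train_data: ArrayDataset,
    val_data: ArrayDataset,
    config: TrainConfig,
) -> TrainResult:
    """Fit a model, returning the training history and the parameters of
    the best validation checkpoint in the terminal window."""
    if len(train_data) == 0:
        raise ValueError("empty training data")
    if len(val_data) == 0:
        raise ValueError("empty validation data")
    rng = np.random.default_rng(config.seed)
    # materialize parameters deterministically before the optimizer attaches
    model.forward(train_data.subset(np.arange(min(2, len(train_data)))).x,
                  train_data.cov[: min(2, len(train_data))])
    opt = Adam(model.store, lr=config.initial_learning_rate)
    history: list = []
    window: list = []  # (epoch, val_loss, state) ring buffer of window_n
    best_val = np.inf
    epochs_since_best = 0
    lr = config.initial_learning_rate
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_data))
        steps = 0
        train_loss_sum, seen = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            if config.steps_per_epoch is not None and steps >= config.steps_per_epoch:
                break
            idx = order[lo : lo + config.batch_size]
            sub = train_data.subset(idx)
            model.store.zero_grad()
            out = model.forward(sub.x, sub.cov, train=True)
            loss = loss_for_head(model.spec.head, out, sub.y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            loss.backward()
            opt.lr = lr
            opt.step()
            train_loss_sum += float(loss.data) * len(idx)
            seen += len(idx)
            steps += 1
        train_loss = train_loss_sum / max(seen, 1)
        val_loss = _batched_loss(model, val_data, config.batch_size)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr}
        )
        window.append((epoch, val_loss, model.store.state_dict()))
        if len(window) > config.window_n:
            window.pop(0)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best % config.patience == 0:
                lr *= config.lr_reduce_factor
        if epochs_since_best >= 2 * config.patience:
            break
    sel_epoch, _, sel_state = min(window, key=lambda t: (t[1], t[0]))
    model.store.load_state_dict(sel_state)
    return TrainResult(
        history=history, selected_epoch=sel_epoch,
        final_params=sel_state, config=config,
    )


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_classifier(model: Model, test_data: ArrayDataset,
                        antigen_names: Optional[Sequence[str]] = None) -> EvalReport:
    """AUC/F1/FNR/FPR of a classification model on held-out data."""
    probs = model.predict(test_data.x, test_data.cov)
    y = np.asarray(test_data.y)
    if model.spec.head == "binary":
        try:
            auc = auc_roc(y, probs)
        except MetricUndefinedError:
            auc = None
        rates = classification_rates(y, (probs >= 0.5).astype(int))
        return EvalReport(auc_roc=auc, n_test=len(y), **rates)
    res = multiclass_auc(y, probs)
    per_antigen = {}
    for k, v in res["per_class"].items():
        if k < model.spec.n_antigens:
            name = antigen_names[k] if antigen_names else str(k)
            per_antigen[name] = v
    rates = classification_rates(y, probs.argmax(axis=1))
    return EvalReport(
        auc_roc=res["micro"], auc_macro=res["macro"],
        auc_per_antigen=per_antigen, n_test=len(y), **rates,
    )


def evaluate_count_model(model: Model, test_data: ArrayDataset,
                         antigen_names: Optional[Sequence[str]] = None) -> EvalReport:
    """R² on log(1+x) counts of a count model on held-out data."""
    pred = model.predict(test_data.x, test_data.cov)
    y = np.asarray(test_data.y, dtype=float)
    overall = r2_log(y, pred)
    per_antigen = {}
    for j in range(y.shape[1]):
        name = antigen_names[j] if antigen_names else str(j)
        try:
            per_antigen[name] = r2_log(y[:, j], pred[:, j])
        except MetricUndefinedError:
            per_antigen[name] = None
    return EvalReport(
        auc_roc=None, f1=0.0, fnr=0.0, fpr=0.0, n_test=len(y),
        r2_log=overall, r2_per_antigen=per_antigen,
    )


# ---------------------------------------------------------------------------
# Cross-validation


def run_cross_validation(
    cells,
    panel,
    model_spec: ModelSpec,
    train_config: TrainConfig,
    scheme: str = "clonotype_fraction",
    k: int = 3,
    base_seed: int = 0,
    test_fraction: float = 0.25,
    val_fraction: float = 0.1,
) -> list:
    """Seeded k-fold cross-validation of one model configuration.

    Fold memberships depend only on the cells and ``base_seed``, so two
    different model specs evaluated with the same seed see identical
    splits.  ``scheme`` is ``clonotype_fraction`` (k seeded clonotype
    splits) or ``leave_one_donor_out`` (one fold per donor).
    """
    if scheme == "clonotype_fraction":
        n_clono = len({c.clonotype_id for c in cells})
        if k > n_clono:
            raise ValueError(f"k={k} exceeds {n_clono} available clonotypes")
        splits = [
            split_by_clonotype(cells, test_fraction, val_fraction, seed=base_seed + i)
            for i in range(k)
        ]
    elif scheme == "leave_one_donor_out":
        splits = split_leave_one_donor_out(cells, val_fraction, seed=base_seed)
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    reports = []
    for i, split in enumerate(splits):
        datasets = build_screen_datasets(
            cells, panel, split,
            chain_mode=model_spec.chain_mode,
            embedding=model_spec.embedding,
            covariate_set=model_spec.covariate_set,
            head=model_spec.head,
        )
        model = Model(model_spec, seed=train_config.seed + i)
        train_model(model, datasets[Part.TRAIN], datasets[Part.VAL], train_config)
        if model_spec.head == "count":
            reports.append(
                evaluate_count_model(model, datasets[Part.TEST], panel.names)
            )
        else:
            reports.append(
                evaluate_classifier(model, datasets[Part.TEST], panel.names)
            )
    return reports


def aggregate_reports(reports: Sequence[EvalReport]) -> dict:
    """Mean and spread of the headline metric across folds."""
    out = {}
    for key in ("auc_roc", "r2_log", "f1"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            out[f"{key}_mean"] = float(np.mean(vals))
            out[f"{key}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    out["n_folds"] = len(reports)
    return out
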