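"""Loss functions and the seeded training loop.

Class imbalance is the central nuisance in per-minute apnea detection:
apneic minutes are typically far rarer than normal ones, and a plain
cross-entropy model drifts toward the majority class. Three strategies are
provided and compared: plain cross-entropy, class-weighted cross-entropy
``CE(p_t) = -alpha_t log(p_t)``, and the focal loss
``FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t)``, whose modulation factor
``(1 - p_t)^gamma`` down-weights easy samples so training concentrates on
hard ones. With ``gamma = 0`` the focal loss reduces exactly to the
class-weighted cross-entropy.

Training is plain mini-batch Adam, deterministic given the seed. The
train/validation split is by record, not by segment, so minutes of one
recording never straddle the split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MultiScaleResNet, ModelConfig, build_model, desk_config
from .nnet import Adam, softmax
from .preprocess import SegmentDataset

__all__ = ["FocalParams", "TrainConfig", "focal_loss", "weighted_ce",
           "fit", "imbalance_experiment", "record_split"]

_P_CLAMP = 1e-7

LOSS_MODES = ("focal", "class_weight", "plain")


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss parameters: per-class weights alpha_t and exponent gamma."""

    alpha: tuple[float, ...] = (0.5, 0.5)
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if any(not 0 < a < 1 for a in self.alpha):
            raise ValueError("each alpha must lie in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    loss_mode: str = "focal"
    focal: FocalParams | None = None  # None: alpha from inverse class freq
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


def _check_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.clip(p, _P_CLAMP, 1.0)


def focal_loss(true_class_probs: np.ndarray, labels: np.ndarray,
               params: FocalParams) -> float:
    """Mean of ``-alpha_t (1 - p_t)^gamma log(p_t)`` over samples.

    ``true_class_probs`` holds each sample's predicted probability for its
    *true* class; ``alpha_t`` is selected per sample by its label.
    """
    p = _check_probs(true_class_probs)
    labels = np.asarray(labels, dtype=np.int64)
    alpha = np.asarray(params.alpha, dtype=np.float64)[labels]
    return float(np.mean(-alpha * (1.0 - p) ** params.gamma * np.log(p)))


def weighted_ce(true_class_probs: np.ndarray, labels: np.ndarray,
                alpha: tuple[float, ...] | np.ndarray = (1.0, 1.0)) -> float:
    """Mean of ``-alpha_t log(p_t)``; all-ones alpha gives plain CE."""
    p = _check_probs(true_class_probs)
    labels = np.asarray(labels, dtype=np.int64)
    a = np.asarray(alpha, dtype=np.float64)[labels]
    return float(np.mean(-a * np.log(p)))


def _loss_and_grad(logits: np.ndarray, labels: np.ndarray,
                   alpha: np.ndarray, gamma: float
                   ) -> tuple[float, np.ndarray]:
    """Focal loss value and its gradient w.r.t. the logits (mean reduction)."""
    n = len(labels)
    probs = softmax(logits.astype(np.float64))
    p_t = np.clip(probs[np.arange(n), labels], _P_CLAMP, 1.0 - _P_CLAMP)
    a = alpha[labels]
    one_m = 1.0 - p_t
    loss = float(np.mean(-a * one_m ** gamma * np.log(p_t)))
    if gamma == 0:
        dldp = -a / p_t
    else:
        dldp = a * (gamma * one_m ** (gamma - 1.0) * np.log(p_t)
                    - one_m ** gamma / p_t)
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), labels] = 1.0
    dlogits = (dldp * p_t)[:, None] * (onehot - probs) / n
    return loss, dlogits.astype(np.float32)


def _resolve_alpha(mode: str, labels: np.ndarray, n_classes: int,
                   focal: FocalParams | None) -> np.ndarray:
    if mode == "plain":
        return np.ones(n_classes)
    if focal is not None:
        return np.asarray(focal.alpha, dtype=np.float64)
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError(
            f"loss_mode={mode!r} needs every class present in the training "
            "split")
    inv = 1.0 / counts
    return inv / inv.sum()


def _recalibrate_bn(model: MultiScaleResNet, x: np.ndarray,
                    idx: np.ndarray, batch_size: int,
                    rng: np.random.Generator) -> None:
    """Replace BN running statistics with the training-split averages.

    With few gradient steps the exponential running estimates lag the true
    feature statistics badly, which skews eval-mode predictions; a pass
    over the training data with cumulative-average momentum fixes them.
    """
    bns = model.batchnorms()
    for bn in bns:
        bn.running_mean.fill(0.0)
        bn.running_var.fill(0.0)
    for i, start in enumerate(range(0, len(idx), batch_size)):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        model.forward(x[idx[start:start + batch_size]], training=True, rng=rng)
    for bn in bns:
        bn.momentum = 0.1


def record_split(dataset: SegmentDataset, val_fraction: float = 0.2
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/validation index split, by record where possible."""
    ids = np.asarray(dataset.record_ids)
    unique = sorted(set(ids.tolist()))
    if len(unique) >= 2:
        n_val = max(1, int(round(val_fraction * len(unique))))
        n_val = min(n_val, len(unique) - 1)
        val_ids = set(unique[-n_val:])
        val_mask = np.array([r in val_ids for r in ids])
    else:  # single record: fall back to a tail split over minutes
        n = len(dataset)
        n_val = max(1, int(round(val_fraction * n)))
        val_mask = np.zeros(n, dtype=bool)
        val_mask[n - n_val:] = True
    idx = np.arange(len(dataset))
    return idx[~val_mask], idx[val_mask]


def fit(model: MultiScaleResNet, dataset: SegmentDataset,
        config: TrainConfig = TrainConfig()
        ) -> tuple[MultiScaleResNet, pd.DataFrame]:
    """Train in place; returns the model and a per-epoch history table.

    History columns: epoch, loss (mean training loss), val_accuracy and
    per-class validation recalls (NaN when the split has no such class).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    train_idx, val_idx = record_split(dataset, config.val_fraction)
    y_train = dataset.labels[train_idx]
    n_classes = model.config.n_classes
    alpha = _resolve_alpha(config.loss_mode, y_train, n_classes, config.focal)
    gamma = 0.0 if config.loss_mode in ("plain", "class_weight") else (
        config.focal.gamma if config.focal is not None else 2.0)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    x = dataset.segments
    y = dataset.labels
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            logits = model.forward(x[batch], training=True, rng=rng)
            loss, dlogits = _loss_and_grad(logits, y[batch], alpha, gamma)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        _recalibrate_bn(model, x, train_idx, config.batch_size, rng)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if len(val_idx):
            pred = model.predict(x[val_idx])
            yv = y[val_idx]
            row["val_accuracy"] = float(np.mean(pred == yv))
            for c, name in enumerate(["val_recall_n", "val_recall_ah"][:n_classes]):
                mask = yv == c
                row[name] = float(np.mean(pred[mask] == c)) if mask.any() \
                    else float("nan")
        rows.append(row)
    return model, pd.DataFrame(rows)


def imbalance_experiment(dataset: SegmentDataset,
                         base_config: TrainConfig = TrainConfig(),
                         seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                         model_config: ModelConfig | None = None,
                         out_dir: str | Path | None = None) -> pd.DataFrame:
    """Compare focal loss, class weighting and no technique on one dataset.

    Trains one fresh model per (loss mode, seed), evaluates on the common
    record-level validation split, and reports the confusion matrix and
    per-class recalls per run. With ``out_dir`` set, a delimited table and
    a bar plot of median minority-class recall are written.
    """
    labels = dataset.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("imbalance experiment needs both classes present")
    minority = int(np.argmin(np.bincount(labels)))
    model_config = model_config or desk_config()
    from dataclasses import replace

    _, val_idx = record_split(dataset, base_config.val_fraction)
    rows = []
    for mode in LOSS_MODES:
        for seed in seeds:
            cfg = replace(base_config, loss_mode=mode, seed=seed)
            model = build_model(model_config, seed=seed)
            model, _ = fit(model, dataset, cfg)
            pred = model.predict(dataset.segments[val_idx])
            yv = labels[val_idx]
            tp = int(np.sum((yv == 1) & (pred == 1)))
            tn = int(np.sum((yv == 0) & (pred == 0)))
            fp = int(np.sum((yv == 0) & (pred == 1)))
            fn = int(np.sum((yv == 1) & (pred == 0)))
            rec = {0: tn / max(tn + fp, 1), 1: tp / max(tp + fn, 1)}
            rows.append({
                "mode": mode, "seed": seed,
                "tn": tn, "fp": fp, "fn": fn, "tp": tp,
                "recall_minority": rec[minority],
                "recall_majority": rec[1 - minority],
            })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "imbalance_comparison.csv", index=False)
        _plot_imbalance(table, out_dir / "imbalance_comparison.png")
    return table


def _plot_imbalance(table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med = table.groupby("mode")[["recall_minority", "recall_majority"]].median()
    med = med.reindex(list(LOSS_MODES))
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = np.arange(len(med))
    ax.bar(xs - 0.2, med["recall_minority"], width=0.4,
           label="minority-class recall")
    ax.bar(xs + 0.2, med["recall_majority"], width=0.4,
           label="majority-class recall")
    ax.set_xticks(xs, med.index)
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("median recall over seeds")
    ax.set_title("Class-imbalance strategies")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
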