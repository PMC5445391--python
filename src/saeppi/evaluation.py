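"""Confusion-matrix metrics and the cross-validation evaluation protocol.

The positive class (label 1) is "interaction".  Four metrics are derived
from the confusion counts:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)

A metric whose denominator is zero is reported as ``None`` (explicitly
undefined) rather than silently coerced to 0, so degenerate folds are
visible in sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean, stdev

import numpy as np

from .dataset_builder import make_folds
from .sae import SAEModel, TrainConfig
from .sequence_codec import PairScaler

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Tally confusion counts with class 1 = interaction = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred have different lengths")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """The four ratio metrics; zero-denominator metrics come back as None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "accuracy": ratio(c.TP + c.TN, c.total),
        "sensitivity": ratio(c.TP, c.TP + c.FN),
        "specificity": ratio(c.TN, c.TN + c.FP),
        "precision": ratio(c.TP, c.TP + c.FP),
    }


@dataclass
class MetricsReport:
    """Per-fold metrics plus their mean and standard deviation.

    Means/sds ignore folds where a metric is undefined; a metric undefined
    in every fold has mean None.
    """

    folds: list[dict[str, float | None]] = field(default_factory=list)

    def summary(self) -> dict[str, tuple[float | None, float | None]]:
        out = {}
        for name in METRIC_NAMES:
            vals = [f[name] for f in self.folds if f[name] is not None]
            if not vals:
                out[name] = (None, None)
            else:
                out[name] = (mean(vals), stdev(vals) if len(vals) > 1 else 0.0)
        return out

    def mean_accuracy(self) -> float:
        m = self.summary()["accuracy"][0]
        if m is None:
            raise ValueError("accuracy undefined in every fold")
        return m


def _fit_fold(
    Va_tr: np.ndarray,
    Vb_tr: np.ndarray,
    y_tr: np.ndarray,
    hidden: list[int],
    cfg: TrainConfig,
    seed: int,
) -> tuple[SAEModel, PairScaler]:
    """Fit the pair scaler and SAE on training data only."""
    scaler = PairScaler().fit(np.vstack([Va_tr, Vb_tr]))
    X_tr = np.hstack([scaler.transform(Va_tr), scaler.transform(Vb_tr)])
    model = SAEModel([X_tr.shape[1], *hidden, 2], seed=seed)
    fold_cfg = TrainConfig(
        learning_rate=cfg.learning_rate,
        finetune_learning_rate=cfg.finetune_learning_rate,
        momentum=cfg.momentum,
        pretrain_epochs=cfg.pretrain_epochs,
        finetune_epochs=cfg.finetune_epochs,
        batch_size=cfg.batch_size,
        seed=seed,
    )
    model.fit(X_tr, y_tr, fold_cfg)
    return model, scaler


def cross_validate(
    Va: np.ndarray,
    Vb: np.ndarray,
    y: np.ndarray,
    hidden: list[int],
    cfg: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full scaler + SAE pipeline.

    ``Va`` and ``Vb`` are the unscaled per-protein feature vectors of each
    pair's two members (rows aligned with ``y``).  For every fold the
    min-max scaler and the network are fitted on the k-1 training folds
    only, so no information from the evaluated fold leaks into training.
    """
    if cfg is None:
        cfg = TrainConfig()
    y = np.asarray(y, dtype=int)
    folds = make_folds(y, k=k, seed=seed)
    report = MetricsReport()
    for fold in range(k):
        test_mask = folds == fold
        y_tr = y[~test_mask]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training split contains a single class")
        model, scaler = _fit_fold(
            Va[~test_mask], Vb[~test_mask], y_tr, hidden, cfg, seed=seed + fold
        )
        X_te = np.hstack(
            [scaler.transform(Va[test_mask]), scaler.transform(Vb[test_mask])]
        )
        y_pred = model.predict(X_te)
        report.folds.append(metrics(confusion(y[test_mask], y_pred)))
    return report


def architecture_sweep(
    Va: np.ndarray,
    Vb: np.ndarray,
    y: np.ndarray,
    candidates: list[list[int]],
    cfg: TrainConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[list[dict], list[int]]:
    """Cross-validate each hidden-layer candidate and pick the best.

    Returns the full result table (one row per candidate with its mean and
    sd of CV accuracy) and the selected hidden-layer sizes: highest mean
    accuracy, ties broken toward the architecture with fewer parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate architecture")
    d = 2 * Va.shape[1]

    def n_params(hidden: list[int]) -> int:
        sizes = [d, *hidden, 2]
        return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))

    table = []
    for hidden in candidates:
        report = cross_validate(Va, Vb, y, hidden, cfg, k=k, seed=seed)
        acc_mean, acc_sd = report.summary()["accuracy"]
        table.append(
            {
                "hidden": list(hidden),
                "mean_accuracy": acc_mean,
                "sd_accuracy": acc_sd,
                "n_params": n_params(hidden),
            }
        )
    best = max(table, key=lambda row: (row["mean_accuracy"], -row["n_params"]))
    return table, list(best["hidden"])
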