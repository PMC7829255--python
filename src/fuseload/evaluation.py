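"""Evaluation metrics: label error, LoW, histograms, confusion, chance.

All metrics operate in label space ([0, 1]) and convert to levels of
workload (LoW, 1/6 of label space per level) for reporting.  Predictions
are continuous; class-style metrics (confusion matrix, accuracy) first
snap each prediction to the nearest label value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LEVEL_WIDTH, low_from_error
from .models import ModelSpec
from .training import TrainConfig, holdout_train

__all__ = [
    "EvalReport",
    "AblationReport",
    "mean_abs_error",
    "within_fraction",
    "bin_to_nearest_label",
    "confusion",
    "chance_accuracy",
    "error_histogram",
    "evaluate",
    "run_ablation",
]


@dataclass
class EvalReport:
    mean_abs_error: float
    low: float
    within_1_level: float
    within_1_5_levels: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    error_mean: float
    error_sd: float
    confusion_counts: np.ndarray
    confusion_proportions: np.ndarray
    accuracy: float
    off_by_one_accuracy: float
    chance_accuracy_pct: float
    off_by_one_chance_pct: float
    label_values: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class AblationReport:
    rows: list[dict] = field(default_factory=list)  # variant, modalities, mae, low


def _check_lengths(predictions, labels):
    p = np.asarray(predictions, dtype=np.float64).reshape(-1)
    y = np.asarray(labels, dtype=np.float64).reshape(-1)
    if p.size != y.size:
        raise ValueError(f"length mismatch: {p.size} predictions vs {y.size} labels")
    if p.size == 0:
        raise ValueError("empty inputs")
    return p, y


def mean_abs_error(predictions, labels) -> float:
    """Mean of |prediction - label| in label space."""
    p, y = _check_lengths(predictions, labels)
    return float(np.mean(np.abs(p - y)))


def within_fraction(predictions, labels, tolerance_levels: float) -> float:
    """Fraction of samples within ``tolerance_levels`` levels of workload."""
    if tolerance_levels < 0:
        raise ValueError("tolerance must be >= 0")
    p, y = _check_lengths(predictions, labels)
    return float(np.mean(np.abs(p - y) <= tolerance_levels * LEVEL_WIDTH + 1e-12))


def bin_to_nearest_label(prediction: float, label_values) -> int:
    """Index of the label value closest to ``prediction``; ties go low."""
    vals = np.asarray(label_values, dtype=np.float64)
    if vals.size == 0:
        raise ValueError("label_values must be non-empty")
    d = np.abs(vals - float(prediction))
    return int(np.argmin(d))  # argmin takes the first (lower) index on ties


def confusion(predictions, labels, label_values):
    """Nearest-label confusion matrix: counts and row-relative proportions.

    Rows are true classes, columns the classes predictions were binned
    into.  Returns ``(counts, proportions, accuracy, off_by_one_accuracy)``
    where off-by-one counts |row - col| <= 1 as correct.
    """
    p, y = _check_lengths(predictions, labels)
    vals = np.asarray(label_values, dtype=np.float64)
    k = vals.size
    true_idx = np.empty(p.size, dtype=int)
    for i, label in enumerate(y):
        j = np.argmin(np.abs(vals - label))
        if abs(vals[j] - label) > 1e-9:
            raise ValueError(f"label {label} not among label_values")
        true_idx[i] = j
    pred_idx = np.array([bin_to_nearest_label(x, vals) for x in p])
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true_idx, pred_idx), 1)
    rowsums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = np.where(rowsums > 0, counts / rowsums, 0.0)
    accuracy = float(np.trace(counts) / counts.sum())
    off_by_one = float(
        counts[np.abs(np.subtract.outer(np.arange(k), np.arange(k))) <= 1].sum()
        / counts.sum()
    )
    return counts, proportions, accuracy, off_by_one


def chance_accuracy(n_classes: int, neighbourhood: int = 0,
                    mode: str = "uniform-approximation") -> float:
    """Expected accuracy (percent) of a uniform random classifier.

    ``uniform-approximation`` ignores edge classes:
    ``100 * (2 * neighbourhood + 1) / n_classes`` capped at 100 (the 3/7
    = 43 % convention).  ``exact-edge-aware`` enumerates all (true,
    predicted) pairs under uniform labels, so edge classes with fewer
    neighbours count properly.
    """
    if n_classes < 1 or neighbourhood < 0:
        raise ValueError("need n_classes >= 1 and neighbourhood >= 0")
    if mode == "uniform-approximation":
        return 100.0 * min(1.0, (2 * neighbourhood + 1) / n_classes)
    if mode == "exact-edge-aware":
        i, j = np.meshgrid(np.arange(n_classes), np.arange(n_classes))
        hits = (np.abs(i - j) <= neighbourhood).sum()
        return 100.0 * hits / n_classes**2
    raise ValueError(f"unknown mode {mode!r}")


def error_histogram(predictions, labels, bin_width: float = 1.0 / 24.0):
    """Histogram of signed errors (prediction - label) with mean and SD.

    Offsets every prediction by its true label so a perfect model piles
    all mass at zero; the +-1/6 one-level bounds are the natural reference
    lines.  Returns ``(edges, counts, mu, sigma)``.
    """
    p, y = _check_lengths(predictions, labels)
    err = p - y
    lo = np.floor(min(err.min(), -LEVEL_WIDTH) / bin_width) * bin_width
    hi = np.ceil(max(err.max(), LEVEL_WIDTH) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(err, bins=edges)
    return edges, counts, float(err.mean()), float(err.std(ddof=0))


def evaluate(predictions, labels, label_values,
             n_classes_for_chance: int | None = None) -> EvalReport:
    """Assemble the full evaluation report for one prediction set."""
    p, y = _check_lengths(predictions, labels)
    vals = np.asarray(label_values, dtype=np.float64)
    mae = mean_abs_error(p, y)
    edges, hist_counts, mu, sd = error_histogram(p, y)
    counts, proportions, acc, off1 = confusion(p, y, vals)
    k = n_classes_for_chance or vals.size
    return EvalReport(
        mean_abs_error=mae,
        low=low_from_error(mae),
        within_1_level=within_fraction(p, y, 1.0),
        within_1_5_levels=within_fraction(p, y, 1.5),
        hist_edges=edges,
        hist_counts=hist_counts,
        error_mean=mu,
        error_sd=sd,
        confusion_counts=counts,
        confusion_proportions=proportions,
        accuracy=acc,
        off_by_one_accuracy=off1,
        chance_accuracy_pct=chance_accuracy(k, 0),
        off_by_one_chance_pct=chance_accuracy(k, 1),
        label_values=vals,
    )


def run_ablation(
    sample_set,
    variants,
    modality_subsets,
    train_config: TrainConfig | None = None,
    hp_per_variant: dict | None = None,
    width_scale: float = 1.0,
) -> AblationReport:
    """Evaluate every (variant, modality subset) on a 90-10 holdout.

    ``hp_per_variant`` optionally supplies tuned hyperparameters (lr_max,
    momentum, dropout_rate) per variant, mirroring the reuse of the best
    multimodal settings for the unimodal runs.  The all-modality
    configuration is always included as a reference.
    """
    cfg = train_config or TrainConfig()
    subsets = [tuple(s) for s in modality_subsets]
    all_mods = ("PPG", "GSR", "ET", "fNIRS")
    if all_mods not in subsets:
        subsets.append(all_mods)
    report = AblationReport()
    for variant in variants:
        hp = (hp_per_variant or {}).get(variant, {})
        for subset in subsets:
            if not subset:
                raise ValueError("modality subsets must be non-empty")
            spec = ModelSpec(
                variant=variant,
                modalities=subset,
                dropout_rate=hp.get("dropout_rate", 0.1),
                width_scale=width_scale,
            )
            run_cfg = TrainConfig(
                lr_max=hp.get("lr_max", cfg.lr_max),
                momentum=hp.get("momentum", cfg.momentum),
                batch_size=cfg.batch_size,
                epochs_per_fold=cfg.epochs_per_fold,
                folds=cfg.folds,
                holdout_fraction=cfg.holdout_fraction,
                seed=cfg.seed,
            )
            _, _, preds, yte = holdout_train(spec, sample_set, run_cfg)
            mae = mean_abs_error(preds, yte)
            report.rows.append(
                {
                    "variant": variant,
                    "modalities": subset,
                    "mean_abs_error": mae,
                    "low": low_from_error(mae),
                }
            )
    return report


# ---------------------------------------------------------------------------
# plotting (thin, optional)


def plot_histogram(report: EvalReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (report.hist_edges[:-1] + report.hist_edges[1:]) / 2
    ax.bar(centers, report.hist_counts, width=np.diff(report.hist_edges), color="C0")
    for x in (-LEVEL_WIDTH, LEVEL_WIDTH):
        ax.axvline(x, color="k", ls="--", lw=1)
    ax.set_xlabel("prediction - label")
    ax.set_ylabel("count")
    ax.set_title(f"mu={report.error_mean:.3f}, sigma={report.error_sd:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_confusion(report: EvalReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(report.confusion_proportions, cmap="Blues", vmin=0, vmax=1)
    k = report.confusion_counts.shape[0]
    for i in range(k):
        for j in range(k):
            ax.text(j, i,
                    f"{report.confusion_counts[i, j]}\n({report.confusion_proportions[i, j]:.2f})",
                    ha="center", va="center", fontsize=7)
    ax.set_xlabel("predicted class")
    ax.set_ylabel("true class")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
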