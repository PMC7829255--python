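"""Model training: MSE loss, SGD with momentum, 1Cycle schedule, CV.

The objective throughout is the mean squared error between the sigmoid
output and the [0, 1] label; model selection reports the mean *absolute*
label error, which converts directly to levels of workload.  Training
uses stochastic gradient descent with momentum under a triangular
("pyramidal") 1Cycle learning-rate policy: linear ramp from ``lr_max/10``
up to ``lr_max`` over the first half of all training steps, then back
down.  Cross-validation is 5-fold with a fresh model per fold; the
holdout mode is a seeded random 90-10 split.

Inputs are standardised per channel with statistics of the training
portion only; the fitted scaler travels with the network handle so
inference sees the same transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .models import ModelSpec, NetworkHandle, build_model, predict
from .nn import mse_loss, sgd_momentum_step
from .segmentation import SampleSet

__all__ = [
    "TrainConfig",
    "FoldResult",
    "TrainingDivergedError",
    "one_cycle_lr",
    "train_model",
    "cross_validate",
    "holdout_train",
]


@dataclass
class TrainConfig:
    lr_max: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32
    epochs_per_fold: int = 25
    folds: int = 5
    holdout_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_max <= 0:
            raise ValueError("lr_max must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.epochs_per_fold < 1 or self.folds < 1:
            raise ValueError("epochs and folds must be >= 1")


@dataclass
class FoldResult:
    fold: int
    mean_abs_error: float
    history: list[float] = field(default_factory=list)
    test_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        if self.mean_abs_error < 0:
            raise ValueError("error must be >= 0")


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; carries the history up to the failure."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


def one_cycle_lr(step: int, total_steps: int, lr_max: float) -> float:
    """Triangular 1Cycle schedule value at ``step`` of ``total_steps``.

    Rises linearly from ``lr_max / 10`` to ``lr_max`` at the midpoint and
    falls symmetrically back; ``lr(s) == lr(total_steps - s)``.
    """
    if total_steps <= 0:
        raise ValueError("total_steps must be > 0")
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    base = lr_max / 10.0
    half = total_steps / 2.0
    frac = step / half if step <= half else (total_steps - step) / half
    return base + (lr_max - base) * frac


def _as_arrays(data, modalities) -> tuple[dict[str, np.ndarray], np.ndarray]:
    if isinstance(data, SampleSet):
        return data.to_arrays(modalities), data.labels
    inputs, y = data
    return ({m: np.asarray(inputs[m]) for m in modalities},
            np.asarray(y, dtype=np.float64))


def _fit_scalers(inputs: dict[str, np.ndarray]) -> dict:
    scalers = {}
    for m, x in inputs.items():
        mean = x.mean(axis=(0, 1), keepdims=True).astype(np.float32)
        std = x.std(axis=(0, 1), keepdims=True).astype(np.float32)
        std[std < 1e-8] = 1.0
        scalers[m] = (mean[0], std[0])  # broadcast over (time, channels)
    return scalers


def train_model(
    spec: ModelSpec,
    data,
    config: TrainConfig | None = None,
    handle: NetworkHandle | None = None,
) -> tuple[NetworkHandle, list[float]]:
    """Train one model; returns the handle and per-epoch training loss.

    ``data`` is a :class:`SampleSet` or a ``(inputs, labels)`` pair.  The
    data order is reshuffled every epoch with a seeded generator; with a
    fixed config the run is deterministic.
    """
    config = config or TrainConfig()
    inputs, y = _as_arrays(data, spec.modalities)
    n = y.shape[0]
    if n == 0:
        raise ValueError("cannot train on an empty sample set")
    if handle is None:
        handle = build_model(spec, seed=config.seed)
    if handle.scalers is None:
        handle.scalers = _fit_scalers(inputs)
    X = {
        m: ((inputs[m] - handle.scalers[m][0]) / handle.scalers[m][1]).astype(np.float32)
        for m in spec.modalities
    }
    rng = np.random.default_rng(config.seed)
    net = handle.network
    bs = min(config.batch_size, n)
    n_batches = int(np.ceil(n / bs))
    total_steps = config.epochs_per_fold * n_batches
    history: list[float] = []
    step = 0
    for _ in range(config.epochs_per_fold):
        perm = rng.permutation(n)
        losses = []
        for b in range(n_batches):
            idx = perm[b * bs : (b + 1) * bs]
            batch = {m: X[m][idx] for m in spec.modalities}
            pred = net.forward(batch, train=True)
            loss, dpred = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss diverged at step {step}", history + losses
                )
            net.zero_grad()
            net.backward(dpred.astype(np.float32))
            step += 1
            lr = one_cycle_lr(step, total_steps, config.lr_max)
            sgd_momentum_step(net.params, lr, config.momentum)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return handle, history


def cross_validate(
    spec: ModelSpec, sample_set, config: TrainConfig | None = None
) -> tuple[list[FoldResult], float]:
    """K-fold CV: fresh model per fold, mean absolute label error per fold.

    Every sample lands in exactly one test fold; the returned objective is
    the mean over folds of the test-fold mean absolute error.
    """
    config = config or TrainConfig()
    inputs, y = _as_arrays(sample_set, spec.modalities)
    n = y.shape[0]
    if n < config.folds:
        raise ValueError(f"need at least {config.folds} samples, got {n}")
    kf = KFold(n_splits=config.folds, shuffle=True,
               random_state=int(config.seed) % (2**31))
    results: list[FoldResult] = []
    for fold, (tr, te) in enumerate(kf.split(y)):
        fold_cfg = TrainConfig(**{**config.__dict__, "seed": config.seed + 1000 * fold + 1})
        handle, hist = train_model(
            spec, ({m: inputs[m][tr] for m in spec.modalities}, y[tr]), fold_cfg
        )
        preds = predict(handle, {m: inputs[m][te] for m in spec.modalities})
        err = float(np.mean(np.abs(preds - y[te])))
        results.append(
            FoldResult(fold=fold, mean_abs_error=err, history=hist,
                       test_indices=np.asarray(te))
        )
    return results, float(np.mean([r.mean_abs_error for r in results]))


def holdout_split(n: int, holdout_fraction: float, seed: int):
    """Seeded random split; train size is ``floor((1 - fraction) * n)``."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor((1.0 - holdout_fraction) * n))
    return perm[:n_train], perm[n_train:]


def holdout_train(
    spec: ModelSpec, sample_set, config: TrainConfig | None = None
):
    """Train on a seeded 90-10 split; return handle + held-out predictions.

    Returns ``(handle, test_indices, predictions, test_labels)``.
    """
    config = config or TrainConfig()
    inputs, y = _as_arrays(sample_set, spec.modalities)
    n = y.shape[0]
    if n < 10:
        raise ValueError("holdout training needs at least 10 samples")
    tr, te = holdout_split(n, config.holdout_fraction, config.seed)
    handle, _ = train_model(
        spec, ({m: inputs[m][tr] for m in spec.modalities}, y[tr]), config
    )
    preds = predict(handle, {m: inputs[m][te] for m in spec.modalities})
    return handle, te, preds, y[te]
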