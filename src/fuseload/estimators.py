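"""Scikit-learn style estimator facade over the fusion pipeline.

:class:`WorkloadFusionRegressor` wraps model construction and training in
the familiar fit/predict contract so the network composes with sklearn
model selection; ``X`` is a mapping modality -> ``(n, time, channels)``
array (or a :class:`~fuseload.segmentation.SampleSet`), ``y`` the labels
in [0, 1].
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .models import ModelSpec, predict as _predict
from .segmentation import SampleSet
from .streams import MODALITIES
from .training import TrainConfig, train_model

__all__ = ["WorkloadFusionRegressor"]


class WorkloadFusionRegressor(BaseEstimator, RegressorMixin):
    """Intermediate-fusion workload regressor with a sigmoid output.

    Parameters mirror the architecture and training knobs: the variant
    (``MLP``/``S_MLP``/``LIT``/``S_LIT``), the enabled modalities, the
    dropout rate, a width scale for reduced-size replicas, the 1Cycle
    peak learning rate, SGD momentum, batch size and epochs.

    Examples
    --------
    >>> reg = WorkloadFusionRegressor(variant="S_MLP", epochs=10,
    ...                               width_scale=0.5, random_state=0)
    >>> reg.fit(sample_set)                 # doctest: +SKIP
    >>> reg.predict(sample_set)             # doctest: +SKIP
    """

    def __init__(
        self,
        variant: str = "S_MLP",
        modalities: tuple = MODALITIES,
        dropout_rate: float = 0.1,
        width_scale: float = 1.0,
        lr_max: float = 0.05,
        momentum: float = 0.9,
        batch_size: int = 32,
        epochs: int = 25,
        random_state: int | None = None,
    ):
        self.variant = variant
        self.modalities = modalities
        self.dropout_rate = dropout_rate
        self.width_scale = width_scale
        self.lr_max = lr_max
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            variant=self.variant,
            modalities=tuple(self.modalities),
            dropout_rate=self.dropout_rate,
            width_scale=self.width_scale,
        )

    @staticmethod
    def _coerce(X, y):
        if isinstance(X, SampleSet):
            return X, X.labels
        if y is None:
            raise ValueError("y is required when X is not a SampleSet")
        return (X, np.asarray(y, dtype=np.float64)), np.asarray(y, dtype=np.float64)

    def fit(self, X, y=None):
        data, labels = self._coerce(X, y)
        spec = self._spec()
        cfg = TrainConfig(
            lr_max=self.lr_max,
            momentum=self.momentum,
            batch_size=self.batch_size,
            epochs_per_fold=self.epochs,
            seed=0 if self.random_state is None else int(self.random_state),
        )
        self.handle_, self.history_ = train_model(spec, data, cfg)
        self.spec_ = spec
        self.n_samples_seen_ = int(labels.shape[0])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "handle_"):
            raise AttributeError("estimator is not fitted; call fit first")
        inputs = X.to_arrays(self.spec_.modalities) if isinstance(X, SampleSet) else X
        return _predict(self.handle_, inputs)
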