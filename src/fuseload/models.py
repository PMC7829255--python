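"""The four intermediate-fusion network variants.

Each architecture is a set of per-modality branch networks (MNets) whose
flattened outputs are projected by a single dense layer into a shared
representation; the concatenated projections feed a Head network ending
in one sigmoid unit, so predictions live in [0, 1].

Variants: ``MLP`` (dense-only MNets and Head), ``LIT`` (literature-based
MNets: convolutions for PPG/ET, conv+LSTM for GSR, conv+dense for fNIRS,
a conv-bearing Head) and their small siblings ``S_MLP`` / ``S_LIT`` with
exactly half the units/filters in every layer.  Per-modality projection
widths at full size: PPG 256, GSR 256, ET 1024, fNIRS 2048, so the
all-modality fused width is 3584.

Removing a modality removes only its branch and narrows the Head input;
nothing else changes, which is what makes modalities freely switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    LSTM,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    FusionNetwork,
    MaxPool1D,
    ReLU,
    Reshape1D,
    Sequential,
    Sigmoid,
)
from .streams import CHANNELS, DEFAULT_RATES, MODALITIES

__all__ = ["ModelSpec", "NetworkHandle", "build_mnet", "build_model",
           "fused_width", "predict", "VARIANTS", "PROJECTION_WIDTHS"]

VARIANTS = ("MLP", "S_MLP", "LIT", "S_LIT")

#: Full-size dense projection width per modality (the MNet output width).
PROJECTION_WIDTHS = {"PPG": 256, "GSR": 256, "ET": 1024, "fNIRS": 2048}

# Full-size layer widths; S_ variants take floor(width / 2) layer-for-layer.
_MLP_WIDTHS = {
    "PPG": [256, 256],
    "GSR": [256, 256],
    "ET": [1024, 1024, 1024],
    "fNIRS": [2048, 2048, 2048],
}
_MLP_HEAD = [3584, 2048, 1024, 512]  # leading width == all-modality fused width

_LIT_CONV = {"PPG": [128, 128], "GSR": [128, 128],
             "ET": [256, 256, 256, 256], "fNIRS": [512, 512]}
_LIT_LSTM = {"GSR": [256, 256]}
_LIT_DENSE = {"PPG": [256], "GSR": [256], "ET": [1024], "fNIRS": [2048, 2048, 2048]}
_LIT_HEAD_DENSE12 = [3584, 4096]
_LIT_HEAD_CONV = [512, 512, 256]
_LIT_HEAD_DENSE34 = [512, 256]


def _default_input_shapes(window_length: float = 8.0) -> dict[str, tuple[int, int]]:
    return {
        m: (int(round(window_length * DEFAULT_RATES[m])), CHANNELS[m])
        for m in MODALITIES
    }


@dataclass
class ModelSpec:
    """Architecture description: variant, enabled modalities, widths.

    ``width_scale`` uniformly scales every layer width (after the S_
    halving), allowing reduced-size replicas of the same architecture for
    CPU-scale experiments; 1.0 reproduces the published widths.
    """

    variant: str = "S_MLP"
    modalities: tuple = MODALITIES
    dropout_rate: float = 0.1
    width_scale: float = 1.0
    input_shapes: dict = field(default_factory=_default_input_shapes)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {VARIANTS}")
        bad = [m for m in self.modalities if m not in MODALITIES]
        if bad:
            raise ValueError(f"unknown modalities {bad}; expected subset of {MODALITIES}")
        if not self.modalities:
            raise ValueError("at least one modality must be enabled")
        # canonical concatenation order: (PPG, GSR, ET, fNIRS)
        self.modalities = tuple(m for m in MODALITIES if m in self.modalities)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be > 0")

    @property
    def is_small(self) -> bool:
        return self.variant.startswith("S_")

    @property
    def is_lit(self) -> bool:
        return self.variant.endswith("LIT")

    def width(self, full: int) -> int:
        w = full // 2 if self.is_small else full
        return max(1, int(w * self.width_scale))

    def projection_width(self, modality: str) -> int:
        return self.width(PROJECTION_WIDTHS[modality])


def fused_width(spec: ModelSpec) -> int:
    """Sum of dense-projection widths over the enabled modalities."""
    return sum(spec.projection_width(m) for m in spec.modalities)


def _dense_block(seq, in_f, out_f, rng, dropout):
    seq.append(Dense(in_f, out_f, rng))
    seq.append(ReLU())
    if dropout > 0:
        seq.append(Dropout(dropout, rng))
    return out_f


def _conv_block(seq, in_ch, out_ch, rng, T):
    seq.append(Conv1D(in_ch, out_ch, rng))
    seq.append(BatchNorm(out_ch))
    seq.append(ReLU())
    seq.append(MaxPool1D(2))
    return out_ch, T // 2


def build_mnet(
    modality: str,
    variant: str,
    dropout_rate: float = 0.1,
    rng: np.random.Generator | None = None,
    spec: ModelSpec | None = None,
) -> Sequential:
    """Build one per-modality branch network ending in its projection."""
    spec = spec or ModelSpec(variant=variant, dropout_rate=dropout_rate)
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    rng = rng or np.random.default_rng(0)
    T, C = spec.input_shapes[modality]
    layers: list = []
    proj = spec.projection_width(modality)
    if not spec.is_lit:  # MLP family: flatten then dense stack
        f = T * C
        layers.append(Flatten())
        widths = [spec.width(w) for w in _MLP_WIDTHS[modality]]
        for w in widths[:-1]:
            f = _dense_block(layers, f, w, rng, spec.dropout_rate)
        layers.append(Dense(f, proj, rng))  # final dense = the projection
        layers.append(ReLU())
    else:  # LIT family
        ch, t = C, T
        for w in _LIT_CONV[modality]:
            ch, t = _conv_block(layers, ch, spec.width(w), rng, t)
        if modality in _LIT_LSTM:
            h1, h2 = (spec.width(w) for w in _LIT_LSTM[modality])
            layers.append(LSTM(ch, h1, rng, return_sequences=True))
            layers.append(LSTM(h1, h2, rng, return_sequences=False))
            f = h2
        else:
            layers.append(Flatten())
            f = ch * t
        dense_widths = [spec.width(w) for w in _LIT_DENSE[modality]]
        for w in dense_widths[:-1]:
            f = _dense_block(layers, f, w, rng, spec.dropout_rate)
        layers.append(Dense(f, proj, rng))
        layers.append(ReLU())
    return Sequential(layers)


def _build_head(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    f = fused_width(spec)
    layers: list = []
    if not spec.is_lit:
        widths = [spec.width(w) for w in _MLP_HEAD[1:]]
        # head Dense1 width tracks the fused width of the enabled subset
        f = _dense_block(layers, f, fused_width(spec), rng, spec.dropout_rate)
        for w in widths:
            f = _dense_block(layers, f, w, rng, spec.dropout_rate)
    else:
        f = _dense_block(layers, f, fused_width(spec), rng, spec.dropout_rate)
        d2 = spec.width(_LIT_HEAD_DENSE12[1])
        f = _dense_block(layers, f, d2, rng, spec.dropout_rate)
        layers.append(Reshape1D())
        ch, t = 1, f
        for w in _LIT_HEAD_CONV:
            ch, t = _conv_block(layers, ch, spec.width(w), rng, t)
        layers.append(Flatten())
        f = ch * t
        for w in _LIT_HEAD_DENSE34:
            f = _dense_block(layers, f, spec.width(w), rng, spec.dropout_rate)
    layers.append(Dense(f, 1, rng))
    layers.append(Sigmoid())
    return Sequential(layers)


@dataclass
class NetworkHandle:
    """A built (possibly trained) network plus its spec and scalers."""

    network: FusionNetwork
    spec: ModelSpec
    scalers: dict | None = None  # modality -> (mean, std) input standardisation

    @property
    def n_params(self) -> int:
        return self.network.n_params


def build_model(spec: ModelSpec, seed: int = 0) -> NetworkHandle:
    """Instantiate the full fusion network for a spec, seeded."""
    rng = np.random.default_rng(seed)
    mnets = {
        m: build_mnet(m, spec.variant, spec.dropout_rate, rng=rng, spec=spec)
        for m in spec.modalities
    }
    head = _build_head(spec, rng)
    return NetworkHandle(network=FusionNetwork(mnets, head), spec=spec)


def _standardise(handle: NetworkHandle, inputs: dict[str, np.ndarray]):
    if not handle.scalers:
        return inputs
    out = {}
    for m, x in inputs.items():
        if m in handle.scalers:
            mean, std = handle.scalers[m]
            out[m] = (x - mean) / std
        else:
            out[m] = x
    return out


def predict(handle: NetworkHandle, inputs: dict[str, np.ndarray],
            batch_size: int = 256) -> np.ndarray:
    """Deterministic inference (dropout off); one value in [0, 1] per sample."""
    for m in handle.spec.modalities:
        if m not in inputs:
            raise KeyError(f"missing input for modality {m!r}")
        want = handle.spec.input_shapes[m]
        got = inputs[m].shape[1:]
        if tuple(got) != tuple(want):
            raise ValueError(f"modality {m!r}: window shape {got} != expected {want}")
    inputs = _standardise(handle, inputs)
    n = next(iter(inputs.values())).shape[0]
    outs = []
    for lo in range(0, n, batch_size):
        batch = {m: np.asarray(x[lo : lo + batch_size], dtype=np.float32)
                 for m, x in inputs.items()}
        outs.append(handle.network.forward(batch, train=False).reshape(-1))
    return np.concatenate(outs) if outs else np.zeros(0)
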