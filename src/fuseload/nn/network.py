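"""Containers and the optimiser step."""

from __future__ import annotations

import numpy as np

from .layers import Layer, Param


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        self.params = [p for layer in layers for p in layer.params]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class FusionNetwork:
    """Per-modality branch networks whose outputs concatenate into a head.

    ``mnets`` is an ordered mapping modality -> Sequential; each branch
    ends in its dense projection, the concatenation of projections feeds
    ``head``, which ends in a single sigmoid unit.
    """

    def __init__(self, mnets: dict[str, Sequential], head: Sequential):
        self.mnets = mnets
        self.head = head
        self.params: list[Param] = [
            p for net in mnets.values() for p in net.params
        ] + list(head.params)

    @property
    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, inputs: dict[str, np.ndarray], train: bool = False) -> np.ndarray:
        outs = []
        self._widths = []
        for m, net in self.mnets.items():
            if m not in inputs:
                raise KeyError(f"missing input for modality {m!r}")
            z = net.forward(inputs[m], train=train)
            outs.append(z)
            self._widths.append(z.shape[1])
        fused = np.concatenate(outs, axis=1)
        return self.head.forward(fused, train=train)

    def backward(self, grad: np.ndarray) -> None:
        dfused = self.head.backward(grad)
        offset = 0
        for (m, net), w in zip(self.mnets.items(), self._widths):
            net.backward(dfused[:, offset : offset + w])
            offset += w

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. the prediction."""
    pred = pred.reshape(-1)
    diff = pred - target.astype(pred.dtype)
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.reshape(-1, 1)


def sgd_momentum_step(params: list[Param], lr: float, momentum: float) -> None:
    """Classical momentum update: v <- m v - lr g; w <- w + v."""
    for p in params:
        p.velocity = momentum * p.velocity - lr * p.grad
        p.value += p.velocity
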