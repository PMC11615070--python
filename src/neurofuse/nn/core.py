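"""Minimal NumPy neural-network kernel: parameters, modules, FLOP tape.

Layers implement ``forward`` plus an explicit ``backward`` that consumes the
gradient of the loss w.r.t. their output and returns the gradient w.r.t. their
input(s), accumulating parameter gradients in place. Intermediate activations
are cached only while ``training`` is set, so full-resolution inference runs
without holding im2col buffers.
"""

from __future__ import annotations

import contextlib
from typing import Iterator

import numpy as np

DTYPE = np.float32


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class FlopTape:
    """Accumulates floating-point operations under the 2x-MACs convention.

    Multiply-accumulates count as two FLOPs; bias terms count their additions;
    normalization, activations and pooling are excluded by convention.
    """

    convention = "2*MACs, conv/linear/attention only, + bias adds"

    def __init__(self) -> None:
        self.flops = 0

    def add(self, macs: int = 0, adds: int = 0) -> None:
        self.flops += 2 * int(macs) + int(adds)


_TAPE: FlopTape | None = None


@contextlib.contextmanager
def flop_tape():
    """Context manager recording FLOPs of every layer executed inside it."""
    global _TAPE
    tape = FlopTape()
    prev, _TAPE = _TAPE, tape
    try:
        yield tape
    finally:
        _TAPE = prev


def record_flops(macs: int = 0, adds: int = 0) -> None:
    if _TAPE is not None:
        _TAPE.add(macs, adds)


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    training: bool = True

    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, *grads):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- introspection ----------------------------------------------------
    def _children(self) -> Iterator["Module"]:
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self) -> Iterator[Parameter]:
        for module in self.modules():
            for value in module.__dict__.values():
                if isinstance(value, Parameter):
                    yield value
                elif isinstance(value, (list, tuple)):
                    for item in value:
                        if isinstance(item, Parameter):
                            yield item

    # -- state ------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for module in self.modules():
            module.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- (de)serialization -------------------------------------------------
    def state_list(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_list(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError(
                f"state mismatch: model has {len(params)} parameters, "
                f"got {len(arrays)} arrays"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data[...] = a


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
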