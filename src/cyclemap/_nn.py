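"""Neural-network building blocks on top of the autodiff core.

Layers follow the DCGAN idiom used by the manifold networks: stride-2
4x4 convolutions, batch normalisation, leaky-ReLU.  Parameters are plain
NumPy arrays wrapped in :class:`~cyclemap._autodiff.Tensor`; a module's
``state_dict`` is a flat name -> array mapping, which keeps checkpoints a
single ``.npz`` file.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvTranspose2d", "Dense",
    "BatchNorm2d", "LeakyReLU", "Sigmoid", "Flatten", "Reshape", "Adam",
]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v.data for k, v in self._params.items()}
        out.update({prefix + k: v for k, v in self._buffers.items()})
        for name, child in self._children.items():
            out.update(child.named_state(prefix + name + "."))
        return out

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for k, t in self._params.items():
            t.data = np.array(state[prefix + k], dtype=t.data.dtype)
        for k in self._buffers:
            self._buffers[k] = np.array(state[prefix + k])
        for name, child in self._children.items():
            child.load_state(state, prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = layers
        for i, layer in enumerate(layers):
            self._children[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _normal_init(rng: np.random.Generator, shape, std: float, dtype) -> np.ndarray:
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=4, stride=2, padding=1, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        # He-style scaling keeps activations stable through stacked stride-2 convs
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = self.register(
            "weight", _normal_init(rng, (c_out, c_in, kernel, kernel), std, dtype))
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel=4, stride=2, padding=1, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.stride, self.padding = stride, padding
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = self.register(
            "weight", _normal_init(rng, (c_in, c_out, kernel, kernel), std, dtype))
        self.bias = self.register("bias", np.zeros(c_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)


class Dense(Module):
    def __init__(self, n_in, n_out, *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.weight = self.register("weight", _normal_init(rng, (n_in, n_out), std, dtype))
        self.bias = self.register("bias", np.zeros(n_out, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel, with running stats."""

    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = self.register("gamma", np.ones(c, dtype=dtype))
        self.beta = self.register("beta", np.zeros(c, dtype=dtype))
        self._buffers["running_mean"] = np.zeros(c, dtype=np.float64)
        self._buffers["running_var"] = np.ones(c, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=0, keepdims=True).mean(axis=2, keepdims=True) \
                    .mean(axis=3, keepdims=True)
            var = ((x - mean) ** 2).mean(axis=0, keepdims=True) \
                .mean(axis=2, keepdims=True).mean(axis=3, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"]
                + m * mean.data.reshape(c).astype(np.float64))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"]
                + m * var.data.reshape(c).astype(np.float64))
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1)
                          .astype(x.dtype))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1)
                         .astype(x.dtype))
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], -1)


class Reshape(Module):
    def __init__(self, *shape):
        super().__init__()
        self.shape = shape

    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], *self.shape)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr=1e-4, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def state(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
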