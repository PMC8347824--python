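"""Layer modules over the autodiff core: parameter containers with a
``forward`` method, Kaiming initialisation, train/eval mode, and flat
state-dict serialisation."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Module:
    """Base class: child modules and parameters are discovered from
    ``__dict__``, in definition order."""

    def __init__(self):
        self.training = True

    # -- discovery ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_modules(self, prefix: str = "") -> list[tuple[str, "Module"]]:
        out = [(prefix, self)]
        for name, v in vars(self).items():
            if isinstance(v, Module):
                out.extend(v.named_modules(f"{prefix}.{name}" if prefix else name))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_modules(f"{prefix}.{name}.{i}" if prefix else f"{name}.{i}"))
        return out

    # -- state ----------------------------------------------------------
    def _buffers(self) -> list[tuple[str, np.ndarray]]:
        return [(k, v) for k, v in vars(self).items() if isinstance(v, np.ndarray)]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for mod_name, mod in self.named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    state[f"{mod_name}.{k}" if mod_name else k] = v.data.copy()
            for k, v in mod._buffers():
                state[f"{mod_name}.{k}" if mod_name else k] = v.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        for mod_name, mod in self.named_modules():
            for k, v in vars(mod).items():
                if isinstance(v, Tensor) and v.requires_grad:
                    own[f"{mod_name}.{k}" if mod_name else k] = v
                elif isinstance(v, np.ndarray):
                    own[f"{mod_name}.{k}" if mod_name else k] = v
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)[:3]} unexpected={sorted(unexpected)[:3]}")
        for k, target in own.items():
            src = np.asarray(state[k], dtype=np.float32)
            if isinstance(target, Tensor):
                if target.data.shape != src.shape:
                    raise ValueError(f"shape mismatch for {k}")
                target.data = src.copy()
            else:
                target[...] = src

    # -- mode -----------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(_kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_kaiming_normal(rng, (out_features, in_features), in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(x, self.weight, self.bias, self.running_mean, self.running_var,
                              training=self.training, momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in params]
        self._v = [np.zeros_like(p.data) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
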