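"""Small neural-network building blocks and optimizers on top of ``autodiff``.

Layers follow the usual conventions: NCHW tensors, He-normal initialization
from an explicit seeded generator (every constructor takes an ``rng``), batch
normalization with running statistics, AdamW with decoupled weight decay and
a cosine learning-rate schedule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Module", "Parameter", "Conv2d", "DepthwiseConv2d", "Linear",
    "BatchNorm2d", "Sequential", "AdamW", "cosine_lr", "save_state",
    "load_state",
]


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # state dict: ordered by recursive attribute path
    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out[name] = v.data
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                out[name] = v
            elif isinstance(v, Module):
                v._collect_state(name + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_state(f"{name}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = item.data

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = {}
        self._collect_refs("", own)
        missing = set(own) - set(arrays)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")
        for name, ref in own.items():
            holder, attr_or_idx = ref
            arr = np.array(arrays[name], dtype=np.float64)
            if isinstance(attr_or_idx, int):
                holder[attr_or_idx].data = arr
            else:
                tgt = getattr(holder, attr_or_idx)
                if isinstance(tgt, Parameter):
                    tgt.data = arr
                else:
                    setattr(holder, attr_or_idx, arr)

    def _collect_refs(self, prefix: str, out: dict) -> None:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter) or (
                    isinstance(v, np.ndarray) and k.startswith("running_")):
                out[name] = (self, k)
            elif isinstance(v, Module):
                v._collect_refs(name + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item._collect_refs(f"{name}.{i}.", out)
                    elif isinstance(item, Parameter):
                        out[f"{name}.{i}"] = (v, i)

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, k: int, *, stride: int = 1,
                 padding: int = 0, pad_mode: str = "zero", groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding, self.pad_mode, self.groups = stride, padding, pad_mode, groups
        fan_in = in_ch // groups * k * k
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, pad_mode=self.pad_mode,
                      groups=self.groups)


class DepthwiseConv2d(Module):
    """One k x k kernel per channel, stride 1, same-size output."""

    def __init__(self, ch: int, k: int, *, pad_mode: str = "zero",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.pad_mode = pad_mode
        self.weight = Parameter(_he_init(rng, (ch, k, k), k * k))
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import depthwise_conv2d

        return depthwise_conv2d(x, self.weight, pad_mode=self.pad_mode)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f))
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.eps, self.momentum = eps, momentum
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = centered / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - mu) / Tensor(sd)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class _ReLU(Module):
    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


def relu_layer() -> Module:
    return _ReLU()


class AdamW:
    """Adam with decoupled weight decay (applied to the raw weights)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.99),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(lr_init: float, t: int, total: int) -> float:
    """lr(t) = lr_init * 0.5 * (1 + cos(pi t / T)); lr(0)=lr_init, lr(T)=0."""
    if total <= 0:
        return lr_init
    return lr_init * 0.5 * (1.0 + np.cos(np.pi * t / total))


def save_state(model: Module, path: str | Path, manifest: dict | None = None) -> None:
    """Write model weights (.npz) plus a JSON manifest sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_arrays())
    if manifest is not None:
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_state(model: Module, path: str | Path) -> dict:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    with np.load(path) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    mpath = path.with_suffix(".json")
    return json.loads(mpath.read_text()) if mpath.exists() else {}
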