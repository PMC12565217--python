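"""The compact CNN that predicts all filter parameters from a downscaled
copy of the slice: p_1..n = h(I_small).

The network never touches the image itself; it only emits a handful of
scalars (one brightness offset, one contrast factor, three sharpening
intensities, ...). This is what makes the preprocessing incapable of
hallucinating structure: the pixel pathway is the fixed filter algebra,
the learned pathway is a low-dimensional parameter regression.

Architecture: three conv blocks (3x3 kernel, stride 2, padding 1, each
followed by batch normalization and ReLU) taking 3x128x128 input down to
128x16x16, then two fully connected layers and per-group range activations
(sigmoid for [0,1], tanh for [-1,1], identity for unconstrained).

Two head variants are provided. ``lite`` (default) replaces the flatten
with global average pooling (128 features -> 512 -> heads), keeping the
whole generator under 100k parameters. ``flatten`` flattens the
full 128*16*16 = 32768 features into the first FC layer, which is the
textually described wiring but two orders of magnitude heavier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, concat, no_grad
from .filter_bank import get_filter
from .io_windowing import WindowedImage

__all__ = ["HeadSpec", "GeneratorConfig", "FilterParams",
           "ParameterGenerator", "build_generator", "predict_params",
           "default_head_spec"]

_ACTIVATIONS = {"unit": "sigmoid", "signed": "tanh", "free": "linear"}


@dataclass(frozen=True)
class HeadSpec:
    filter_name: str
    param_count: int
    range_tag: str

    def __post_init__(self):
        if self.range_tag not in _ACTIVATIONS:
            raise ValueError(f"unknown range tag {self.range_tag!r}")


def default_head_spec(filter_names) -> list[HeadSpec]:
    """One head group per image-predicted parameter block of the named
    filters. The pretrained kernel-combination block is excluded: its
    softmax logits are shared trainable weights of the pipeline, not
    per-image predictions."""
    from .filter_bank import CB_NAME

    heads = []
    for name in filter_names:
        info = get_filter(name)
        if info.name == CB_NAME:
            continue
        if info.n_params > 0 and info.trainable:
            heads.append(HeadSpec(info.name, info.n_params, info.range_tag))
    return heads


@dataclass
class GeneratorConfig:
    conv_widths: tuple[int, int, int] = (32, 64, 128)
    fc_hidden: int = 512
    head_spec: list[HeadSpec] = field(default_factory=list)
    variant: str = "lite"   # or "flatten"
    input_size: int = 128

    def __post_init__(self):
        if len(self.conv_widths) != 3:
            raise ValueError("exactly three conv blocks are required")
        if self.variant not in ("lite", "flatten"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not self.head_spec:
            raise ValueError("head_spec must not be empty")
        self.head_spec = [h if isinstance(h, HeadSpec) else HeadSpec(*h)
                          for h in self.head_spec]

    @property
    def n_outputs(self) -> int:
        return sum(h.param_count for h in self.head_spec)

    def to_dict(self) -> dict:
        return {
            "conv_widths": list(self.conv_widths),
            "fc_hidden": self.fc_hidden,
            "head_spec": [[h.filter_name, h.param_count, h.range_tag]
                          for h in self.head_spec],
            "variant": self.variant,
            "input_size": self.input_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(conv_widths=tuple(d["conv_widths"]),
                   fc_hidden=d["fc_hidden"],
                   head_spec=[HeadSpec(*h) for h in d["head_spec"]],
                   variant=d["variant"],
                   input_size=d.get("input_size", 128))


class FilterParams(dict):
    """Mapping filter name -> 1-D parameter Tensor (already activated)."""

    def numpy(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v.data if isinstance(v, Tensor) else v)
                for k, v in self.items()}


class ParameterGenerator(nn.Module):
    def __init__(self, cfg: GeneratorConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = cfg.conv_widths
        self.cfg = cfg
        self.seed = seed
        lite = cfg.variant == "lite"
        self.block1 = self._block(3, w1, rng)
        # lite trades the two wide conv blocks for depthwise-separable ones
        # (depthwise 3x3 then strided 1x1 pointwise) to stay lightweight
        self.block2 = self._block(w1, w2, rng, separable=lite)
        self.block3 = self._block(w2, w3, rng, separable=lite)
        feat = cfg.input_size // 8
        if cfg.variant == "flatten":
            fc_in = w3 * feat * feat
        else:
            fc_in = w3
        self.fc1 = nn.Linear(fc_in, cfg.fc_hidden, rng)
        self.fc2 = nn.Linear(cfg.fc_hidden, cfg.n_outputs, rng)
        # identity start: zeroing the head puts signed parameters at 0 and
        # unit-range ones at mid-scale, so the pipeline begins near the
        # identity map and training refines from there instead of having to
        # recover from a saturated random state with clipped outputs
        self.fc2.weight.data[:] = 0.0
        self.fc2.bias.data[:] = 0.0
        self.training = True

    @staticmethod
    def _block(cin: int, cout: int, rng, separable: bool = False) -> nn.Sequential:
        if separable:
            return nn.Sequential(
                nn.DepthwiseConv2d(cin, 3, rng=rng),
                nn.Conv2d(cin, cout, 1, stride=2, rng=rng),
                nn.BatchNorm2d(cout),
                nn.relu_layer(),
            )
        return nn.Sequential(
            nn.Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng),
            nn.BatchNorm2d(cout),
            nn.relu_layer(),
        )

    def features(self, x: Tensor) -> Tensor:
        return self.block3(self.block2(self.block1(x)))

    def forward(self, x: Tensor) -> Tensor:
        """Raw head outputs (pre-activation), shape (N, n_outputs)."""
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.cfg.input_size \
                or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected (N, 3, {self.cfg.input_size}, {self.cfg.input_size}) "
                f"input, got {x.shape}")
        f = self.features(x)
        if self.cfg.variant == "flatten":
            f = f.reshape(f.shape[0], -1)
        else:
            f = f.global_avg_pool2d()
        return self.fc2(self.fc1(f).relu())

    def predict(self, x: Tensor,
                reference_calibrated: bool = False) -> list[FilterParams]:
        """Activated per-filter parameters for each image in the batch.

        With ``reference_calibrated`` the head's pre-activations are taken
        relative to those of a featureless mid-gray reference image passed
        through the same forward (appended to the batch). A structureless
        input is then guaranteed to produce exactly neutral signed
        parameters - the safety property the uniform-phantom protocol
        verifies - while structured inputs keep the full output range.
        """
        if reference_calibrated:
            ref = Tensor(np.full((1,) + tuple(x.shape[1:]), 0.5))
            raw_all = self.forward(concat([x, ref], axis=0))
            raw = raw_all[: x.shape[0]] - raw_all[x.shape[0]:]
        else:
            raw = self.forward(x)
        groups: list[Tensor] = []
        offset = 0
        for head in self.cfg.head_spec:
            g = raw[:, offset:offset + head.param_count]
            if head.range_tag == "unit":
                g = g.sigmoid()
            elif head.range_tag == "signed":
                g = g.tanh()
            groups.append(g)
            offset += head.param_count
        out = []
        for i in range(x.shape[0]):
            fp = FilterParams()
            for head, g in zip(self.cfg.head_spec, groups):
                fp[head.filter_name] = g[i]
            out.append(fp)
        return out


def build_generator(cfg: GeneratorConfig, seed: int = 0) -> ParameterGenerator:
    return ParameterGenerator(cfg, seed=seed)


def predict_params(gen: ParameterGenerator, img128: WindowedImage | np.ndarray) -> FilterParams:
    """Inference-mode parameter prediction for a single 3x128x128 image."""
    arr = img128.values if isinstance(img128, WindowedImage) else np.asarray(img128)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"expected a 3-channel image, got shape {arr.shape}")
    gen.eval()
    with no_grad():
        params = gen.predict(Tensor(arr[None]))
    return FilterParams({k: Tensor(v.data) for k, v in params[0].items()})
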