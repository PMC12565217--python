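"""Pretraining of the skip-convolution U-Net and extraction of its skip
kernels into the frozen multi-scale bank.

The U-Net's skip paths each contain one convolution of fixed spatial size
(default 5x5 on the shallowest selected level, 7x7 on the next, 11x11 on
the deepest). After training the autoencoder-style network - either on
core/penumbra segmentation with Dice loss, or on degraded-to-clean
reconstruction with L1 - each skip convolution's weight tensor is reduced
to a single spatial kernel (channel mean by default) and normalized to
unit sum, so that the resulting combination block preserves constant
images. Only the three softmax combination weights remain trainable in the
downstream preprocessing pipeline; the kernels themselves are frozen.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor
from .filter_bank import KernelBank
from .losses_metrics import dice_loss_t
from .unet import UNet

__all__ = ["SkipUNetConfig", "build_skip_unet", "pretrain", "extract_kernels"]


@dataclass
class SkipUNetConfig:
    depth: int = 5
    skip_kernel_sizes: tuple[int, ...] = (5, 7, 11)
    base_width: int = 8
    task: str = "segmentation"          # or "reconstruction"
    input_size: int = 64

    def __post_init__(self):
        if self.depth < 3:
            raise ValueError("depth must be at least 3")
        for ks in self.skip_kernel_sizes:
            if ks % 2 == 0:
                raise ValueError(f"skip kernel sizes must be odd, got {ks}")
        if self.task not in ("segmentation", "reconstruction"):
            raise ValueError(f"unknown task {self.task!r}")


def build_skip_unet(cfg: SkipUNetConfig, seed: int = 0) -> UNet:
    out_ch = 3  # core / penumbra / background, or RGB reconstruction
    return UNet(in_ch=3, out_ch=out_ch, depth=cfg.depth,
                base_width=cfg.base_width,
                skip_kernel_sizes=cfg.skip_kernel_sizes, seed=seed)


def _model_hash(model: nn.Module) -> str:
    h = hashlib.sha256()
    for name, arr in sorted(model.state_arrays().items()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def pretrain(model: UNet, samples, epochs: int = 50, seed: int = 0, *,
             task: str = "segmentation", lr: float = 3e-3,
             batch_size: int = 4) -> dict:
    """Train the skip U-Net on phantom samples; returns the loss history.

    ``samples`` is a sequence of ``PhantomSample``. For the segmentation
    task the inputs are the clean slices and the targets the one-hot
    core/penumbra/background masks (Dice loss over the lesion classes);
    for reconstruction the inputs are the degraded twins and the targets
    the clean slices (L1).
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=0.05, betas=(0.9, 0.99))
    history = []
    model.train()
    total_steps = epochs * max(1, len(samples) // batch_size)
    step = 0
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(samples), batch_size):
            idx = order[start:start + batch_size]
            xs = np.stack([_input_of(samples[i], task) for i in idx])
            opt.lr = nn.cosine_lr(lr, step, total_steps)
            pred = model(Tensor(xs))
            if task == "segmentation":
                probs = pred.softmax(axis=1)
                target = np.stack([_onehot_masks(samples[i]) for i in idx])
                loss = dice_loss_t(probs, Tensor(target))
            else:
                target = np.stack([_input_of(samples[i], "segmentation")
                                   for i in idx])
                loss = (pred.sigmoid() - Tensor(target)).abs().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        history.append(float(np.mean(losses)))
    return {"epoch_loss": history, "task": task, "epochs": epochs, "seed": seed}


def _input_of(sample, task: str) -> np.ndarray:
    img = sample.degraded if task == "reconstruction" and sample.degraded is not None \
        else sample.clean
    arr = img.values
    if arr.ndim == 2:
        arr = np.broadcast_to(arr, (3,) + arr.shape)
    return arr


def _onehot_masks(sample) -> np.ndarray:
    core = sample.masks.core[0].astype(np.float64)
    pen = sample.masks.penumbra[0].astype(np.float64)
    bg = 1.0 - core - pen
    return np.stack([core, pen, bg])


def extract_kernels(model: UNet, sizes: tuple[int, ...] = (5, 7, 11),
                    reduction: str = "channel-mean") -> KernelBank:
    """Harvest one spatial kernel per requested size from the skip convs.

    Read-only: the source model is left untouched. The reduced kernel is
    normalized to unit sum (recorded in the manifest) so the combination
    block maps constant images to themselves.
    """
    before = _model_hash(model)
    available = {}
    for sc in model.skip_convs:
        if sc is not None:
            available[sc.weight.shape[-1]] = sc.weight.data
    kernels = []
    for size in sizes:
        if size not in available:
            raise ValueError(f"no skip convolution of size {size} in the model; "
                             f"available: {sorted(available)}")
        w = available[size]                      # (O, I, k, k)
        if reduction == "channel-mean":
            kern = w.mean(axis=(0, 1))
        elif reduction == "first-channel":
            kern = w[0, 0].copy()
        elif reduction == "frobenius-top-1":
            flat = w.reshape(-1, size * size)
            norms = np.linalg.norm(flat, axis=1)
            kern = flat[int(np.argmax(norms))].reshape(size, size).copy()
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
        # bound the kernel's energy (L1) and then enforce unit DC gain by a
        # center correction; dividing by the raw sum is ill-conditioned (a
        # reduced random-ish kernel can sum to nearly zero, exploding the
        # entries and forcing the rest of the pipeline to fight the block)
        kern = kern.copy()
        l1 = np.abs(kern).sum()
        if l1 < 1e-12:
            kern = np.zeros_like(kern)
        else:
            kern /= l1
        kern[size // 2, size // 2] += 1.0 - kern.sum()
        kernels.append(kern)
    assert _model_hash(model) == before, "extraction must not mutate the model"
    return KernelBank(list(kernels), np.zeros(len(kernels)),
                      manifest={"reduction": reduction,
                                "normalization": "l1-bounded, unit-sum via center correction",
                                "sizes": [int(s) for s in sizes],
                                "source": "skip-convolutions"})
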