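"""Shared fixtures.

The expensive artifacts (a pretrained kernel bank and the scaled trained
preprocessor checkpoint) are session-scoped so the restoration-gain and
artifact-safety checks reuse one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctprep.enhancement_pipeline import EnhancementPipeline, PipelineConfig
from ctprep.kernel_pretraining import (SkipUNetConfig, build_skip_unet,
                                       extract_kernels)
from ctprep.synthetic_data import build_paired_dataset, generate_phantom
from ctprep.training_validation import TrainConfig, pretrain_preprocessor

TRAIN_SEED = 1234
N_PAIRS = 200
N_VAL = 40


@pytest.fixture(scope="session")
def kernel_bank():
    """Bank extracted from a briefly pretrained skip-convolution U-Net
    (segmentation task on 64x64 phantoms; the desk-scale stand-in for the
    full 50-epoch pretraining)."""
    from ctprep.kernel_pretraining import pretrain
    from ctprep.synthetic_data import _shrink_sample

    model = build_skip_unet(SkipUNetConfig(depth=5, base_width=4), seed=1)
    phantoms = [_shrink_sample(generate_phantom(s, size=128), 64)
                for s in range(24)]
    pretrain(model, phantoms, epochs=2, seed=0)
    return extract_kernels(model)


@pytest.fixture(scope="session")
def paired_dataset():
    """The scaled study dataset: 200 paired phantoms generated and degraded
    at 512x512, held at the 128x128 training resolution."""
    return build_paired_dataset(N_PAIRS, seed=TRAIN_SEED, size=512,
                                store_size=128)


@pytest.fixture(scope="session")
def trained_pipeline(kernel_bank, paired_dataset):
    """Preprocessor trained on the scaled profile (5 epochs, 128x128)."""
    cfg = TrainConfig.scaled(seed=TRAIN_SEED)
    pipe = EnhancementPipeline(PipelineConfig(kernel_bank=kernel_bank),
                               seed=TRAIN_SEED)
    train = paired_dataset[N_VAL:]
    history = pretrain_preprocessor(pipe, cfg, train)
    pipe.history = history
    return pipe


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
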