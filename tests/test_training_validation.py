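"""Schedules, reproducibility, freeze contracts, the artifact-safety
protocol and the ablation harness (all at toy scale)."""

import numpy as np
import pytest

from ctprep import nn
from ctprep.enhancement_pipeline import (DEFAULT_FILTERS, EnhancementPipeline,
                                         PipelineConfig)
from ctprep.filter_bank import KernelBank
from ctprep.synthetic_data import DegradationSpec, build_paired_dataset
from ctprep.training_validation import (TrainConfig, artifact_safety_report,
                                        evaluate_segmenter, run_ablation,
                                        train_segmenter,
                                        pretrain_preprocessor)
from ctprep.unet import UNet


def tiny_bank():
    delta = np.zeros((5, 5))
    delta[2, 2] = 1.0
    return KernelBank([delta])


def tiny_dataset(n=6, seed=3):
    spec = DegradationSpec(crop_range=(400, 512))
    return build_paired_dataset(n, seed=seed, size=512, store_size=64,
                                spec=spec)


def tiny_cfg(seed=0, **kw):
    cfg = TrainConfig.scaled(seed=seed)
    cfg.batch_size = 3
    cfg.train_size = 64
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestSchedule:
    def test_cosine_endpoints_and_midpoint(self):
        assert nn.cosine_lr(1e-3, 0, 100) == pytest.approx(1e-3)
        assert nn.cosine_lr(1e-3, 100, 100) == pytest.approx(0.0, abs=1e-18)
        assert nn.cosine_lr(1e-3, 50, 100) == pytest.approx(5e-4)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs_pretrain=0)
        cfg = TrainConfig()
        assert cfg.betas == (0.9, 0.99)
        assert cfg.weight_decay == 0.05
        assert cfg.lr_init == 1e-4 and cfg.lr_joint_init == 1e-6
        assert cfg.epochs_pretrain == 10 and cfg.epochs_joint == 40
        assert cfg.batch_size == 32


class TestPretrainPreprocessor:
    def test_zero_learning_rate_changes_nothing(self):
        pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                   seed=0)
        before = [p.data.copy() for p in pipe.trainable_parameters()]
        cfg = tiny_cfg(lr_init=0.0, weight_decay=0.0)
        hist = pretrain_preprocessor(pipe, cfg, tiny_dataset(), epochs=1)
        assert len(hist["train_loss"]) == 1
        for p, b in zip(pipe.trainable_parameters(), before):
            assert np.array_equal(p.data, b)

    def test_reproducible_from_seed(self):
        finals = []
        for _ in range(2):
            pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                       seed=7)
            hist = pretrain_preprocessor(pipe, tiny_cfg(seed=7),
                                         tiny_dataset(), epochs=1)
            finals.append(hist["train_loss"][-1])
        assert finals[0] == finals[1]

    def test_empty_dataset_rejected(self):
        pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                   seed=0)
        with pytest.raises(ValueError):
            pretrain_preprocessor(pipe, tiny_cfg(), [])


class TestFreezeContracts:
    def test_frozen_segmenter_only_generator_changes(self):
        data = tiny_dataset()
        pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                   seed=0)
        seg = UNet(depth=2, base_width=4, seed=0)
        seg_before = {k: v.copy() for k, v in seg.state_arrays().items()
                      if not k.endswith(("running_mean", "running_var"))}
        gen_before = [p.data.copy() for p in pipe.trainable_parameters()]
        train_segmenter(seg, data, tiny_cfg(), 64, pipeline=pipe,
                        train_generator=True, train_segmenter_weights=False,
                        epochs=1, lr=1e-2)
        after = seg.state_arrays()
        for k, v in seg_before.items():
            assert np.array_equal(after[k], v), k
        changed = any(not np.array_equal(p.data, b)
                      for p, b in zip(pipe.trainable_parameters(), gen_before))
        assert changed

    def test_all_frozen_rejected(self):
        seg = UNet(depth=2, base_width=4, seed=0)
        with pytest.raises(ValueError):
            train_segmenter(seg, tiny_dataset(), tiny_cfg(), 64,
                            train_segmenter_weights=False, epochs=1)


class TestArtifactSafety:
    def test_identity_pipeline_perfect_scores(self):
        cfg = PipelineConfig(kernel_bank=tiny_bank(),
                             gains={n: 0.0 for n in DEFAULT_FILTERS})
        pipe = EnhancementPipeline(cfg, seed=0)
        rep = artifact_safety_report(pipe, n_phantoms=5, phantom_size=128)
        assert rep.phantom_ssim == pytest.approx(1.0)
        assert rep.max_abs_diff == 0.0
        assert rep.max_output_std <= 1e-12   # np.std rounding on constants
        assert not rep.flags["structure_on_uniform_input"]

    def test_untrained_pipeline_flag_clear_on_constants(self):
        """Constant preservation of the filter algebra keeps the flag clear
        for any generator weights, trained or not."""
        pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                   seed=5)
        rep = artifact_safety_report(pipe, n_phantoms=5, phantom_size=128)
        assert rep.max_output_std <= 1e-6
        assert not rep.flags["structure_on_uniform_input"]

    def test_difference_maps_written(self, tmp_path):
        pipe = EnhancementPipeline(PipelineConfig(kernel_bank=tiny_bank()),
                                   seed=0)
        artifact_safety_report(pipe, n_phantoms=3, phantom_size=128,
                               diff_dir=tmp_path)
        assert len(list(tmp_path.glob("phantom_*.png"))) == 3


class TestAblation:
    def test_identical_configs_identical_rows(self, tmp_path):
        data = tiny_dataset(8)
        factory = lambda seed: None
        rows = run_ablation({"a": None, "b": None}, data[:6], data[6:],
                            seeds=[1], out_csv=tmp_path / "t.csv",
                            size=64, epochs=1)
        a = {k: v for k, v in rows[0].items() if k != "config"}
        b = {k: v for k, v in rows[1].items() if k != "config"}
        assert a == b

    def test_single_config_warns_and_schema(self, tmp_path):
        data = tiny_dataset(8)
        with pytest.warns(UserWarning):
            rows = run_ablation({"solo": None}, data[:6], data[6:],
                                seeds=[1, 2], out_csv=tmp_path / "t.csv",
                                size=64, epochs=1)
        row = rows[0]
        for cls in ("core", "penumbra"):
            for metric in ("dice2d", "iou2d", "dice3d", "iou3d"):
                assert f"{metric}_{cls}" in row
                assert f"{metric}_{cls}_ci95" in row
        header = (tmp_path / "t.csv").read_text().splitlines()[0]
        assert header.split(",")[0] == "config"


def test_evaluate_segmenter_keys():
    data = tiny_dataset(4)
    seg = UNet(depth=2, base_width=4, seed=0)
    out = evaluate_segmenter(seg, data, 64)
    assert set(out) >= {"dice2d_core", "dice3d_penumbra", "iou3d_core",
                        "dice3d_mean"}
    assert 0 <= out["dice3d_mean"] <= 1
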