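"""Training loop: determinism, initial-loss sanity, overfit, checkpoints."""

import logging

import numpy as np
import pytest
from click.testing import CliRunner

from ndnseg import nn
from ndnseg.cli import main as cli_main
from ndnseg.netspec import NetworkSpec, softmax
from ndnseg.objectives import dice_score
from ndnseg.runner import (
    TrainConfig,
    _Case,
    desk_profile,
    load_checkpoint,
    make_predictor,
    restore_net,
    save_checkpoint,
    train_stage,
)
from ndnseg.synthdata import PhantomConfig, generate_phantom
from ndnseg.preprocess import zscore_normalize

logging.disable(logging.WARNING)


def _tiny_cases(n=3, seed=0):
    cases = []
    rng = np.random.default_rng(seed)
    config = PhantomConfig(
        shape=(32, 32, 16),
        whole_semi_axes=(8, 8, 5),
        core_semi_axes=(5, 5, 3),
        enhancing_semi_axes=(2.5, 2.5, 1.5),
        brain_semi_axes=(14, 14, 7),
        center_jitter=(2, 2, 1),
    )
    for i in range(n):
        volume, labels = generate_phantom(config, rng=rng)
        cases.append(_Case(f"case_{i}", zscore_normalize(volume), labels))
    return cases


def _tiny_config(**overrides):
    base = dict(
        lr=1e-3,
        epochs=1,
        steps_per_epoch=5,
        batch_size=1,
        patch_size=(16, 16, 8),
        loss="dice",
        stage=1,
        seed=3,
        augment=None,
    )
    base.update(overrides)
    return TrainConfig(**base)


def _tiny_spec(filters=2):
    return NetworkSpec(in_channels=4, classes=2, base_filters=filters)


def test_same_seed_gives_identical_loss_traces():
    cases = _tiny_cases()
    a = train_stage(cases, _tiny_spec(), _tiny_config())
    b = train_stage(cases, _tiny_spec(), _tiny_config())
    assert a.loss_trace == b.loss_trace
    assert a.val_dice_trace == b.val_dice_trace


def test_initial_cross_entropy_near_ln_two():
    # a randomly initialized 2-class softmax is uninformative: the first
    # cross-entropy value sits near -ln(1/2) regardless of the patch
    cases = _tiny_cases()
    res = train_stage(cases, _tiny_spec(), _tiny_config(loss="ce"))
    assert res.loss_trace[0] == pytest.approx(np.log(2), rel=0.2)


def test_overfit_single_phantom_patch():
    # 300 steps on one fixed patch (the source volume equals the patch
    # size, so every draw is the same patch) memorizes it
    case = _tiny_cases(n=1)[0]
    from ndnseg.volio import LabelVolume, MultiModalVolume

    crop = _Case(
        case.case_id,
        MultiModalVolume(case.volume.intensities[8:24, 8:24, 4:12, :]),
        LabelVolume(case.labels.labels[8:24, 8:24, 4:12]),
    )
    config = _tiny_config(epochs=6, steps_per_epoch=50, batch_size=1, val_fraction=0.0)
    res = train_stage([crop], _tiny_spec(filters=4), config)
    net = restore_net(_tiny_spec(filters=4), res.state)
    prob = softmax(net(crop.volume.intensities))[..., 1]
    target = crop.labels.labels > 0
    assert dice_score(prob >= 0.5, target) >= 0.95


def test_non_finite_loss_aborts(monkeypatch):
    # the guard itself: a NaN loss value must abort with a diagnostic
    import ndnseg.runner as runner_mod

    def nan_loss(logits, p, **kwargs):
        return float("nan"), np.zeros_like(logits)

    monkeypatch.setattr(runner_mod, "loss_and_logit_grad", nan_loss)
    with pytest.raises(FloatingPointError, match="diverged"):
        train_stage(_tiny_cases(n=1), _tiny_spec(), _tiny_config())


def test_checkpoint_round_trip(tmp_path):
    cases = _tiny_cases()
    config = _tiny_config(checkpoint_path=tmp_path / "ckpt.npz")
    res = train_stage(cases, _tiny_spec(), config)
    net = restore_net(_tiny_spec(), res.state)
    x = cases[0].volume.intensities[:16, :16, :8, :]
    before = net(x)

    spec, state, meta = load_checkpoint(tmp_path / "ckpt.npz")
    assert meta["stage"] == 1
    net2 = restore_net(spec, state)
    np.testing.assert_array_equal(before, net2(x))


def test_predictor_pads_odd_crops():
    from ndnseg.netspec import NDN

    net = NDN(_tiny_spec(), rng=np.random.default_rng(0))
    predict = make_predictor(net)
    crop = np.random.default_rng(0).normal(size=(13, 21, 9, 4))
    prob = predict(crop)
    assert prob.shape == (13, 21, 9)
    assert np.all((prob >= 0) & (prob <= 1))


def test_yaml_run_config_round_trip(tmp_path):
    from ndnseg.runner import load_run_config

    (tmp_path / "run.yaml").write_text(
        """
network:
  classes: 2
  base_filters: 8
  rates: [1, 2, 5]
  kernel: 3
train:
  lr: 0.001
  epochs: 2
  steps_per_epoch: 10
  patch_size: [32, 32, 16]
  loss: focal
augment:
  enable_elastic: false
postprocess:
  min_enhancing_volume: 20
"""
    )
    spec, config, post = load_run_config(tmp_path / "run.yaml")
    assert spec.base_filters == 8 and spec.classes == 2
    assert spec.scheme.rates == (1, 2, 5)
    assert config.loss == "focal" and config.patch_size == (32, 32, 16)
    assert config.augment is not None and not config.augment.enable_elastic
    assert post.min_enhancing_volume == 20


class TestCli:
    def test_validate_hdc_valid_scheme(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["validate-hdc", "--rates", "1,2,5", "--kernel", "3"])
        assert result.exit_code == 0
        assert "valid:         True" in result.output

    def test_validate_hdc_invalid_scheme_nonzero_exit(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["validate-hdc", "--rates", "2,4,6"])
        assert result.exit_code == 1
        assert "coprime_ok:    False" in result.output

    def test_validate_hdc_bad_input(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["validate-hdc", "--rates", "0,2"])
        assert result.exit_code != 0

    def test_synth_is_deterministic(self, tmp_path):
        runner = CliRunner()
        for sub in ("a", "b"):
            result = runner.invoke(
                cli_main,
                ["synth", "--n", "2", "--out", str(tmp_path / sub), "--seed", "7"],
            )
            assert result.exit_code == 0, result.output
        from ndnseg.volio import read_case, read_manifest

        for ra, rb in zip(
            read_manifest(tmp_path / "a" / "manifest.json"),
            read_manifest(tmp_path / "b" / "manifest.json"),
        ):
            va, la = read_case(ra)
            vb, lb = read_case(rb)
            np.testing.assert_array_equal(va.intensities, vb.intensities)
            np.testing.assert_array_equal(la.labels, lb.labels)

    def test_unknown_subcommand_fails(self):
        runner = CliRunner()
        assert runner.invoke(cli_main, ["frobnicate"]).exit_code != 0

    def test_train_predict_evaluate_round_trip(self, tmp_path):
        # a deliberately tiny run: the point is the wiring, not the Dice
        runner = CliRunner()
        data = tmp_path / "data"
        result = runner.invoke(
            cli_main, ["synth", "--n", "2", "--out", str(data), "--seed", "3"]
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            cli_main,
            [
                "train", "--manifest", str(data / "manifest.json"),
                "--checkpoint", str(tmp_path / "ckpt"),
                "--seed", "3", "--epochs", "1", "--steps-per-epoch", "2",
            ],
        )
        assert result.exit_code == 0, result.output
        result = runner.invoke(
            cli_main,
            [
                "predict", "--manifest", str(data / "manifest.json"),
                "--checkpoint", str(tmp_path / "ckpt"),
                "--out", str(tmp_path / "preds"),
                "--min-enhancing-volume", "20",
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "preds" / "stage_rois.jsonl").exists()
        result = runner.invoke(
            cli_main,
            [
                "evaluate", "--manifest", str(data / "manifest.json"),
                "--pred-dir", str(tmp_path / "preds"),
                "--csv", str(tmp_path / "dice.csv"),
            ],
        )
        assert result.exit_code == 0, result.output
        lines = (tmp_path / "dice.csv").read_text().strip().splitlines()
        assert len(lines) == 3  # header + two cases
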