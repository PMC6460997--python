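"""Training, prediction and evaluation for the cascade stages.

Each cascade stage is a binary segmentation network trained with Adam
(first-moment decay 0.9, L2 weight decay 1e-5) on tumor-centered patches
cropped from ground-truth stage regions and optionally augmented.  The
paper-scale profile uses base filters 16, 96x96x48 patches, batch 4,
learning rate 1e-4 and 300 epochs; the desk-scale profile (base filters
4, 32x32x16 patches, a few hundred steps, learning rate 1e-3) trains the
same architecture on synthetic phantoms in minutes on one CPU.  Cases are
split 80/20 into train/validation by case id and the checkpoint with the
best validation Dice is kept.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentConfig, augment_pipeline
from .cascade import (
    DEFAULT_MARGINS,
    CascadeStage,
    make_stage_training_example,
    run_cascade,
)
from .netspec import NDN, NetworkSpec, softmax
from .objectives import dice_score, evaluate_case, loss_and_logit_grad, one_hot
from .postprocess import PostprocessConfig, postprocess_pipeline
from .preprocess import zscore_normalize
from .volio import CaseRecord, LabelVolume, MultiModalVolume, read_case

LOSSES = ("ce", "wce", "focal", "dice")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    weight_decay: float = 1e-5
    epochs: int = 300
    steps_per_epoch: int = 50
    batch_size: int = 4
    patch_size: tuple[int, int, int] = (96, 96, 48)
    loss: str = "dice"
    focal_gamma: float = 2.0
    dice_include_background: bool = False
    class_weights: tuple[float, ...] | None = None
    stage: int = 1
    seed: int = 0
    val_fraction: float = 0.2
    #: fraction of patches centered on stage-target voxels; the rest are
    #: placed uniformly in the stage crop so empty context is in-distribution
    fg_patch_fraction: float = 0.67
    checkpoint_path: Path | None = None
    augment: AugmentConfig | None = None

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}, got {self.loss!r}")
        if min(self.lr, self.epochs, self.steps_per_epoch, self.batch_size) <= 0:
            raise ValueError("rates, sizes and counts must be positive")


def desk_profile(stage: int = 1, seed: int = 0, epochs: int = 6, steps_per_epoch: int = 40) -> tuple[NetworkSpec, TrainConfig]:
    """Small-network profile for CPU-scale runs on 64x64x32 phantoms.

    Flips-only augmentation and a 1e-3 learning rate suit the few hundred
    optimization steps the profile allows; the paper-scale profile
    (:class:`TrainConfig` defaults) keeps the published settings.
    """
    spec = NetworkSpec(in_channels=4, classes=2, base_filters=4)
    config = TrainConfig(
        lr=1e-3,
        epochs=epochs,
        steps_per_epoch=steps_per_epoch,
        batch_size=2,
        patch_size=(32, 32, 16),
        loss="dice",
        stage=stage,
        seed=seed,
        augment=AugmentConfig(
            enable_flip=True, enable_rotate=False, enable_gamma=False, enable_elastic=False
        ),
    )
    return spec, config


@dataclass
class TrainResult:
    state: dict
    spec: NetworkSpec
    loss_trace: list[float]
    val_dice_trace: list[float]
    best_val_dice: float
    stage: int
    patch_size: tuple[int, int, int] = (96, 96, 48)


@dataclass
class _Case:
    case_id: str
    volume: MultiModalVolume
    labels: LabelVolume


def _load_cases(records: list[CaseRecord]) -> list[_Case]:
    cases = []
    for rec in records:
        volume, labels = read_case(rec)
        if labels is None:
            raise ValueError(f"case {rec.case_id} has no labels; cannot train on it")
        cases.append(_Case(rec.case_id, zscore_normalize(volume), labels))
    return cases


def _split(cases: list[_Case], val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(len(cases))
    n_val = max(1, int(round(val_fraction * len(cases)))) if len(cases) > 1 else 0
    val = [cases[i] for i in idx[:n_val]]
    train = [cases[i] for i in idx[n_val:]]
    return train, val


def _patch_val_dice(net: NDN, case: _Case, stage: int, patch_size, rng) -> float | None:
    example = make_stage_training_example(
        case.volume, case.labels, stage, patch_size, rng=rng
    )
    if example is None:
        return None
    patch, target = example
    prob = softmax(net(patch.intensities))[..., 1]
    return dice_score(prob >= 0.5, target)


def train_stage(
    records: list[CaseRecord] | list[_Case],
    spec: NetworkSpec,
    config: TrainConfig,
) -> TrainResult:
    """Train one cascade stage; returns the best-validation checkpoint state.

    Training patches are drawn from ground-truth stage regions of randomly
    chosen training cases, optionally augmented; the selected loss is
    optimized with Adam.  A non-finite loss aborts with a diagnostic.
    """
    if spec.classes != 2:
        raise ValueError("stage networks are binary: spec.classes must be 2")
    rng = np.random.default_rng(config.seed)
    cases = records if records and isinstance(records[0], _Case) else _load_cases(records)
    if not cases:
        raise ValueError("empty training manifest")
    train_cases, val_cases = _split(cases, config.val_fraction, rng)
    if not train_cases:
        train_cases = cases

    net = NDN(spec, rng=np.random.default_rng(rng.integers(2**31)))
    optimizer = nn.Adam(
        net.parameters(),
        lr=config.lr,
        beta1=config.beta1,
        weight_decay=config.weight_decay,
    )

    loss_trace: list[float] = []
    val_trace: list[float] = []
    best_val = -1.0
    best_state = nn.get_state(net)

    for _epoch in range(config.epochs):
        for _step in range(config.steps_per_epoch):
            xs, ys = [], []
            while len(xs) < config.batch_size:
                case = train_cases[rng.integers(len(train_cases))]
                center = "tumor" if rng.random() < config.fg_patch_fraction else "uniform"
                example = make_stage_training_example(
                    case.volume, case.labels, config.stage, config.patch_size,
                    rng=rng, center=center,
                )
                if example is None:
                    continue
                patch, target = example
                if config.augment is not None:
                    patch = augment_pipeline(patch, config.augment, rng)
                    target = np.isin(
                        patch.labels, list(CascadeStage(config.stage).targets)
                    )
                xs.append(patch.intensities)
                ys.append(target)
            x = np.stack(xs).astype(nn.DTYPE)
            p = one_hot(np.stack(ys).astype(np.int64), 2)

            logits = net.forward(x, train=True)
            loss, grad = loss_and_logit_grad(
                logits,
                p,
                kind=config.loss,
                gamma=config.focal_gamma,
                weights=config.class_weights,
                dice_include_background=config.dice_include_background,
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"loss diverged (value {loss}) at step {len(loss_trace)}"
                )
            loss_trace.append(float(loss))
            nn.zero_gradients(net)
            net.backward(grad)
            optimizer.step()

        # end of epoch: validation Dice on one patch per validation case
        scores = []
        val_rng = np.random.default_rng(config.seed + 7919)
        for case in val_cases or train_cases:
            s = _patch_val_dice(net, case, config.stage, config.patch_size, val_rng)
            if s is not None:
                scores.append(s)
        val_dice = float(np.mean(scores)) if scores else 0.0
        val_trace.append(val_dice)
        if val_dice >= best_val:
            best_val = val_dice
            best_state = nn.get_state(net)

    result = TrainResult(
        state=best_state,
        spec=spec,
        loss_trace=loss_trace,
        val_dice_trace=val_trace,
        best_val_dice=best_val,
        stage=config.stage,
        patch_size=tuple(config.patch_size),
    )
    if config.checkpoint_path is not None:
        save_checkpoint(config.checkpoint_path, result)
    return result


def train_cascade(
    records: list[CaseRecord],
    spec: NetworkSpec,
    config: TrainConfig,
) -> list[TrainResult]:
    """Train stages 1, 2, 3 sequentially on ground-truth-derived crops."""
    cases = _load_cases(records)
    results = []
    for stage in (1, 2, 3):
        stage_config = replace(
            config,
            stage=stage,
            seed=config.seed + stage,
            checkpoint_path=(
                None
                if config.checkpoint_path is None
                else Path(str(config.checkpoint_path)).with_suffix(f".stage{stage}.npz")
            ),
        )
        results.append(train_stage(cases, spec, stage_config))
    return results


# ---------------------------------------------------------------------------
# prediction


def _pad_to_multiple(x: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    pads, sls = [], []
    for ax in range(3):
        extent = x.shape[ax]
        target = -(-extent // factor) * factor
        short = target - extent
        pads.append((short // 2, short - short // 2))
        sls.append(slice(short // 2, short // 2 + extent))
    return np.pad(x, pads + [(0, 0)]), tuple(sls)


def make_predictor(net: NDN, tile: tuple[int, int, int] | None = None):
    """Wrap a stage network as crop -> foreground-probability closure.

    With ``tile`` unset the whole crop is pushed through in one pass
    (zero-padded to the pooling-compatible multiple of 8).  With ``tile``
    set — normally the training patch size — the crop is scanned by
    overlapping windows (stride = half the tile) whose probabilities are
    blended with Gaussian importance weights centered in each window.
    Tiled inference keeps the test-time context statistics close to the
    training patches (the squeeze step of the channel attention pools over
    the whole input, so a crop much larger and emptier than any training
    patch shifts the channel weights), and the center weighting lets each
    voxel be decided mainly by the window that sees it with the most
    context rather than by windows that clip it at their border.
    """

    def predict_full(crop: np.ndarray) -> np.ndarray:
        padded, sls = _pad_to_multiple(np.asarray(crop, dtype=nn.DTYPE), 2**net.spec.depth)
        prob = softmax(net(padded))[..., 1]
        return prob[sls]

    if tile is None:
        return predict_full

    # Gaussian importance map: weight 1 at the tile center falling to ~0.05
    # at the faces, so border predictions defer to better-centered windows
    axes = [np.exp(-0.5 * ((np.arange(t) - (t - 1) / 2) / (t / 4)) ** 2) for t in tile]
    weight = axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]

    def predict_tiled(crop: np.ndarray) -> np.ndarray:
        crop = np.asarray(crop, dtype=nn.DTYPE)
        # pad any axis shorter than the tile
        pads = []
        for ax in range(3):
            short = max(0, tile[ax] - crop.shape[ax])
            pads.append((short // 2, short - short // 2))
        padded = np.pad(crop, pads + [(0, 0)])
        shape = padded.shape[:3]
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        starts = []
        for ax in range(3):
            stride = max(1, tile[ax] // 2)
            pos = list(range(0, shape[ax] - tile[ax] + 1, stride))
            if pos[-1] != shape[ax] - tile[ax]:
                pos.append(shape[ax] - tile[ax])
            starts.append(pos)
        for sx in starts[0]:
            for sy in starts[1]:
                for sz in starts[2]:
                    sl = (
                        slice(sx, sx + tile[0]),
                        slice(sy, sy + tile[1]),
                        slice(sz, sz + tile[2]),
                    )
                    prob = softmax(net(padded[sl]))[..., 1]
                    acc[sl] += prob * weight
                    cnt[sl] += weight
        prob = acc / cnt
        unpad = tuple(slice(p[0], p[0] + crop.shape[ax]) for ax, p in enumerate(pads))
        return prob[unpad]

    return predict_tiled


def predict_case(
    nets: list[NDN],
    volume: MultiModalVolume,
    margins: tuple[int, int, int] = DEFAULT_MARGINS,
    postprocess: PostprocessConfig | None = None,
    roi_log: list | None = None,
    tile: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Full cascade inference on one raw volume (z-scored internally)."""
    volume = zscore_normalize(volume)
    predictors = [make_predictor(net, tile=tile) for net in nets]
    _, fused = run_cascade(predictors, volume, margins=margins, roi_log=roi_log)
    if postprocess is not None:
        fused = postprocess_pipeline(fused, postprocess)
    return fused


def evaluate_manifest(
    pred_by_case: dict[str, LabelVolume],
    truth_by_case: dict[str, LabelVolume],
    csv_path: Path | None = None,
) -> dict[str, dict[int, float]]:
    """Per-case per-class Dice report, optionally written as CSV."""
    rows = {}
    for case_id, truth in truth_by_case.items():
        rows[case_id] = evaluate_case(pred_by_case[case_id], truth)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "dice_edema", "dice_non_enhancing", "dice_enhancing"])
            for case_id, scores in rows.items():
                writer.writerow([case_id, scores[1], scores[2], scores[3]])
    return rows


# ---------------------------------------------------------------------------
# run configuration


def load_run_config(path: Path) -> tuple[NetworkSpec, TrainConfig, PostprocessConfig]:
    """Build the run objects from a YAML file.

    The file may contain ``network``, ``train``, ``augment`` and
    ``postprocess`` mappings whose keys mirror the corresponding dataclass
    fields; omitted keys keep their defaults.  The augmentation section is
    attached to the returned :class:`TrainConfig`.
    """
    import yaml

    from .netspec import DilationScheme

    raw = yaml.safe_load(Path(path).read_text()) or {}
    net_kwargs = dict(raw.get("network", {}))
    if "rates" in net_kwargs or "kernel" in net_kwargs:
        net_kwargs["scheme"] = DilationScheme(
            rates=tuple(net_kwargs.pop("rates", (1, 2, 5))),
            kernel=int(net_kwargs.pop("kernel", 3)),
        )
    spec = NetworkSpec(**net_kwargs)

    train_kwargs = dict(raw.get("train", {}))
    if "patch_size" in train_kwargs:
        train_kwargs["patch_size"] = tuple(train_kwargs["patch_size"])
    if "augment" in raw:
        train_kwargs["augment"] = AugmentConfig(**raw["augment"])
    config = TrainConfig(**train_kwargs)

    post = PostprocessConfig(**raw.get("postprocess", {}))
    return spec, config, post


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: Path, result: TrainResult) -> None:
    spec = result.spec
    meta = {
        "in_channels": spec.in_channels,
        "classes": spec.classes,
        "base_filters": spec.base_filters,
        "depth": spec.depth,
        "rnd_levels": spec.rnd_levels,
        "rates": list(spec.scheme.rates),
        "kernel": spec.scheme.kernel,
        "se_reduction": spec.se_reduction,
        "stage": result.stage,
        "best_val_dice": result.best_val_dice,
        "patch_size": list(result.patch_size),
    }
    arrays = {f"param_{i}": v for i, v in enumerate(result.state["params"])}
    for i, (mean, var) in enumerate(result.state["running"]):
        arrays[f"bn_mean_{i}"] = mean
        arrays[f"bn_var_{i}"] = var
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: Path) -> tuple[NetworkSpec, dict, dict]:
    """Returns (spec, state, meta); use :func:`restore_net` to rebuild."""
    from .netspec import DilationScheme

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    spec = NetworkSpec(
        in_channels=meta["in_channels"],
        classes=meta["classes"],
        base_filters=meta["base_filters"],
        depth=meta["depth"],
        rnd_levels=meta["rnd_levels"],
        scheme=DilationScheme(rates=tuple(meta["rates"]), kernel=meta["kernel"]),
        se_reduction=meta["se_reduction"],
    )
    n_params = len([k for k in data.files if k.startswith("param_")])
    n_bn = len([k for k in data.files if k.startswith("bn_mean_")])
    state = {
        "params": [data[f"param_{i}"] for i in range(n_params)],
        "running": [(data[f"bn_mean_{i}"], data[f"bn_var_{i}"]) for i in range(n_bn)],
    }
    return spec, state, meta


def restore_net(spec: NetworkSpec, state: dict) -> NDN:
    net = NDN(spec, rng=np.random.default_rng(0))
    nn.set_state(net, state)
    return net
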