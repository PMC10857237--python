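"""Training loop, dataset splitting, model comparison and checkpoints.

The training protocol follows the compared-models experiment: SGD with
momentum on the weighted BCE + Dice loss, an 80/20 train/test split, and
model selection by the best test IoU after convergence.  Two presets are
provided:

* ``paper``: depth-5 / width-32 models, 256x256 inputs, SGD lr 0.001,
  momentum 0.9, weight decay 1e-4, 200 epochs, batch 16 — the full-scale
  protocol.
* ``desk``: depth-3 / width-8 models on 128x128 synthetic scenes, 30
  epochs, batch 8, lr 0.05 — a CPU-scale configuration for development and
  the test suite.  The larger constant learning rate compensates for the
  ~40x shorter schedule.

Runs are bit-reproducible from the seed: weight initialization, data order
and the synthetic data itself all derive from it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .metrics import (MetricReport, bce_dice_loss, evaluate_dataset,
                      evaluate_masks, metrics_from_counts, ConfusionCounts,
                      confusion_counts)
from .optim import SGD
from .synthetic import GeneratorConfig, ImageMaskPair, generate_dataset
from .unetpp import ModelConfig, MODEL_NAMES, build_model
from .seam import SeamConfig

TABLE_COLUMNS = ("Accuracy", "Loss", "IoU", "Recall", "Precision", "Dice")


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the published full-scale protocol."""

    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    epochs: int = 200
    batch_size: int = 16
    w_bce: float = 0.5
    w_dice: float = 1.0
    split: float = 0.8
    seed: int = 0
    device: str = "cpu"
    scale: str = "paper"

    def __post_init__(self):
        if not (0 < self.split < 1):
            raise ValueError("split must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunRecord:
    """Everything produced by one training run."""

    train_loss: list[float] = field(default_factory=list)
    eval_metrics: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_iou: float = -1.0
    best_state: dict | None = None
    checkpoint_path: str | None = None
    config_hash: str = ""
    seed: int = 0
    wall_time: float = 0.0

    def to_json(self, path) -> None:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "best_state"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def desk_preset(seed: int = 0) -> tuple[GeneratorConfig, ModelConfig, TrainConfig]:
    """CPU-scale preset: 64x64 scenes, depth-3/width-8 models, 30 epochs."""
    gen = GeneratorConfig(canvas=(64, 64), n_cells=(3, 7),
                          semi_major=(5.0, 10.0), blur_sigma=0.8)
    model = ModelConfig(depth=3, base_width=8,
                        seam=SeamConfig(channels=8))
    train_cfg = TrainConfig(lr=0.05, epochs=30, batch_size=8, seed=seed,
                            scale="desk")
    return gen, model, train_cfg


def paper_preset(seed: int = 0) -> tuple[GeneratorConfig, ModelConfig, TrainConfig]:
    """Full-scale preset mirroring the published protocol (data regenerated
    synthetically; the original 246-image dataset is private)."""
    gen = GeneratorConfig(canvas=(256, 256))
    model = ModelConfig(depth=5, base_width=32,
                        seam=SeamConfig(channels=32))
    return gen, model, TrainConfig(seed=seed)


def split_dataset(pairs: list, fraction: float = 0.8,
                  seed: int = 0) -> tuple[list, list]:
    """Seeded shuffle then disjoint, exhaustive split; the train size is
    round-half-up of fraction * n (so 2307 -> 1846/461)."""
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    train = [pairs[i] for i in idx[:n_train]]
    test = [pairs[i] for i in idx[n_train:]]
    return train, test


def _stack(pairs: list[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.transpose(p.image, (2, 0, 1)) for p in pairs]).astype(np.float32)
    y = np.stack([p.mask[None].astype(np.float32) for p in pairs])
    return x, y


def train(model, train_pairs: list[ImageMaskPair], config: TrainConfig,
          eval_pairs: list[ImageMaskPair] | None = None,
          checkpoint_path=None, verbose: bool = False) -> RunRecord:
    """Mini-batch SGD on the BCE + Dice loss.

    Evaluates on ``eval_pairs`` after every epoch and keeps the state with
    the highest aggregate IoU (earlier epoch wins ties).  Raises on NaN
    loss with a diagnostic.
    """
    from . import autograd as ag

    if not train_pairs:
        raise ValueError("training set is empty")
    x_all, y_all = _stack(train_pairs)
    n = len(train_pairs)
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
              weight_decay=config.weight_decay)
    record = RunRecord(config_hash=config.config_hash(), seed=config.seed)
    t0 = time.perf_counter()
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb = ag.Tensor(x_all[batch])
            yb = y_all[batch]
            prob = model(xb)
            try:
                loss = bce_dice_loss(prob, yb, w_bce=config.w_bce,
                                     w_dice=config.w_dice)
                diverged = not np.isfinite(loss.item())
            except FloatingPointError:
                diverged = True
            if diverged:
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}, "
                    f"batch starting {start}; lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        record.train_loss.append(float(np.mean(losses)))
        if eval_pairs:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                report = evaluate_dataset(model, eval_pairs)
            record.eval_metrics.append(report.aggregate)
            if report.aggregate["iou"] > record.best_iou:
                record.best_iou = report.aggregate["iou"]
                record.best_epoch = epoch
                record.best_state = model.state_dict()
        if verbose:
            msg = {"epoch": epoch, "train_loss": record.train_loss[-1]}
            if eval_pairs:
                msg.update(record.eval_metrics[-1])
            print(json.dumps(msg))
    if eval_pairs is None:
        record.best_state = model.state_dict()
        record.best_epoch = config.epochs - 1
    record.wall_time = time.perf_counter() - t0
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, state=record.best_state)
        record.checkpoint_path = str(checkpoint_path)
    return record


# ---------------------------------------------------------------------------
# model comparison harness
# ---------------------------------------------------------------------------

def boundary_zone(instances: np.ndarray, radius: int = 3) -> np.ndarray:
    """Pixels within ``radius`` (Chebyshev) of an inter-cell boundary:
    locations whose neighbourhood contains two distinct cell labels."""
    size = 2 * radius + 1
    lab = instances.astype(np.int64)
    sentinel = int(lab.max()) + 1  # stands in for background in the min filter
    big = np.where(lab > 0, lab, sentinel)
    lo = ndimage.minimum_filter(big, size=size)
    hi = ndimage.maximum_filter(lab, size=size)
    return (lo < sentinel) & (hi > lo)


def compare_models(names: list[str], pairs: list[ImageMaskPair],
                   model_config: ModelConfig, train_config: TrainConfig,
                   boundary_radius: int = 3, verbose: bool = False) -> dict:
    """Train each named model under identical splits/seeds/schedules.

    Returns {"table": {name: {Accuracy, Loss, IoU, Recall, Precision, Dice}},
    "boundary": adhesion-zone metrics (pixels within ``boundary_radius`` of
    an inter-cell boundary), "records": per-model RunRecord, "split_hash"}.
    """
    if len(names) < 2:
        raise ValueError("compare_models needs at least two model names")
    for name in names:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}")
    train_set, test_set = split_dataset(pairs, train_config.split,
                                        train_config.seed)
    split_hash = hashlib.sha256(
        b"".join(np.ascontiguousarray(p.mask).tobytes() for p in train_set)
    ).hexdigest()[:12]
    table: dict[str, dict] = {}
    boundary: dict[str, dict] = {}
    records: dict[str, RunRecord] = {}
    for name in names:
        model = build_model(name, model_config,
                            rng=np.random.default_rng(train_config.seed))
        record = train(model, train_set, train_config, eval_pairs=test_set,
                       verbose=verbose)
        if record.best_state is not None:
            model.load_state_dict(record.best_state)
        report = evaluate_dataset(model, test_set)
        x_test, y_test = _stack(test_set)
        probs = model.predict_proba(x_test)
        test_loss = bce_dice_loss(probs, y_test, w_bce=train_config.w_bce,
                                  w_dice=train_config.w_dice).item()
        agg = report.aggregate
        table[name] = {"Accuracy": agg["accuracy"], "Loss": test_loss,
                       "IoU": agg["iou"], "Recall": agg["recall"],
                       "Precision": agg["precision"], "Dice": agg["dice"]}
        boundary[name] = _boundary_metrics(probs, test_set, boundary_radius)
        records[name] = record
    return {"table": table, "boundary": boundary, "records": records,
            "split_hash": split_hash}


def _boundary_metrics(probs: np.ndarray, test_set: list[ImageMaskPair],
                      radius: int) -> dict:
    total = ConfusionCounts(0, 0, 0, 0)
    n_zone = 0
    for i, pair in enumerate(test_set):
        if pair.instances is None:
            continue
        zone = boundary_zone(pair.instances, radius)
        if not zone.any():
            continue
        pred = (probs[i, 0] >= 0.5)[zone]
        true = pair.mask.astype(bool)[zone]
        total = total + confusion_counts(pred, true)
        n_zone += int(zone.sum())
    if total.total == 0:
        return {"n_pixels": 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = metrics_from_counts(total)
    out["n_pixels"] = n_zone
    return out


def format_table(table: dict[str, dict]) -> str:
    header = "Model".ljust(14) + "".join(c.rjust(11) for c in TABLE_COLUMNS)
    lines = [header]
    for name, row in table.items():
        lines.append(name.ljust(14)
                     + "".join(f"{row[c]:11.4f}" for c in TABLE_COLUMNS))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path, state: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar with the architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **(state or model.state_dict()))
    sidecar = {"model": _model_name(model), "config": model.config.to_dict()}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path):
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    config = ModelConfig.from_dict(sidecar["config"])
    model = build_model(sidecar["model"], config)
    try:
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
    except (KeyError, ValueError, OSError) as exc:
        raise RuntimeError(f"corrupt or incompatible checkpoint {path}: {exc}") from exc
    return model


def _model_name(model) -> str:
    from .unetpp import UNet, UNetPP

    if isinstance(model, UNet):
        return "unet"
    if isinstance(model, UNetPP):
        return "seam_unetpp" if model.seam is not None else "unetpp"
    raise TypeError(f"unknown model type {type(model)}")
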