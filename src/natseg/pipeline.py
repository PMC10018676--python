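"""Training, prediction and evaluation orchestration.

Two named configuration profiles ship with the package: ``desk`` (96 px
phantoms, embed_dim 16, one block per stage, 20 epochs, Adam lr 1e-3) runs a
full experiment on one CPU in minutes; ``paper`` (288 px, embed_dim 32, two
blocks per stage, 200 epochs, Adam lr 1e-4, batch 4) is the full-scale
protocol.  Training is seeded end to end — the data split, augmentation
draws, parameter initialization and batch order all derive from the run
seed — so two runs with the same config produce bit-identical logs, and a
run resumed from its last checkpoint continues exactly where an
uninterrupted run would be.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data import list_cases, load_case, save_label, save_preview
from .encoder import EncoderConfig
from .errors import InvalidConfigError
from .losses import MixedLossConfig, mixed_loss, one_hot
from .metrics import CaseResult, evaluate_case, group_mask, write_report
from .model import (ModelConfig, MultiModalSegNet, load_checkpoint,
                    predict_labels, save_checkpoint)
from .nn import Adam, clip_grad_norm
from .phantom import PhantomSpec, make_dataset, random_rotate, random_warp
from .vocab import EVAL_GROUPS

__all__ = ["TrainConfig", "desk_profile", "paper_profile", "train",
           "predict", "evaluate_dataset", "overfit_single_case"]


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: MixedLossConfig = field(default_factory=MixedLossConfig)
    optimizer: str = "adam"
    lr: float = 1e-4
    epochs: int = 200
    batch_size: int = 4
    seed: int = 0
    augment: bool = True
    aug_replicas: int = 1        # augmented passes over the training set per epoch
    lr_schedule: str = "constant"  # "constant" or "cosine" (decay to lr/10)
    warp_amplitude: float = 4.0
    phantom: PhantomSpec | None = None     # synthetic data source ...
    data_dir: str | None = None            # ... or a directory of NIfTI cases
    n_cases: int = 25
    split_ratio: float = 0.2

    def validate(self) -> None:
        if self.lr <= 0:
            raise InvalidConfigError("lr must be positive")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise InvalidConfigError("batch_size must be >= 1")
        if self.aug_replicas < 1:
            raise InvalidConfigError("aug_replicas must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise InvalidConfigError("lr_schedule must be 'constant' or 'cosine'")
        if self.phantom is None and self.data_dir is None:
            raise InvalidConfigError("either phantom spec or data_dir must be set")


def desk_profile(seed: int = 0, **overrides) -> TrainConfig:
    cfg = TrainConfig(
        model=ModelConfig(
            encoder=EncoderConfig(embed_dim=16, depths=(1, 1, 1), num_heads=(2, 4, 8),
                                  seed=seed),
            seed=seed),
        lr=1e-3, epochs=20, batch_size=1, seed=seed,
        aug_replicas=4, lr_schedule="cosine", warp_amplitude=1.5,
        phantom=PhantomSpec(image_size=96, seed=seed))
    return replace(cfg, **overrides)


def paper_profile(seed: int = 0, **overrides) -> TrainConfig:
    cfg = TrainConfig(
        model=ModelConfig(
            encoder=EncoderConfig(embed_dim=32, depths=(2, 2, 2), num_heads=(2, 4, 8),
                                  seed=seed),
            seed=seed),
        lr=1e-4, epochs=200, batch_size=4, seed=seed,
        phantom=PhantomSpec(image_size=288, seed=seed))
    return replace(cfg, **overrides)


def _load_dataset(cfg: TrainConfig):
    """Returns (cases, train_idx, val_idx) where each case is
    (images, label, spacing)."""
    if cfg.data_dir is not None:
        dirs = list_cases(cfg.data_dir)
        if not dirs:
            raise InvalidConfigError(f"no cases found under {cfg.data_dir}")
        cases = []
        for d in dirs:
            images, label, spacing = load_case(d)
            cases.append(([np.asarray(im, dtype=np.float32) for im in images],
                          label, spacing))
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(cases))
        n_test = max(1, int(round(len(cases) * cfg.split_ratio)))
        return cases, sorted(order[n_test:].tolist()), sorted(order[:n_test].tolist())
    split = make_dataset(cfg.phantom, cfg.n_cases, cfg.split_ratio, seed=cfg.seed)
    cases = [(c.images, c.label, (1.0, 1.0)) for c in split.cases]
    return cases, split.train_idx, split.test_idx


def _augment(images, label, amplitude: float, seed: int):
    warped = [random_warp(im, label, amplitude, seed)[0] for im in images]
    _, label_w = random_warp(images[0], label, amplitude, seed)
    out_images, out_label = [], None
    for im in warped:
        im_r, out_label = random_rotate(im, label_w, seed)
        out_images.append(im_r)
    return out_images, out_label


def _batch_tensors(cases, idx, augment_flags, amplitude: float, aug_seeds=None):
    mods = [[], [], []]
    labels = []
    for pos, i in enumerate(idx):
        images, label, _ = cases[i]
        if augment_flags[pos]:
            images, label = _augment(images, label, amplitude, int(aug_seeds[pos]))
        for m in range(3):
            mods[m].append(np.asarray(images[m], dtype=np.float32)[None])
        labels.append(label)
    xs = [Tensor(np.stack(m)) for m in mods]
    return xs, np.stack(labels)


def _foreground_dice(res: CaseResult) -> float:
    vals = [v for v in res.dice.values() if not math.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _validate(model, cases, idx):
    per_group = {g: [] for g in EVAL_GROUPS}
    for i in idx:
        images, label, spacing = cases[i]
        xs = [Tensor(np.asarray(im, dtype=np.float32)[None, None]) for im in images]
        pred = predict_labels(model(*xs))[0]
        res = evaluate_case(pred, label, spacing)
        for g in EVAL_GROUPS:
            per_group[g].append(res.dice[g])
    return {g: float(np.mean(v)) for g, v in per_group.items()}


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_checkpoint: Path
    last_checkpoint: Path
    val_dice: dict


def train(cfg: TrainConfig, out_dir, resume: bool = False, quiet: bool = False) -> TrainResult:
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases, train_idx, val_idx = _load_dataset(cfg)
    if not train_idx:
        raise InvalidConfigError("empty training set")

    model = MultiModalSegNet(cfg.model)
    opt = Adam(model.named_parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    start_epoch = 0
    rows = []
    best_dice = -1.0
    best_path = out_dir / "best.npz"
    last_path = out_dir / "last.npz"
    log_path = out_dir / "train_log.csv"

    if resume and last_path.exists():
        model, extra = load_checkpoint(last_path)
        opt = Adam(model.named_parameters(), lr=cfg.lr)
        opt.load_state_dict({"t": extra["opt_t"],
                             "m": {n: extra[f"opt_m/{n}"] for n in dict(model.named_parameters())},
                             "v": {n: extra[f"opt_v/{n}"] for n in dict(model.named_parameters())}})
        rng.bit_generator.state = json.loads(str(extra["rng_state"]))
        start_epoch = int(extra["epoch"]) + 1
        best_dice = float(extra["best_dice"])
        if log_path.exists():
            rows = pd.read_csv(log_path).to_dict("records")

    # with several passes per epoch, the first pass is unaugmented so the
    # model also trains on the clean orientation it is validated in
    replicas = cfg.aug_replicas if cfg.augment else 1
    n_base = len(train_idx)
    n_train = n_base * replicas
    for epoch in range(start_epoch, cfg.epochs):
        if cfg.lr_schedule == "cosine":
            frac = epoch / max(cfg.epochs - 1, 1)
            opt.lr = cfg.lr * (0.1 + 0.9 * 0.5 * (1 + math.cos(math.pi * frac)))
        perm = rng.permutation(n_train)
        aug_seeds = rng.integers(0, 2 ** 31 - 1, size=n_train)
        epoch_loss, comp_sums, n_batches = 0.0, {"msssim": 0.0, "focal": 0.0, "tversky": 0.0}, 0
        for b0 in range(0, n_train, cfg.batch_size):
            sel = perm[b0:b0 + cfg.batch_size]
            idx = [train_idx[i % n_base] for i in sel]
            flags = [cfg.augment and (i >= n_base or replicas == 1) for i in sel]
            xs, labels = _batch_tensors(cases, idx, flags, cfg.warp_amplitude,
                                        aug_seeds[b0:b0 + cfg.batch_size])
            out = model(*xs)
            target = one_hot(labels, cfg.model.num_classes)
            total, parts = mixed_loss(out.probs, target, cfg.loss)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_loss += float(total.data)
            for kk in comp_sums:
                comp_sums[kk] += parts[kk]
            n_batches += 1
        val = _validate(model, cases, val_idx) if val_idx else {g: float("nan") for g in EVAL_GROUPS}
        mean_fg = float(np.nanmean(list(val.values())))
        row = {"epoch": epoch, "loss": epoch_loss / n_batches,
               **{f"loss_{k}": v / n_batches for k, v in comp_sums.items()},
               **{f"dice_{g}": val[g] for g in EVAL_GROUPS},
               "dice_mean": mean_fg}
        rows.append(row)
        if not quiet:
            print(f"epoch {epoch:3d}  loss {row['loss']:.4f}  val dice {mean_fg:.4f}")
        if mean_fg >= best_dice or math.isnan(mean_fg):
            best_dice = mean_fg if not math.isnan(mean_fg) else best_dice
            save_checkpoint(model, best_path)
        extra = {"epoch": epoch, "best_dice": best_dice,
                 "rng_state": json.dumps(rng.bit_generator.state),
                 "opt_t": opt.t}
        for n in dict(model.named_parameters()):
            extra[f"opt_m/{n}"] = opt.m[n]
            extra[f"opt_v/{n}"] = opt.v[n]
        save_checkpoint(model, last_path, extra=extra)
        pd.DataFrame(rows).to_csv(log_path, index=False)

    history = pd.DataFrame(rows)
    return TrainResult(history=history, best_checkpoint=best_path,
                       last_checkpoint=last_path,
                       val_dice=_validate(model, cases, val_idx) if val_idx else {})


def overfit_single_case(cfg: TrainConfig, case, steps: int = 200, quiet: bool = True,
                        lr: float | None = None, warmup_steps: int = 20,
                        grad_clip: float = 1.0):
    """Fit the model to ONE case for `steps` gradient steps (learnability probe).

    The probe uses an aggressive schedule stabilized for very short budgets:
    twice the config learning rate with a short linear warmup and global
    gradient-norm clipping.  Returns (model, history of losses)."""
    cfg.validate()
    images, label = case
    model = MultiModalSegNet(cfg.model)
    peak_lr = lr if lr is not None else 2.0 * cfg.lr
    opt = Adam(model.named_parameters(), lr=peak_lr)
    params = list(model.parameters())
    xs = [Tensor(np.asarray(im, dtype=np.float32)[None, None]) for im in images]
    target = one_hot(label[None], cfg.model.num_classes)
    losses = []
    for step in range(steps):
        if warmup_steps:
            opt.lr = peak_lr * min(1.0, (step + 1) / warmup_steps)
        out = model(*xs)
        total, _ = mixed_loss(out.probs, target, cfg.loss)
        opt.zero_grad()
        total.backward()
        if grad_clip:
            clip_grad_norm(params, grad_clip)
        opt.step()
        losses.append(float(total.data))
        if not quiet and step % 20 == 0:
            print(f"step {step:4d}  loss {losses[-1]:.4f}")
    return model, losses


def predict(checkpoint, case_dir, out_dir) -> np.ndarray:
    """Forward + argmax on one case directory; writes label NIfTI and PNG."""
    model, _ = load_checkpoint(checkpoint)
    images, _, spacing = load_case(case_dir)
    xs = [Tensor(np.asarray(im, dtype=np.float32)[None, None]) for im in images]
    pred = predict_labels(model(*xs))[0]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_label(pred, out_dir / "prediction.nii.gz", spacing)
    save_preview(out_dir / "prediction.png", images, pred)
    return pred


def evaluate_dataset(checkpoint, case_dirs, report_csv, quiet: bool = True) -> pd.DataFrame:
    """Evaluate a checkpoint over case directories; per-case failures are
    recorded and the run continues.  Groups with no truth foreground are
    reported as NaN (not applicable), never as zero."""
    model, _ = load_checkpoint(checkpoint)
    results, errors = {}, {}
    for d in case_dirs:
        d = Path(d)
        try:
            images, label, spacing = load_case(d)
            xs = [Tensor(np.asarray(im, dtype=np.float32)[None, None]) for im in images]
            pred = predict_labels(model(*xs))[0]
            res = evaluate_case(pred, label, spacing)
            for g in EVAL_GROUPS:
                if not group_mask(label, g).any():
                    res.dice[g] = float("nan")
                    res.hd[g] = float("nan")
            results[d.name] = res
        except (FileNotFoundError, ValueError) as exc:
            errors[d.name] = str(exc)
            if not quiet:
                print(f"case {d.name} failed: {exc}")
    df = write_report(results, report_csv)
    if errors:
        pd.Series(errors, name="error").to_csv(Path(report_csv).with_suffix(".errors.csv"))
    return df
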