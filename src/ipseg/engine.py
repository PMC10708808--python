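"""Training, evaluation, checkpointing and the ablation harness.

The composite loss supervises the fused base-resolution prediction with
pixelwise two-class cross-entropy and adds an auxiliary cross-entropy term
(weight 0.4 by default) on every per-scale prediction against the mask
resampled (nearest-neighbor) to that scale; fused-only supervision starves
the outer pyramid rungs early in training.

Optimization is SGD with momentum under an equal-interval step-decay
schedule (default interval epochs/3, factor 0.1).  Model selection keeps the
epoch with the best validation mean Dice.  Everything is deterministic in
the configured seed on a fixed device.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as M
from . import nn
from .nn import functional as F
from .nn.autograd import Tensor
from .pablock import PABlockConfig
from .panet import ASPPConfig, BackboneConfig, PANet, PANetConfig
from .pyramid import Image, InterpKernelConfig, read_image, upscale
from .synthetic_data import load_manifest

__all__ = [
    "TrainConfig",
    "TrainResult",
    "load_split",
    "precompute_pyramids",
    "nearest_resize_mask",
    "fit_model",
    "predict_scores",
    "predict_masks",
    "evaluate_model",
    "save_checkpoint",
    "load_checkpoint",
    "ablate",
    "config_to_dict",
    "config_from_dict",
]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    momentum: float = 0.9
    epochs: int = 150
    batch_size: int = 8
    seed: int = 0
    lr_step_interval: int | None = None   # None -> epochs // 3 (min 1)
    lr_step_factor: float = 0.1
    fused_weight: float = 1.0
    aux_weight: float = 0.4
    augment_flip: bool = False
    device: str = "cpu"

    def decay_interval(self) -> int:
        if self.lr_step_interval is not None:
            return max(1, self.lr_step_interval)
        return max(1, self.epochs // 3)


@dataclass
class TrainResult:
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float
    best_state: dict[str, np.ndarray] = field(repr=False)


# ------------------------------------------------------------------ data prep
def load_split(manifest: pd.DataFrame | str | Path, split: str
               ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load one manifest split into (images (N,1,H,W), masks (N,H,W), ids)."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    rows = manifest[manifest["split"] == split]
    if len(rows) == 0:
        raise ValueError(f"manifest split {split!r} is empty")
    images, masks, ids = [], [], []
    for _, row in rows.iterrows():
        images.append(read_image(row["image"]).pixels.astype(np.float32))
        mask = read_image(row["mask"]).pixels[0]
        masks.append((mask > 0.5).astype(np.uint8))
        ids.append(str(row["id"]))
    return np.stack(images), np.stack(masks), ids


def _ensure_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[:, None]
    if images.ndim != 4:
        raise ValueError(f"expected (N,H,W) or (N,C,H,W) images, got "
                         f"{images.shape}")
    return images


def precompute_pyramids(images: np.ndarray, factors,
                        cfg: InterpKernelConfig = InterpKernelConfig()
                        ) -> list[np.ndarray]:
    """Per-factor stacks of bicubic-enlarged inputs (float32, clamped)."""
    images = _ensure_nchw(images)
    rungs: list[list[np.ndarray]] = [[] for _ in factors]
    for img in images:
        src = Image(img.astype(np.float64))
        for k, f in enumerate(factors):
            if f == 1:
                rungs[k].append(img.astype(np.float32))
            else:
                up = np.clip(upscale(src, f, cfg).pixels, 0.0, 1.0)
                rungs[k].append(up.astype(np.float32))
    return [np.stack(r) for r in rungs]


def nearest_resize_mask(mask: np.ndarray, oh: int, ow: int) -> np.ndarray:
    """Nearest-neighbor label resampling with half-pixel centers."""
    h, w = mask.shape[-2:]
    ri = np.clip(((np.arange(oh) + 0.5) * h / oh - 0.5).round().astype(int), 0, h - 1)
    ci = np.clip(((np.arange(ow) + 0.5) * w / ow - 0.5).round().astype(int), 0, w - 1)
    return mask[..., ri[:, None], ci[None, :]]


# ----------------------------------------------------------------- train loop
def _batch_loss(model: PANet, rung_batches: list[np.ndarray],
                mask_batch: np.ndarray, cfg: TrainConfig) -> Tensor:
    per_scale, fused = model([Tensor(r) for r in rung_batches])
    loss = F.softmax_cross_entropy(fused, mask_batch) * Tensor(
        np.float32(cfg.fused_weight))
    if cfg.aux_weight > 0:
        for p in per_scale:
            target = nearest_resize_mask(mask_batch, p.shape[2], p.shape[3])
            loss = loss + F.softmax_cross_entropy(p, target) * Tensor(
                np.float32(cfg.aux_weight))
    return loss


def fit_model(model: PANet, train_images: np.ndarray, train_masks: np.ndarray,
              cfg: TrainConfig, val_images: np.ndarray | None = None,
              val_masks: np.ndarray | None = None, verbose: int = 0
              ) -> TrainResult:
    """SGD training of a PANet on in-memory arrays; returns the best state."""
    factors = model.cfg.factors
    rng = np.random.default_rng(cfg.seed)
    rungs = precompute_pyramids(train_images, factors)
    n = len(train_images)
    if n == 0:
        raise ValueError("empty training set")
    opt = nn.SGD(list(model.named_parameters()), lr=cfg.lr,
                 momentum=cfg.momentum)
    interval = cfg.decay_interval()

    history_rows = []
    best = (-1.0, -1, None)  # (val dice, epoch, state)
    for epoch in range(cfg.epochs):
        opt.lr = nn.step_decay_lr(cfg.lr, epoch, interval, cfg.lr_step_factor)
        model.train()
        order = rng.permutation(n)
        flip = (rng.random(n) < 0.5) if cfg.augment_flip else None
        epoch_loss, t0 = 0.0, time.time()
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            rb = [r[idx] for r in rungs]
            mb = train_masks[idx]
            if flip is not None:
                fl = flip[order[start:start + cfg.batch_size]]
                rb = [np.where(fl[:, None, None, None], r[:, :, :, ::-1], r)
                      for r in rb]
                mb = np.where(fl[:, None, None], mb[:, :, ::-1], mb)
            opt.zero_grad()
            loss = _batch_loss(model, rb, mb, cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n

        val_dice = np.nan
        if val_images is not None:
            table, summary = evaluate_model(model, val_images, val_masks)
            val_dice = float(summary["mean"]["dice"])
            if val_dice > best[0]:
                best = (val_dice, epoch,
                        {k: v.copy() for k, v in model.state_dict().items()})
        history_rows.append({"epoch": epoch, "lr": opt.lr,
                             "train_loss": epoch_loss, "val_dice": val_dice})
        if verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.4g}  loss {epoch_loss:.4f}"
                  f"  val dice {val_dice:.4f}  ({time.time() - t0:.1f}s)")

    if best[2] is None:  # no validation set: keep the final parameters
        best = (np.nan, cfg.epochs - 1,
                {k: v.copy() for k, v in model.state_dict().items()})
    model.load_state_dict(best[2])
    return TrainResult(history=pd.DataFrame(history_rows),
                       best_epoch=best[1], best_val_dice=best[0],
                       best_state=best[2])


# ----------------------------------------------------------------- inference
def predict_scores(model: PANet, images: np.ndarray,
                   batch_size: int = 8) -> np.ndarray:
    """Fused class score maps (N, K, H, W) for a stack of (N,1,H,W) images."""
    model.eval()
    rungs = precompute_pyramids(images, model.cfg.factors)
    outs = []
    for start in range(0, len(images), batch_size):
        rb = [Tensor(r[start:start + batch_size]) for r in rungs]
        _, fused = model(rb)
        outs.append(fused.data)
    return np.concatenate(outs, axis=0)


def predict_masks(model: PANet, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    scores = predict_scores(model, images, batch_size)
    return (np.argmax(scores, axis=1) == 1).astype(np.uint8)


def evaluate_model(model: PANet, images: np.ndarray, masks: np.ndarray,
                   ids: list[str] | None = None, batch_size: int = 8
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-image metric table and a mean/std summary over the set."""
    preds = predict_masks(model, images, batch_size)
    reports = [M.evaluate_masks(p, g) for p, g in zip(preds, masks)]
    table = M.summarize_reports(reports)
    if ids is not None:
        table.insert(0, "id", ids)
    metric_cols = ["dice", "jaccard", "precision", "recall", "f_measure"]
    summary = pd.DataFrame({"mean": table[metric_cols].mean(),
                            "std": table[metric_cols].std(ddof=0)})
    return table, summary


# --------------------------------------------------------------- checkpoints
def config_to_dict(cfg: PANetConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> PANetConfig:
    d = dict(d)
    d["backbone"] = BackboneConfig(**d["backbone"])
    d["aspp"] = ASPPConfig(**{**d["aspp"], "dilation_rates":
                              tuple(d["aspp"]["dilation_rates"])})
    d["pablock"] = PABlockConfig(**d["pablock"])
    d["factors"] = tuple(d["factors"])
    return PANetConfig(**d)


def save_checkpoint(path: str | Path, model: PANet, train_cfg: TrainConfig,
                    epoch: int, optimizer: nn.SGD | None = None,
                    rng: np.random.Generator | None = None):
    """Serialize model parameters, optimizer state and configs to one .npz."""
    meta = {
        "model_config": config_to_dict(model.cfg),
        "train_config": dataclasses.asdict(train_cfg),
        "epoch": int(epoch),
        "rng_state": rng.bit_generator.state if rng is not None else None,
    }
    arrays = {f"model.{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        arrays.update({f"opt.{k}": v for k, v in optimizer.state_dict().items()})
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path, seed: int = 0
                    ) -> tuple[PANet, TrainConfig, int]:
    """Rebuild the model from a checkpoint; parameters restored bit-exactly."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model_cfg = config_from_dict(meta["model_config"])
        model = PANet(model_cfg, np.random.default_rng(seed))
        state = {k[len("model."):]: data[k] for k in data.files
                 if k.startswith("model.")}
        model.load_state_dict(state)
        train_cfg = TrainConfig(**meta["train_config"])
    return model, train_cfg, meta["epoch"]


# ------------------------------------------------------------------ ablation
def ablate(train_images: np.ndarray, train_masks: np.ndarray,
           eval_images: np.ndarray, eval_masks: np.ndarray,
           base_cfg: PANetConfig, train_cfg: TrainConfig,
           verbose: int = 0) -> pd.DataFrame:
    """Train and evaluate the 2x2 grid {pyramid on/off} x {PABlock on/off}.

    Rows: baseline, +pyramid, +pablock, both — all with the same seed and
    budget; cells are mean metrics over the evaluation set.
    """
    grid = [
        ("baseline", (1.0,), False),
        ("+pyramid", base_cfg.factors, False),
        ("+pablock", (1.0,), True),
        ("both", base_cfg.factors, True),
    ]
    rows = []
    for name, factors, use_pab in grid:
        cfg = dataclasses.replace(base_cfg, factors=tuple(factors),
                                  use_pablocks=use_pab)
        model = PANet(cfg, np.random.default_rng(train_cfg.seed))
        fit_model(model, train_images, train_masks, train_cfg,
                  verbose=verbose)
        _, summary = evaluate_model(model, eval_images, eval_masks)
        row = {"variant": name}
        row.update(summary["mean"].to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
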