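"""Training and inference orchestration.

Implements the full training regime: patient-level 9:1 split, multi-scale
input jitter (each step resamples the whole batch to one of the ratios
0.75 / 1 / 1.25 of the 96×96 base size), Adam with the learning rate
multiplied by 0.9 every 30 epochs, early stopping on validation DSC, NaN
guarding with last-good-checkpoint retention, per-epoch CSV logging, and
deterministic seeded runs on CPU.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as sk_resize

from .losses import LossConfig, total_loss
from .metrics import region_metrics
from .model import NoduleCompNet
from .nn import Adam, Tensor
from .synthdata import load_patch


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.9          # multiply lr by this ...
    lr_step_epochs: int = 30       # ... every 30 epochs
    batch_size: int = 4
    max_epochs: int = 60
    early_stop_patience: int = 10
    scales: tuple[float, ...] = (0.75, 1.0, 1.25)
    multiscale: bool = True
    input_size: int = 96
    seed: int = 0
    split_ratio: float = 0.9       # 9:1 at patient level
    width: float = 1.0
    blocks: tuple[int, ...] = (3, 4, 6, 3)
    threshold: float = 0.5
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if 1.0 not in self.scales:
            raise ValueError("scales must contain 1.0")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")


@dataclass
class TrainResult:
    """Outcome of a training run: log, best checkpoint, final metrics."""

    log: pd.DataFrame
    best_epoch: int
    best_val_dsc: float
    checkpoint_path: Path
    stopped_early: bool

    def summary(self) -> str:
        last = self.log.iloc[-1]
        lines = [
            "Training summary",
            "----------------",
            f"epochs run        : {len(self.log)}",
            f"best epoch        : {self.best_epoch}",
            f"best val DSC      : {self.best_val_dsc:.4f}",
            f"final total loss  : {last['total']:.4f}",
            f"early stopped     : {self.stopped_early}",
            f"checkpoint        : {self.checkpoint_path}",
        ]
        return "\n".join(lines)


def split_patients(manifest: pd.DataFrame, ratio: float = 0.9,
                   seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level split: all crops of one patient land on one side."""
    if "patient_id" not in manifest.columns:
        raise ValueError("manifest lacks a patient_id column")
    patients = sorted(manifest["patient_id"].unique())
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(ratio * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_ids = {patients[i] for i in order[:n_train]}
    is_train = manifest["patient_id"].isin(train_ids)
    return (manifest[is_train].reset_index(drop=True),
            manifest[~is_train].reset_index(drop=True))


def multiscale_batch(images: np.ndarray, masks: np.ndarray,
                     scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Resize a (N,H,W) batch by one ratio: bilinear images, nearest masks.

    Scale 1 is a bit-identical passthrough; masks stay binary at any scale.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if scale == 1.0:
        return images, masks
    h, w = images.shape[-2:]
    hw = (int(round(h * scale)), int(round(w * scale)))
    out_i = np.stack([
        sk_resize(im, hw, order=1, mode="reflect", anti_aliasing=(scale < 1))
        for im in images])
    out_m = np.stack([
        sk_resize(m.astype(np.float64), hw, order=0, anti_aliasing=False) > 0.5
        for m in masks]).astype(masks.dtype)
    return out_i, out_m


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """Stepped schedule: lr0 dropped 10% every lr_step_epochs (epoch 1-based)."""
    return config.lr0 * config.lr_decay ** ((epoch - 1) // config.lr_step_epochs)


def _load_split(data_dir, manifest: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    imgs, msks = [], []
    for _, row in manifest.iterrows():
        patch = load_patch(data_dir, row)
        imgs.append(patch.image)
        msks.append(patch.mask)
    return np.stack(imgs).astype(np.float32), np.stack(msks).astype(np.uint8)


def evaluate_dsc(net: NoduleCompNet, images: np.ndarray, masks: np.ndarray,
                 threshold: float = 0.5, batch_size: int = 4) -> float:
    """Mean DSC over a split, computed in eval mode at scale 1."""
    net.eval()
    dscs = []
    for i in range(0, len(images), batch_size):
        x = Tensor(images[i:i + batch_size][:, None])
        pred = net(x)
        probs = pred.seg_prob.data[:, 0]
        for p, g in zip(probs, masks[i:i + batch_size]):
            dscs.append(region_metrics((p >= threshold).astype(np.uint8), g)["DSC"])
    net.train()
    return float(np.mean(dscs))


def train(config: TrainConfig, train_manifest: pd.DataFrame,
          data_dir, out_dir, val_manifest: pd.DataFrame | None = None,
          verbose: bool = False) -> TrainResult:
    """Optimize the hybrid loss; returns the log and best checkpoint.

    Validation DSC (on `val_manifest`, or the training split itself when no
    validation manifest is given) drives checkpoint selection and early
    stopping.
    """
    if len(train_manifest) == 0:
        raise ValueError("empty training manifest")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt_path = out / "best.npz"
    log_path = out / "train_log.csv"

    tr_images, tr_masks = _load_split(data_dir, train_manifest)
    if val_manifest is not None and len(val_manifest) > 0:
        va_images, va_masks = _load_split(data_dir, val_manifest)
    else:
        va_images, va_masks = tr_images, tr_masks

    rng = np.random.default_rng(config.seed)
    net = NoduleCompNet(width=config.width, blocks=config.blocks,
                        seed=config.seed)
    opt = Adam(net.parameters(), lr=config.lr0)

    n = len(tr_images)
    best_dsc, best_epoch = -1.0, 0
    rows = []
    stopped_early = False
    for epoch in range(1, config.max_epochs + 1):
        opt.lr = learning_rate(config, epoch)
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        steps = 0
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            imgs, msks = tr_images[idx], tr_masks[idx]
            if config.multiscale:
                scale = float(rng.choice(config.scales))
                imgs, msks = multiscale_batch(imgs, msks, scale)
            pred = net(Tensor(imgs[:, None]))
            loss, breakdown = total_loss(pred, msks, config.loss)
            if not math.isfinite(loss.item()):
                _write_log(rows, log_path)
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; last good checkpoint "
                    f"retained at {ckpt_path}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            for k, v in breakdown.items():
                sums[k] = sums.get(k, 0.0) + v
            steps += 1
        val_dsc = evaluate_dsc(net, va_images, va_masks, config.threshold,
                               config.batch_size)
        row = {"epoch": epoch, "lr": opt.lr}
        row.update({k: v / steps for k, v in sums.items()})
        row["val_dsc"] = val_dsc
        rows.append(row)
        _write_log(rows, log_path)
        if verbose:  # pragma: no cover
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  "
                  f"loss {row['total']:.4f}  val DSC {val_dsc:.4f}")
        if val_dsc > best_dsc + 1e-9:
            best_dsc, best_epoch = val_dsc, epoch
            net.save_checkpoint(ckpt_path)
        elif epoch - best_epoch >= config.early_stop_patience:
            stopped_early = True
            break

    return TrainResult(pd.DataFrame(rows), best_epoch, best_dsc, ckpt_path,
                       stopped_early)


def _write_log(rows: list[dict], path: Path) -> None:
    if rows:
        pd.DataFrame(rows).to_csv(path, index=False)


def predict(checkpoint, inputs, out_dir, threshold: float = 0.5) -> pd.DataFrame:
    """Run a checkpoint on PNG images; write probability + binary mask PNGs.

    `inputs` is a directory of PNGs or an explicit list of paths.  Returns a
    table of output paths.  Deterministic given checkpoint and inputs.
    """
    net = NoduleCompNet.load_checkpoint(checkpoint)
    net.eval()
    out = Path(out_dir)
    (out / "prob").mkdir(parents=True, exist_ok=True)
    (out / "mask").mkdir(parents=True, exist_ok=True)
    paths = (sorted(Path(inputs).glob("*.png")) if isinstance(inputs, (str, Path))
             else [Path(p) for p in inputs])
    if not paths:
        raise FileNotFoundError(f"no input images found in {inputs}")
    rows = []
    for p in paths:
        img = iio.imread(p).astype(np.float32) / 255.0
        pred = net(Tensor(img[None, None]))
        prob = pred.seg_prob.data[0, 0]
        prob_u8 = np.round(prob * 255).astype(np.uint8)
        mask_u8 = ((prob >= threshold) * 255).astype(np.uint8)
        iio.imwrite(out / "prob" / p.name, prob_u8)
        iio.imwrite(out / "mask" / p.name, mask_u8)
        rows.append({"image": str(p), "prob_path": str(out / "prob" / p.name),
                     "mask_path": str(out / "mask" / p.name)})
    return pd.DataFrame(rows)
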