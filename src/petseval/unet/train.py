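"""Training protocol for the per-slice U-net.

Volumes are segmented slice-by-slice: axial slices are extracted,
normalized by the per-volume SUV maximum (scale invariance across
simulated scanners), and fed to the 2-D network. Cross-validation folds
split by *case*, never by slice, so no patient leaks between folds.
Predictions are restacked to the volume grid, thresholded at 0.5
(probability exactly 0.5 counts as foreground), and reduced to the
largest 26-connected component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from petseval.core import PETVolume, SegmentationMask
from petseval.phantom import PhantomRecord
from petseval.unet.losses import loss_and_grad
from petseval.unet.model import Adam, UNet2D

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class UNetConfig:
    depth: int = 3
    base_filters: int = 8
    dropout_p: float = 0.1
    lr: float = 3e-3
    epochs: int = 30
    batch_size: int = 4
    loss: str = "bce"  # bce | dice | combined
    lam: float = 0.5  # BCE weight of the combined loss
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.loss not in ("bce", "dice", "combined"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class CVReport:
    fold_val_dsc: list[float] = field(default_factory=list)
    fold_cases: list[list[str]] = field(default_factory=list)
    final_train_dsc: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "fold_val_dsc": self.fold_val_dsc,
            "fold_cases": self.fold_cases,
            "final_train_dsc": self.final_train_dsc,
        }


def _pad_to_multiple(img: np.ndarray, div: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    return img, (h, w)


def extract_slices(record: PhantomRecord, margin: int = 1):
    """Axial (x, y) slices covering the tumor extent plus a margin.

    Returns (images, truths); images are normalized by the volume max.
    """
    vol = record.volume.values
    truth = record.truth_mask.values
    vmax = float(vol.max())
    if vmax <= 0:
        raise ValueError(f"{record.case_id}: volume has no signal")
    zs = np.where(truth.any(axis=(0, 1)))[0]
    lo = max(int(zs.min()) - margin, 0)
    hi = min(int(zs.max()) + margin + 1, vol.shape[2])
    imgs = [vol[:, :, z] / vmax for z in range(lo, hi)]
    gts = [truth[:, :, z].astype(np.float64) for z in range(lo, hi)]
    return imgs, gts


def slice_dsc(truth: np.ndarray, pred_bin: np.ndarray) -> float:
    denom = truth.sum() + pred_bin.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (truth.astype(bool) & pred_bin.astype(bool)).sum() / denom)


def train_on_slices(
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    config: UNetConfig,
) -> UNet2D:
    """Fit a fresh U-net on a set of 2-D slices; deterministic given seed."""
    if len(images) != len(truths) or not images:
        raise ValueError("need equal, nonzero numbers of images and truths")
    model = UNet2D(
        depth=config.depth,
        base_filters=config.base_filters,
        dropout_p=config.dropout_p,
        seed=config.seed,
    )
    opt = Adam(model, lr=config.lr)
    _, grad_fn = loss_and_grad(config.loss, config.lam)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 21]))
    div = 2**config.depth
    data = []
    for img, gt in zip(images, truths):
        xi, _ = _pad_to_multiple(np.asarray(img, dtype=np.float64), div)
        yi, _ = _pad_to_multiple(np.asarray(gt, dtype=np.float64), div)
        data.append((xi, yi))
    for _ in range(config.epochs):
        order = rng.permutation(len(data))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            accum = None
            for j in batch:
                xi, yi = data[j]
                p = model.forward(xi, train=True)
                dz = grad_fn(yi, p) / len(batch)
                model.backward(dz)
                g = [(layer.dW.copy(), layer.db.copy()) for layer in model.conv_layers()]
                accum = g if accum is None else [
                    (a0 + b0, a1 + b1) for (a0, a1), (b0, b1) in zip(accum, g)
                ]
            for layer, (gw, gb) in zip(model.conv_layers(), accum):
                layer.dW, layer.db = gw, gb
            opt.step()
    return model


def _predict_slice(model: UNet2D, img: np.ndarray) -> np.ndarray:
    div = 2**model.depth
    xi, (h, w) = _pad_to_multiple(np.asarray(img, dtype=np.float64), div)
    return model.forward(xi, train=False)[:h, :w]


def mean_slice_dsc(model: UNet2D, images, truths) -> float:
    vals = [
        slice_dsc(np.asarray(gt), _predict_slice(model, img) >= 0.5)
        for img, gt in zip(images, truths)
    ]
    return float(np.mean(vals))


def train_unet(
    records: Sequence[PhantomRecord], config: UNetConfig
) -> tuple[UNet2D, CVReport]:
    """Case-level k-fold cross-validation, then a final fit on all cases.

    Per-fold validation DSC is the mean volume-level Dice of the held-out
    cases, computed through the same per-slice prediction path used at
    inference time.
    """
    records = list(records)
    if len(records) < config.folds:
        raise ValueError(
            f"need at least {config.folds} cases for {config.folds}-fold CV, got {len(records)}"
        )
    case_ids = [r.case_id for r in records]
    folds = np.array_split(np.arange(len(records)), config.folds)
    report = CVReport()
    for f, val_idx in enumerate(folds):
        val_idx = set(int(i) for i in val_idx)
        train_imgs, train_gts = [], []
        for i, rec in enumerate(records):
            if i in val_idx:
                continue
            imgs, gts = extract_slices(rec)
            train_imgs += imgs
            train_gts += gts
        fold_cfg = UNetConfig(**{**config.__dict__, "seed": config.seed + 1000 + f})
        model = train_on_slices(train_imgs, train_gts, fold_cfg)
        dscs = []
        for i in sorted(val_idx):
            _, pred = predict_volume(model, records[i].volume)
            from petseval.foms import dice_coefficient

            dscs.append(dice_coefficient(records[i].truth_mask, pred))
        report.fold_val_dsc.append(float(np.mean(dscs)))
        report.fold_cases.append([case_ids[i] for i in sorted(val_idx)])
    all_imgs, all_gts = [], []
    for rec in records:
        imgs, gts = extract_slices(rec)
        all_imgs += imgs
        all_gts += gts
    model = train_on_slices(all_imgs, all_gts, config)
    report.final_train_dsc = mean_slice_dsc(model, all_imgs, all_gts)
    return model, report


def predict_volume(
    model: UNet2D, volume: PETVolume
) -> tuple[np.ndarray, SegmentationMask]:
    """Slice-wise inference restacked to the input grid.

    Returns the per-voxel probability map and the binarized mask
    (probability >= 0.5, largest 26-connected component).
    """
    vol = volume.values
    vmax = float(vol.max())
    if vmax <= 0:
        raise ValueError("volume has no signal")
    probs = np.zeros_like(vol)
    for z in range(vol.shape[2]):
        probs[:, :, z] = _predict_slice(model, vol[:, :, z] / vmax)
    binary = probs >= 0.5
    if binary.any():
        labels, _ = ndimage.label(binary, structure=_STRUCT26)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        binary = labels == int(np.argmax(counts))
    mask = SegmentationMask(
        binary, volume.spacing, meta={"algorithm": "unet", "depth": model.depth}
    )
    return probs, mask


def save_checkpoint(model: UNet2D, config: UNetConfig, report: CVReport, path) -> None:
    """Write weights (.npz) plus a JSON sidecar with config and fold metrics."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "config": config.__dict__,
        "cv_report": report.to_dict(),
        "n_parameters": model.n_parameters(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_checkpoint(path) -> tuple[UNet2D, UNetConfig]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg_d = dict(sidecar["config"])
    cfg = UNetConfig(**cfg_d)
    model = UNet2D(
        depth=cfg.depth, base_filters=cfg.base_filters, dropout_p=cfg.dropout_p, seed=cfg.seed
    )
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model, cfg
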