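"""Training, inference and the slice-count experiment harness.

The training protocol: Adam at learning rate 0.003, batch size 8, and a
fixed global seed (default 39) covering weight initialization, data order
and augmentation, with the hybrid Dice+BCE objective.  Augmentation is
random cropping (resized back to the model resolution) plus horizontal and
vertical flips, applied identically to every channel of a stack and to its
center-slice mask.  Validation tracks global Dice over the validation
stacks and the best-validation weights are retained.

Inference rebuilds a stack for *every* slice of a volume (tumor-slice
filtering is a training-set operation only), thresholds the sigmoid output
at 0.5, and pads the cropped prediction back to the original in-plane size.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import resize

from . import nn
from .losses import LossConfig, hybrid_loss
from .model import ModelConfig, RISUNet
from .preprocess import (CTVolume, MaskVolume, PreprocessConfig, build_stack,
                         crop_bounds, preprocess_case, preprocess_volume)


@dataclass
class AugmentConfig:
    random_crop: bool = True
    hflip: bool = True
    vflip: bool = True
    crop_frac: tuple = (0.8, 1.0)   # crop side as a fraction of the image side


@dataclass
class TrainConfig:
    lr: float = 0.003
    batch_size: int = 8
    epochs: int = 150
    seed: int = 39
    n_slices: int = 3
    loss: LossConfig = field(default_factory=LossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    max_steps: int | None = None    # optional hard cap on optimizer steps
    log_stream: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


def augment(stack: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> tuple:
    """Random crop + flips; the same spatial transform hits every channel
    of the stack and the mask.  With everything disabled this is the
    identity."""
    stack = np.asarray(stack, dtype=np.float64)
    mask = np.asarray(mask)
    if cfg.random_crop:
        h, w = stack.shape[1:]
        frac = rng.uniform(*cfg.crop_frac)
        side = max(int(round(frac * h)), 1)
        if side < h:
            r0 = int(rng.integers(0, h - side + 1))
            c0 = int(rng.integers(0, w - side + 1))
            sub = stack[:, r0:r0 + side, c0:c0 + side]
            stack = np.stack([
                resize(ch, (h, w), order=1, preserve_range=True,
                       anti_aliasing=False) for ch in sub])
            mask = resize(mask[r0:r0 + side, c0:c0 + side].astype(np.float64),
                          (h, w), order=0, preserve_range=True,
                          anti_aliasing=False) > 0.5
    if cfg.hflip and rng.random() < 0.5:
        stack = stack[:, :, ::-1]
        mask = mask[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        stack = stack[:, ::-1, :]
        mask = mask[::-1, :]
    return np.ascontiguousarray(stack), np.ascontiguousarray(mask).astype(np.uint8)


def _as_pairs(data) -> list:
    """Accept (SliceStack, mask) or (ndarray, mask) pairs uniformly."""
    return [(np.asarray(getattr(s, "data", s), dtype=np.float64),
             np.asarray(m)) for s, m in data]


def _batch(samples) -> tuple:
    xs = np.stack([s for s, _ in samples])
    ys = np.stack([m for _, m in samples])[:, None, :, :].astype(np.float64)
    return xs, ys


def _validation_dpc(model: RISUNet, val_data, batch_size: int) -> float:
    """Global Dice over all validation stacks (pooled voxels)."""
    inter = pred_sum = target_sum = 0.0
    for start in range(0, len(val_data), batch_size):
        xs, ys = _batch(val_data[start:start + batch_size])
        pred = model.predict(xs) > 0.5
        inter += float((pred * ys).sum())
        pred_sum += float(pred.sum())
        target_sum += float(ys.sum())
    denom = pred_sum + target_sum
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train(model: RISUNet, train_data: list, val_data: list,
          cfg: TrainConfig | None = None, log_path=None) -> dict:
    """Seeded training loop; returns history and the best-validation state.

    ``train_data``/``val_data`` are lists of ``(stack_array, mask_2d)``
    pairs (as produced by :func:`risunet.preprocess.preprocess_case`).
    Per-epoch training loss and validation Dice go to ``log_path`` as CSV
    when given.  Diverging (non-finite) loss aborts with a diagnostic.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if not train_data:
        raise ValueError("training dataset is empty")
    train_data = _as_pairs(train_data)
    val_data = _as_pairs(val_data) if val_data else []
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg.lr)
    history = {"epoch": [], "train_loss": [], "val_dpc": []}
    best = {"val_dpc": -1.0, "epoch": -1, "state": None}
    steps = 0
    done = False
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_data))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            samples = [augment(*train_data[i], cfg.augment, rng)
                       for i in batch_idx]
            xs, ys = _batch(samples)
            pred = model(nn.Tensor(xs))
            loss = hybrid_loss(pred, ys, cfg.loss)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: loss={value} at epoch {epoch}, "
                    f"step {steps}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break
        train_loss = float(np.mean(epoch_losses))
        val_dpc = (_validation_dpc(model, val_data, cfg.batch_size)
                   if val_data else float("nan"))
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_dpc"].append(val_dpc)
        if cfg.log_stream:
            print(f"epoch={epoch} loss={train_loss:.4f} val_dpc={val_dpc:.4f}",
                  file=sys.stderr)
        if not val_data or not np.isnan(val_dpc):
            score = val_dpc if val_data else -train_loss
            if score > best["val_dpc"]:
                best.update(val_dpc=score, epoch=epoch, state=model.state_dict())
        if done:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_dpc"])
            writer.writerows(zip(history["epoch"], history["train_loss"],
                                 history["val_dpc"]))
    history["steps"] = steps
    history["best_epoch"] = best["epoch"]
    return history


def predict_volume(model: RISUNet, vol: CTVolume,
                   pre_cfg: PreprocessConfig | None = None,
                   batch_size: int = 8, threshold: float = 0.5) -> MaskVolume:
    """Segment every slice of a volume and reassemble a 3D mask.

    The volume goes through the same preprocessing as training data (minus
    tumor-slice filtering); predictions are thresholded and padded back to
    the original in-plane size with zeros where the crop removed border.
    """
    pre_cfg = pre_cfg if pre_cfg is not None else PreprocessConfig()
    if pre_cfg.n_slices != model.config.n_slices:
        raise ValueError(
            f"preprocess n_slices={pre_cfg.n_slices} does not match model "
            f"n_slices={model.config.n_slices}")
    processed = preprocess_volume(vol, pre_cfg)
    h, w, d = vol.data.shape
    r0, _ = crop_bounds(h, pre_cfg.crop_size)
    c0, _ = crop_bounds(w, pre_cfg.crop_size)
    out = np.zeros((h, w, d), dtype=np.uint8)
    stacks = [build_stack(processed, t, pre_cfg.n_slices).data for t in range(d)]
    for start in range(0, d, batch_size):
        xs = np.stack(stacks[start:start + batch_size])
        probs = model.predict(xs)[:, 0]
        for offset, prob in enumerate(probs):
            out[r0:r0 + pre_cfg.crop_size,
                c0:c0 + pre_cfg.crop_size, start + offset] = prob > threshold
    return MaskVolume(out, vol.spacing)


@dataclass
class ExperimentGrid:
    """The slice-count experiment: one training run per odd n."""

    n_slices_values: tuple = (1, 3, 5, 7)

    def __post_init__(self):
        if any(n % 2 == 0 or n < 1 for n in self.n_slices_values):
            raise ValueError("all slice counts must be odd and >= 1")


def run_slice_grid(cases: list, grid: ExperimentGrid,
                   model_cfg: ModelConfig, train_cfg: TrainConfig,
                   pre_cfg: PreprocessConfig | None = None) -> "pandas.DataFrame":
    """Train one model per slice count under identical settings and
    evaluate each on the shared test split.

    ``cases`` is a list of :class:`risunet.phantoms.PhantomCase`.  Returns
    one row per n with the mean of each metric over test cases.
    """
    import pandas as pd

    from .metrics import evaluate_case

    pre_cfg = pre_cfg if pre_cfg is not None else PreprocessConfig()
    rows = []
    for n in grid.n_slices_values:
        pre_n = replace(pre_cfg, n_slices=n)
        train_n = replace(train_cfg, n_slices=n)
        model = RISUNet(replace(model_cfg, n_slices=n), seed=train_cfg.seed)
        train_data, val_data = [], []
        for case in cases:
            if case.split == "test":
                continue
            pairs = preprocess_case(case.volume, case.tumor, pre_n)
            (train_data if case.split == "train" else val_data).extend(pairs)
        train(model, train_data, val_data, train_n)
        reports = [
            evaluate_case(case.tumor,
                          predict_volume(model, case.volume, pre_n,
                                         batch_size=train_cfg.batch_size),
                          spacing=case.volume.spacing, case_id=case.case_id)
            for case in cases if case.split == "test"
        ]
        frame = pd.DataFrame([r.as_dict() for r in reports])
        rows.append({
            "n_slices": n,
            "dpc": frame["dpc"].mean(),
            "voe": frame["voe"].mean(),
            "ravd": frame["ravd"].astype(float).mean(skipna=True),
            "assd": frame["assd"].astype(float).mean(skipna=True),
            "rmsd": frame["rmsd"].astype(float).mean(skipna=True),
        })
    return pd.DataFrame(rows)
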