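"""CT preprocessing: from raw HU volumes to normalized 2.5D slice stacks.

The pipeline mirrors the standard recipe for liver-tumor CT segmentation:
clamp intensities to a soft-tissue HU window, center-crop each axial slice
to trim air background, histogram-equalize to stretch the low soft-tissue
contrast, scale to [0, 1], keep only slices that contain tumor (training
only), and stack each retained slice with its ``n`` neighbors as channels —
zero planes stand in for neighbors that fall off the volume.

Conventions: volumes are (H, W, D) with slice index on the third axis,
0-based; stacks are channel-first (n, H', W'), the layout they are saved in
as ``.npy``.  The supervision target of a stack is the mask of its center
slice only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CTVolume:
    """A CT scan: (H, W, D) array in Hounsfield units + voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    volume_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"CT volume must be rank 3, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass
class MaskVolume:
    """Binary segmentation volume aligned voxel-for-voxel with a CTVolume."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"mask must be rank 3, got shape {data.shape}")
        unique = np.unique(data)
        if not np.isin(unique, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)


@dataclass
class SliceStack:
    """2.5D model input: ``n`` consecutive slices centered on one slice."""

    data: np.ndarray                # (n, H', W'), channel k = slice t + k - n//2
    center_index: int
    origin_volume_id: str = ""

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class PreprocessConfig:
    hu_lo: float = -200.0
    hu_hi: float = 200.0
    crop_size: int = 448
    n_slices: int = 3
    equalize: bool = True
    keep_only_tumor_slices: bool = True
    n_bins: int = 256               # histogram-equalization resolution

    def __post_init__(self):
        if self.hu_lo >= self.hu_hi:
            raise ValueError(f"hu_lo must be < hu_hi, got [{self.hu_lo}, {self.hu_hi}]")
        if self.n_slices < 1 or self.n_slices % 2 == 0:
            raise ValueError(f"n_slices must be odd >= 1, got {self.n_slices}")
        if self.crop_size < 1:
            raise ValueError("crop_size must be positive")


def window_hu(vol: CTVolume, lo: float, hi: float) -> CTVolume:
    """Clamp intensities to the HU window [lo, hi]."""
    if lo >= hi:
        raise ValueError(f"invalid HU window: lo={lo} >= hi={hi}")
    return CTVolume(np.clip(vol.data, lo, hi), vol.spacing, vol.volume_id)


def crop_bounds(size: int, crop: int) -> tuple:
    """Start/stop of a centered window; odd margins put the extra pixel on
    the high-index side."""
    lo = (size - crop) // 2
    return lo, lo + crop


def center_crop(slice_2d: np.ndarray, crop_size: int) -> np.ndarray:
    h, w = slice_2d.shape
    if crop_size > min(h, w):
        raise ValueError(
            f"crop_size {crop_size} exceeds slice dims {(h, w)}")
    r0, r1 = crop_bounds(h, crop_size)
    c0, c1 = crop_bounds(w, crop_size)
    return slice_2d[r0:r1, c0:c1]


def hist_equalize(slice_2d: np.ndarray, lo: float | None = None,
                  hi: float | None = None, n_bins: int = 256) -> np.ndarray:
    """Global histogram equalization over ``n_bins`` bins spanning [lo, hi].

    Each pixel is mapped to the empirical CDF of its bin, so the output is a
    monotone non-decreasing function of input rank with range in (0, 1].
    A constant image occupies a single bin and stays constant.
    """
    x = np.asarray(slice_2d, dtype=np.float64)
    if lo is None:
        lo = float(x.min())
    if hi is None:
        hi = float(x.max())
    if hi <= lo:                    # constant input: single occupied bin
        return np.ones_like(x)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    cdf = np.cumsum(counts) / x.size
    return cdf[idx]


def normalize01(slice_2d: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant slice maps to all zeros."""
    x = np.asarray(slice_2d, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def filter_tumor_slices(mask: MaskVolume) -> list:
    """Ascending indices of slices with at least one foreground voxel."""
    return np.flatnonzero(mask.data.any(axis=(0, 1))).tolist()


def build_stack(vol: CTVolume, t: int, n: int) -> SliceStack:
    """Stack the ``n`` slices centered on slice ``t`` as channels; slices
    beyond either end of the volume are zero-filled planes."""
    if n < 1 or n % 2 == 0:
        raise ValueError(f"n must be odd >= 1, got {n}")
    h, w, d = vol.data.shape
    if not 0 <= t < d:
        raise IndexError(f"center slice {t} out of range [0, {d})")
    stack = np.zeros((n, h, w), dtype=np.float64)
    for k in range(n):
        s = t + k - n // 2
        if 0 <= s < d:
            stack[k] = vol.data[:, :, s]
    return SliceStack(stack, center_index=t, origin_volume_id=vol.volume_id)


def preprocess_volume(vol: CTVolume, cfg: PreprocessConfig) -> CTVolume:
    """window -> per-slice crop -> equalize -> normalize; returns the
    processed (crop, crop, D) volume."""
    windowed = window_hu(vol, cfg.hu_lo, cfg.hu_hi)
    d = vol.n_slices
    out = np.empty((cfg.crop_size, cfg.crop_size, d), dtype=np.float64)
    for t in range(d):
        sl = center_crop(windowed.data[:, :, t], cfg.crop_size)
        if cfg.equalize:
            sl = hist_equalize(sl, cfg.hu_lo, cfg.hu_hi, cfg.n_bins)
        out[:, :, t] = normalize01(sl)
    return CTVolume(out, vol.spacing, vol.volume_id)


def crop_mask(mask: MaskVolume, crop_size: int) -> MaskVolume:
    r0, r1 = crop_bounds(mask.data.shape[0], crop_size)
    c0, c1 = crop_bounds(mask.data.shape[1], crop_size)
    return MaskVolume(mask.data[r0:r1, c0:c1, :], mask.spacing)


def preprocess_case(vol: CTVolume, mask: MaskVolume,
                    cfg: PreprocessConfig) -> list:
    """Full training-data pipeline for one case.

    Returns a list of ``(SliceStack, center_slice_mask)`` pairs, one per
    retained center slice (all slices, or only tumor-bearing ones when
    ``cfg.keep_only_tumor_slices``).  At the defaults each stack has shape
    (3, 448, 448).
    """
    if vol.data.shape != mask.data.shape:
        raise ValueError(
            f"volume/mask shapes differ: {vol.data.shape} vs {mask.data.shape}")
    processed = preprocess_volume(vol, cfg)
    cropped_mask = crop_mask(mask, cfg.crop_size)
    if cfg.keep_only_tumor_slices:
        centers = filter_tumor_slices(cropped_mask)
    else:
        centers = list(range(vol.n_slices))
    return [
        (build_stack(processed, t, cfg.n_slices), cropped_mask.data[:, :, t])
        for t in centers
    ]
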