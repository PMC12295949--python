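"""Volumetric segmentation metrics.

Five per-case metrics, with ground truth A and prediction B:

* DPC  — Dice per case, ``2|A∩B| / (|A|+|B|)``
* VOE  — volumetric overlap error, ``1 - |A∩B| / |A∪B|`` (1 - Jaccard)
* RAVD — relative absolute volume difference, ``||B|-|A|| / |A|``
* ASSD — average symmetric surface distance in mm
* RMSD — root-mean-square symmetric surface distance in mm

Surface voxels are foreground voxels with at least one background
6-neighbor, the volume boundary counting as background; distances are
Euclidean in millimeters using the per-axis voxel spacing, evaluated with an
anisotropic distance transform.  Empty-mask conventions: DPC(∅,∅)=1,
VOE(∅,∅)=0; RAVD needs a nonempty reference; the surface metrics need both
masks nonempty and otherwise raise :class:`UndefinedMetricError` (case-level
evaluation reports them as missing instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import MaskVolume


class UndefinedMetricError(ValueError):
    """A metric's preconditions (nonempty masks) are not met."""


@dataclass
class SurfaceSet:
    """Surface voxels of a binary volume, in voxel and mm coordinates."""

    voxels: np.ndarray              # (K, 3) integer voxel indices
    coords_mm: np.ndarray           # (K, 3) spacing-scaled coordinates
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.voxels)


@dataclass
class MetricsReport:
    """Per-case metric values; surface metrics are None when undefined."""

    dpc: float
    voe: float
    ravd: float | None
    assd: float | None
    rmsd: float | None
    case_id: str = ""

    def as_dict(self) -> dict:
        return {"case_id": self.case_id, "dpc": self.dpc, "voe": self.voe,
                "ravd": self.ravd, "assd": self.assd, "rmsd": self.rmsd}


def _as_bool(mask) -> np.ndarray:
    data = mask.data if isinstance(mask, MaskVolume) else np.asarray(mask)
    return data.astype(bool)


def _aligned(a, b):
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def dpc(a, b) -> float:
    """Dice per case; two empty masks count as perfect agreement."""
    a, b = _aligned(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def voe(a, b) -> float:
    """Volumetric overlap error (1 - Jaccard); empty union gives 0."""
    a, b = _aligned(a, b)
    union = int((a | b).sum())
    if union == 0:
        return 0.0
    return 1.0 - int((a & b).sum()) / union


def ravd(a, b) -> float:
    """Relative absolute volume difference, ``||B|-|A||/|A|``; the first
    argument is the reference and must be nonempty."""
    a, b = _aligned(a, b)
    na = int(a.sum())
    if na == 0:
        raise UndefinedMetricError("RAVD is undefined for an empty reference mask")
    return abs(int(b.sum()) - na) / na


_STRUCT6 = ndimage.generate_binary_structure(3, 1)   # 6-connectivity


def _surface_mask(mask: np.ndarray) -> np.ndarray:
    # border_value=0: voxels on the volume boundary face background
    return mask & ~ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)


def extract_surface(mask, spacing=(1.0, 1.0, 1.0), source_id: str = "") -> SurfaceSet:
    """Surface voxels (6-connectivity, boundary-as-background) with
    mm-scaled coordinates."""
    m = _as_bool(mask)
    voxels = np.argwhere(_surface_mask(m))
    coords = voxels * np.asarray(spacing, dtype=np.float64)
    return SurfaceSet(voxels=voxels, coords_mm=coords, source_id=source_id)


def _surface_distances(a: np.ndarray, b: np.ndarray, spacing) -> tuple:
    """Nearest-surface distances in mm: from each S(A) voxel to S(B), and
    from each S(B) voxel to S(A)."""
    sa, sb = _surface_mask(a), _surface_mask(b)
    dt_to_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return dt_to_b[sa], dt_to_a[sb]


def _check_nonempty(a, b, name):
    if not a.any() or not b.any():
        raise UndefinedMetricError(f"{name} is undefined when either mask is empty")


def assd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm."""
    a, b = _aligned(a, b)
    _check_nonempty(a, b, "ASSD")
    d_ab, d_ba = _surface_distances(a, b, spacing)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def rmsd(a, b, spacing=(1.0, 1.0, 1.0)) -> float:
    """Root-mean-square symmetric surface distance in mm."""
    a, b = _aligned(a, b)
    _check_nonempty(a, b, "RMSD")
    d_ab, d_ba = _surface_distances(a, b, spacing)
    return float(np.sqrt((np.square(d_ab).sum() + np.square(d_ba).sum())
                         / (d_ab.size + d_ba.size)))


def evaluate_case(gt, pred, spacing=(1.0, 1.0, 1.0), case_id: str = "") -> MetricsReport:
    """All five metrics for one case.  DPC/VOE/ASSD/RMSD are symmetric in
    their arguments; RAVD is directional (ground truth first).  Metrics
    whose preconditions fail are reported as None."""
    gt_b, pred_b = _aligned(gt, pred)
    try:
        ravd_val = ravd(gt_b, pred_b)
    except UndefinedMetricError:
        ravd_val = None
    try:
        assd_val = assd(gt_b, pred_b, spacing)
        rmsd_val = rmsd(gt_b, pred_b, spacing)
    except UndefinedMetricError:
        assd_val = rmsd_val = None
    return MetricsReport(dpc=dpc(gt_b, pred_b), voe=voe(gt_b, pred_b),
                         ravd=ravd_val, assd=assd_val, rmsd=rmsd_val,
                         case_id=case_id)


def summarize(reports: list) -> "pandas.DataFrame":
    """Per-case table plus mean/std rows (missing values excluded)."""
    import pandas as pd

    frame = pd.DataFrame([r.as_dict() for r in reports])
    numeric = frame[["dpc", "voe", "ravd", "assd", "rmsd"]].astype(float)
    mean = numeric.mean(skipna=True)
    std = numeric.std(skipna=True)
    frame = pd.concat([
        frame,
        pd.DataFrame([{"case_id": "mean", **mean.to_dict()},
                      {"case_id": "std", **std.to_dict()}]),
    ], ignore_index=True)
    return frame
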