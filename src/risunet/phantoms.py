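"""Seeded synthetic CT phantoms with liver and tumor masks.

Each phantom emulates the data regime of low-contrast abdominal CT: a
smoothly deformed ellipsoidal "liver" sits in a darker background, and one
or more spherical "tumors" are embedded fully inside it with a mean
intensity only slightly below the liver parenchyma (15 HU at the defaults,
comparable to the soft-tissue contrast that makes real liver lesions hard).
Per-region voxel intensities are drawn independently, lightly Gaussian
smoothed (partial-volume blur), and overlaid with additive noise.

The generator exists so that every stage of the pipeline — preprocessing,
training, inference, evaluation — can be exercised end-to-end without any
external dataset.  It makes no claim of anatomical fidelity: no vessels, no
neighboring organs, no acquisition artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import CTVolume, MaskVolume


class PhantomGeometryError(ValueError):
    """The configured tumor geometry cannot be placed inside the liver."""


@dataclass
class PhantomConfig:
    """Geometry and intensity model of one phantom volume.

    HU values are plausible for contrast CT (background soft tissue ~ -100,
    liver parenchyma ~ 60, hypodense lesion ~ 45) and are configurable; the
    liver-tumor contrast can be narrowed to probe harder regimes.
    """

    shape: tuple = (64, 64, 24)
    spacing: tuple = (1.0, 1.0, 2.5)            # mm; coarser axially, like CT
    liver_semiaxes: tuple = ((16.0, 24.0), (16.0, 24.0), (7.0, 10.0))  # voxels
    deform_amplitude: float = 0.15              # fraction of the implicit radius
    n_tumors: tuple = (1, 3)
    tumor_radius: tuple = (3.0, 6.0)            # voxels
    background_hu: tuple = (-100.0, 20.0)       # (mean, sd)
    liver_hu: tuple = (60.0, 10.0)
    tumor_hu: tuple = (45.0, 10.0)
    noise_sd: float = 5.0
    smooth_sigma: float = 1.0                   # partial-volume blur, voxels
    max_placement_tries: int = 200

    def __post_init__(self):
        if any(s < 32 for s in self.shape[:2]):
            raise ValueError(f"in-plane dims must be >= 32, got {self.shape}")
        if self.tumor_radius[0] > min(hi for _, hi in self.liver_semiaxes):
            raise ValueError("tumor radii must be smaller than the liver semi-axes")


def _liver_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    h, w, d = cfg.shape
    axes = np.array([rng.uniform(lo, hi) for lo, hi in cfg.liver_semiaxes])
    center = np.array([h / 2, w / 2, d / 2]) + rng.uniform(-2, 2, size=3)
    grid = np.indices(cfg.shape).astype(np.float64)
    radial = sum(((grid[i] - center[i]) / axes[i]) ** 2 for i in range(3))
    # smooth multiplicative warp of the implicit surface
    warp = ndimage.gaussian_filter(rng.standard_normal(cfg.shape), sigma=6.0)
    warp *= cfg.deform_amplitude / max(np.abs(warp).max(), 1e-9)
    return radial <= 1.0 + warp


def _place_tumors(liver: np.ndarray, cfg: PhantomConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Spheres fully inside the liver; rejection-sample centers against the
    liver's interior distance map."""
    n_tumors = int(rng.integers(cfg.n_tumors[0], cfg.n_tumors[1] + 1))
    depth = ndimage.distance_transform_edt(liver)      # voxel distance to liver edge
    grid = np.indices(cfg.shape).astype(np.float64)
    tumors = np.zeros(cfg.shape, dtype=bool)
    interior = np.argwhere(depth > cfg.tumor_radius[0] + 1.0)
    if len(interior) == 0:
        raise PhantomGeometryError(
            "liver too small for the configured minimum tumor radius")
    for _ in range(n_tumors):
        for _ in range(cfg.max_placement_tries):
            center = interior[rng.integers(len(interior))]
            radius = rng.uniform(*cfg.tumor_radius)
            if depth[tuple(center)] > radius + 1.0:
                dist2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
                tumors |= dist2 <= radius ** 2
                break
        else:
            raise PhantomGeometryError(
                f"could not place a tumor of radius in {cfg.tumor_radius} "
                f"inside the liver after {cfg.max_placement_tries} tries")
    return tumors


def generate_phantom(cfg: PhantomConfig | None = None, seed: int = 0,
                     case_id: str = "") -> tuple:
    """One phantom: ``(CTVolume, liver MaskVolume, tumor MaskVolume)``.

    Deterministic in ``seed``; the tumor mask is a subset of the liver mask
    by construction.
    """
    cfg = cfg if cfg is not None else PhantomConfig()
    rng = np.random.default_rng(seed)
    liver = _liver_mask(cfg, rng)
    tumors = _place_tumors(liver, cfg, rng)

    image = rng.normal(*cfg.background_hu, size=cfg.shape)
    image[liver] = rng.normal(*cfg.liver_hu, size=int(liver.sum()))
    image[tumors] = rng.normal(*cfg.tumor_hu, size=int(tumors.sum()))
    image = ndimage.gaussian_filter(image, sigma=cfg.smooth_sigma)
    image += rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    vol = CTVolume(image, cfg.spacing, volume_id=case_id)
    return (vol,
            MaskVolume(liver.astype(np.uint8), cfg.spacing),
            MaskVolume(tumors.astype(np.uint8), cfg.spacing))


@dataclass
class PhantomCase:
    case_id: str
    seed: int
    split: str
    volume: CTVolume
    liver: MaskVolume
    tumor: MaskVolume


def case_seed(master_seed: int, index: int) -> int:
    """Per-case stream seed derived from (master seed, case index); each
    case is independently reproducible."""
    return int((master_seed * 1_000_003 + 7919 * index + 1) % (2 ** 31))


def split_counts(n_cases: int, fractions) -> list:
    """Largest-remainder allocation of ``n_cases`` across normalized
    fractions (so 8:2:2 over 12 cases gives 8/2/2)."""
    fractions = np.asarray(fractions, dtype=np.float64)
    if fractions.sum() <= 0:
        raise ValueError("split fractions must have a positive sum")
    fractions = fractions / fractions.sum()
    ideal = fractions * n_cases
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: n_cases - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_dataset(n_cases: int, cfg: PhantomConfig | None = None,
                     fractions=(8, 2, 2), master_seed: int = 39) -> tuple:
    """Generate ``n_cases`` phantoms and split them into train/val/test.

    Returns ``(cases, manifest)``: the cases carry their volumes in memory;
    the manifest records per-case seeds and the split assignment so any
    case can be regenerated in isolation.
    """
    split_names = ("train", "val", "test")
    if n_cases < len(split_names):
        raise ValueError(f"need at least {len(split_names)} cases, got {n_cases}")
    counts = split_counts(n_cases, fractions)
    rng = np.random.default_rng(master_seed)
    order = rng.permutation(n_cases)
    assignment = {}
    cursor = 0
    for name, count in zip(split_names, counts):
        for idx in order[cursor:cursor + count]:
            assignment[int(idx)] = name
        cursor += count

    cases = []
    for index in range(n_cases):
        cid = f"case_{index:03d}"
        seed = case_seed(master_seed, index)
        vol, liver, tumor = generate_phantom(cfg, seed=seed, case_id=cid)
        cases.append(PhantomCase(case_id=cid, seed=seed,
                                 split=assignment[index],
                                 volume=vol, liver=liver, tumor=tumor))
    manifest = {
        "master_seed": master_seed,
        "fractions": list(np.asarray(fractions, dtype=float)),
        "cases": [{"case_id": c.case_id, "seed": c.seed, "split": c.split}
                  for c in cases],
    }
    return cases, manifest
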