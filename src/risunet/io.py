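"""NIfTI and stack I/O.

Volumes and masks travel as NIfTI (``.nii``/``.nii.gz``) with voxel spacing
taken from the header zooms; preprocessed 2.5D stacks are written as
``.npy`` arrays of shape (n, crop, crop) with a sidecar JSON index mapping
each file to its case and center slice.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .preprocess import CTVolume, MaskVolume


def load_volume(path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(data, spacing, volume_id=Path(path).name.split(".")[0])


def load_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0.5
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MaskVolume(data.astype(np.uint8), spacing)


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(vol: CTVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.spacing)),
             str(path))


def save_mask(mask: MaskVolume, path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing)),
             str(path))


def save_stacks(pairs: list, out_dir, case_id: str) -> list:
    """Write (stack, mask) pairs as npy files plus a JSON index.

    Returns the index entries; masks are saved alongside stacks so the
    training CLI can reload them without the original volumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for stack, mask in pairs:
        stem = f"{case_id}_t{stack.center_index:04d}"
        np.save(out_dir / f"{stem}.npy", stack.data.astype(np.float32))
        np.save(out_dir / f"{stem}_mask.npy", mask.astype(np.uint8))
        entries.append({"case_id": case_id, "center_slice": int(stack.center_index),
                        "n_slices": int(stack.n), "stack": f"{stem}.npy",
                        "mask": f"{stem}_mask.npy"})
    index_path = out_dir / "index.json"
    existing = []
    if index_path.exists():
        existing = json.loads(index_path.read_text())
    index_path.write_text(json.dumps(existing + entries, indent=1))
    return entries


def load_stacks(stack_dir) -> list:
    """Reload (stack, mask) training pairs from a stack directory."""
    stack_dir = Path(stack_dir)
    index = json.loads((stack_dir / "index.json").read_text())
    return [
        (np.load(stack_dir / e["stack"]).astype(np.float64),
         np.load(stack_dir / e["mask"]))
        for e in index
    ]
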