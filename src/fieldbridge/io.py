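"""Reading and writing slice stacks.

NIfTI-1 (.nii / .nii.gz) is the canonical on-disk format, with the slice axis
as the third array axis (axial convention) and pixel spacing carried in the
header zooms.  Acquisition tags that NIfTI has no standard slot for
(subject id, field strength, vendor, repeat index) travel in a JSON sidecar
next to the volume.  2-D fixtures may alternatively be stored as a directory
of 8-bit PNG slices with the same sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .types import SliceStack

try:  # imageio is only needed for the PNG path
    import imageio.v3 as iio
except ImportError:  # pragma: no cover
    iio = None

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path / "stack.json" if path.is_dir() or not path.suffix else path.with_suffix(".json")


def write_volume(stack: SliceStack, path: PathLike) -> Path:
    """Write a stack as NIfTI (.nii/.nii.gz) or a PNG slice directory."""
    path = Path(path)
    meta = {
        "subject_id": stack.subject_id,
        "field_strength": stack.field_strength,
        "vendor": stack.vendor,
        "repeat_index": stack.repeat_index,
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
    }
    if path.name.endswith((".nii", ".nii.gz")):
        # (H, W, n_slices) with spacing in the zooms
        data = np.transpose(stack.slices, (1, 2, 0))
        affine = np.diag(
            [stack.pixel_spacing_mm[0], stack.pixel_spacing_mm[1], 1.0, 1.0]
        )
        img = nib.Nifti1Image(data.astype(np.float64), affine)
        img.header.set_zooms((*stack.pixel_spacing_mm, 1.0))
        path.parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(path))
    else:
        if iio is None:  # pragma: no cover
            raise RuntimeError("imageio is required for PNG stacks")
        path.mkdir(parents=True, exist_ok=True)
        for z, s in enumerate(stack.slices):
            arr = np.floor(255 * np.clip(s, 0, 1) + 0.5).astype(np.uint8)
            iio.imwrite(path / f"slice_{z:03d}.png", arr)
        meta["format"] = "png8"
    sidecar = _sidecar(path)
    sidecar.parent.mkdir(parents=True, exist_ok=True)
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: PathLike) -> SliceStack:
    """Read a stack written by :func:`write_volume`."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 2:
            data = data[:, :, None]
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 2-D/3-D volume, got {data.ndim}-D")
        slices = np.transpose(data, (2, 0, 1))
        zooms = img.header.get_zooms()[:2]
        spacing = tuple(float(z) for z in zooms)
    elif path.is_dir():
        if iio is None:  # pragma: no cover
            raise RuntimeError("imageio is required for PNG stacks")
        files = sorted(path.glob("slice_*.png"))
        if not files:
            raise ValueError(f"{path}: no slice_*.png files found")
        slices = np.stack([iio.imread(f).astype(float) / 255.0 for f in files])
        spacing = tuple(meta.get("pixel_spacing_mm", (1.0, 1.0)))
    else:
        raise ValueError(f"{path}: unrecognized volume format")
    return SliceStack(
        subject_id=meta.get("subject_id", path.stem.split(".")[0]),
        slices=slices,
        pixel_spacing_mm=tuple(spacing),
        field_strength=meta.get("field_strength", "high"),
        vendor=meta.get("vendor", "A"),
        repeat_index=int(meta.get("repeat_index", 0)),
    )
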