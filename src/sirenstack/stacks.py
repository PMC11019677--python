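"""Core array containers and multi-page TIFF I/O.

Package-wide conventions: stacks are indexed ``(z, y, x)``, 0-based, with z
as the TIFF page axis; intensities are carried as float and never rescaled
on read (percentile normalization is the only sanctioned rescale, and it is
explicit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "RepetitionSet", "read_stack", "write_stack",
           "read_repetitions", "write_repetitions"]


@dataclass
class ImageStack:
    """A 3-D grayscale voxel array (z, y, x) with voxel-size metadata."""

    data: np.ndarray
    voxel_size_um: tuple = (1.0, 1.0, 1.0)
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack requires 3 dims (z,y,x), got {self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("ImageStack requires z >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageStack data must be finite")

    @property
    def shape(self):
        return self.data.shape

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.voxel_size_um, self.provenance)


@dataclass
class RepetitionSet:
    """R repeated acquisitions of one stack: array (repetition, z, y, x)."""

    data: np.ndarray
    voxel_size_um: tuple = (1.0, 1.0, 1.0)
    provenance: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("RepetitionSet requires 4 dims (r,z,y,x)")
        if self.data.shape[0] < 2:
            raise ValueError("RepetitionSet requires >= 2 repetitions")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RepetitionSet data must be finite")

    @property
    def n_reps(self) -> int:
        return self.data.shape[0]

    @property
    def stack_shape(self):
        return self.data.shape[1:]

    def repetition(self, r: int) -> ImageStack:
        return ImageStack(self.data[r], self.voxel_size_um,
                          f"{self.provenance}[rep {r}]")


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def read_stack(path) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack (page order = z).

    Integer pixel values are converted to float without rescaling: a 16-bit
    65535 stays 65535.0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected grayscale pages, got array of ndim {arr.ndim}")
    voxel = (1.0, 1.0, 1.0)
    prov = str(path)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel = tuple(meta.get("voxel_size_um", voxel))
        prov = meta.get("provenance", prov)
    return ImageStack(arr.astype(np.float64), voxel, prov)


def write_stack(stack: ImageStack, path, dtype_policy: str = "float32") -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar.

    dtype_policy 'float32' (default) is lossless for float32-representable
    data; 'uint16' scales data in [0, 1] by 65535 and refuses negative
    values rather than clipping silently.
    """
    path = Path(path)
    if dtype_policy == "float32":
        arr = stack.data.astype(np.float32)
        meta = {"dtype_policy": "float32"}
    elif dtype_policy == "uint16":
        if stack.data.min() < 0:
            raise ValueError("uint16 policy forbids negative values (no silent clip)")
        if stack.data.max() > 1.0:
            raise ValueError("uint16 policy expects data in [0, 1]")
        arr = np.round(stack.data * 65535.0).astype(np.uint16)
        meta = {"dtype_policy": "uint16", "scale": 65535.0}
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    tifffile.imwrite(str(path), arr, photometric="minisblack")
    meta["voxel_size_um"] = list(stack.voxel_size_um)
    meta["provenance"] = stack.provenance
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_repetitions(paths: Sequence) -> RepetitionSet:
    """Stack per-repetition TIFFs into a RepetitionSet (order as given)."""
    stacks = [read_stack(p) for p in paths]
    shapes = {s.shape for s in stacks}
    if len(shapes) > 1:
        raise ValueError(f"repetition shape mismatch: {sorted(shapes)}")
    data = np.stack([s.data for s in stacks], axis=0)
    return RepetitionSet(data, stacks[0].voxel_size_um,
                         "; ".join(s.provenance for s in stacks))


def write_repetitions(reps: RepetitionSet, directory, prefix: str = "rep") -> list:
    """Write each repetition as <prefix>_<r>.tif; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in range(reps.n_reps):
        p = directory / f"{prefix}_{r}.tif"
        write_stack(reps.repetition(r), p)
        paths.append(p)
    return paths
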