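"""Percentile normalization, coordinate grids, plane selection, subsampling.

The percentile normalizer rescales intensities by the 2nd and 99.9th
percentiles:

    y_norm = (y - P2) / (P99.9 - P2 + eps),   eps = 1e-20

with no clipping, so values below P2 map below 0 and values above P99.9 map
above 1.  Coordinate grids map voxel centers to [-1, 1] per axis; z
coordinates are always computed against the FULL original z extent so that
acquired and omitted planes share one coordinate frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stacks import ImageStack

__all__ = ["NormalizationParams", "CoordinateSample", "PlaneSelection",
           "fit_normalizer", "apply_normalizer", "invert_normalizer",
           "make_grid", "select_planes", "subsample_pixels"]

EPSILON = 1e-20


@dataclass
class NormalizationParams:
    """Fitted percentile-normalizer parameters (P2, P99.9, eps)."""

    p_low_value: float
    p_high_value: float
    epsilon: float = EPSILON

    def __post_init__(self):
        if self.p_high_value < self.p_low_value:
            raise ValueError("p_high_value must be >= p_low_value")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"p_low_value": self.p_low_value,
                       "p_high_value": self.p_high_value,
                       "epsilon": self.epsilon}, fh)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class CoordinateSample:
    """Paired (normalized coordinates, intensity targets) for a SIREN fit."""

    coords: np.ndarray        # (N, 3) in [-1, 1] per axis
    targets: np.ndarray       # (N, 1)
    grid_shape: tuple         # originating (z, y, x)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.float32).reshape(-1, 1)
        if len(self.coords) != len(self.targets):
            raise ValueError("coords/targets length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PlaneSelection:
    """Train/held-out z-plane split for the omit-every-n protocol.

    ``held_out_plane_indices`` are the evaluated planes, all of which lie
    strictly between two training planes; trailing planes past the last
    training plane would require extrapolation and are excluded from
    evaluation (``trailing_plane_indices``).
    """

    train_plane_indices: np.ndarray
    held_out_plane_indices: np.ndarray
    trailing_plane_indices: np.ndarray
    skip: int
    n_planes: int


def _stack_values(stack) -> np.ndarray:
    if isinstance(stack, ImageStack):
        return stack.data
    return np.asarray(stack, dtype=np.float64)


def fit_normalizer(stack) -> NormalizationParams:
    """Fit P2/P99.9 over all voxels (linear-interpolated percentiles).

    Accepts an ImageStack, a RepetitionSet's 4-D array, or any ndarray; for
    repetition sets the percentiles pool over all repetitions so every
    repetition is normalized identically.
    """
    values = _stack_values(getattr(stack, "data", stack))
    if values.size == 0:
        raise ValueError("cannot fit normalizer on empty stack")
    p2, p999 = np.percentile(values, [2.0, 99.9])
    return NormalizationParams(float(p2), float(p999))


def apply_normalizer(stack, params: NormalizationParams):
    """y -> (y - P2) / (P99.9 - P2 + eps); preserves input container type."""
    scale = params.p_high_value - params.p_low_value + params.epsilon
    if isinstance(stack, ImageStack):
        return ImageStack((stack.data - params.p_low_value) / scale,
                          stack.voxel_size_um, stack.provenance + " [normalized]")
    return (np.asarray(stack, dtype=np.float64) - params.p_low_value) / scale


def invert_normalizer(stack, params: NormalizationParams):
    """Inverse of apply_normalizer: back to acquisition units."""
    scale = params.p_high_value - params.p_low_value + params.epsilon
    if isinstance(stack, ImageStack):
        return ImageStack(stack.data * scale + params.p_low_value,
                          stack.voxel_size_um, stack.provenance + " [denormalized]")
    return np.asarray(stack, dtype=np.float64) * scale + params.p_low_value


def _axis_coords(n: int) -> np.ndarray:
    if n == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n)


def _z_axis_coords(z_indices: np.ndarray, n_z_total: int) -> np.ndarray:
    if n_z_total == 1:
        return np.zeros(len(z_indices), dtype=float)
    return np.asarray(z_indices, dtype=float) / (n_z_total - 1) * 2.0 - 1.0


def make_grid(grid_shape, z_indices: Optional[Sequence] = None,
              n_z_total: Optional[int] = None) -> np.ndarray:
    """Normalized (N, 3) coordinates for the voxel grid, z-major order.

    grid_shape: (z, y, x) of the grid to enumerate.  If ``z_indices`` is
    given, those (possibly fractional) plane indices are mapped against a
    full stack of ``n_z_total`` planes, so training and omitted planes share
    one frame; len(z_indices) must equal grid_shape[0].
    """
    nz, ny, nx = grid_shape
    if min(nz, ny, nx) < 1:
        raise ValueError("all grid dims must be >= 1")
    if z_indices is None:
        zc = _axis_coords(nz)
    else:
        if n_z_total is None:
            raise ValueError("z_indices requires n_z_total")
        z_indices = np.asarray(z_indices, dtype=float)
        if len(z_indices) != nz:
            raise ValueError("len(z_indices) must equal grid_shape[0]")
        zc = _z_axis_coords(z_indices, n_z_total)
    yc = _axis_coords(ny)
    xc = _axis_coords(nx)
    zz, yy, xx = np.meshgrid(zc, yc, xc, indexing="ij")
    return np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1).astype(np.float32)


def stack_to_sample(stack: ImageStack, z_indices=None, n_z_total=None) -> CoordinateSample:
    """Flatten a stack into a CoordinateSample (grid coords + intensities)."""
    coords = make_grid(stack.shape, z_indices=z_indices, n_z_total=n_z_total)
    return CoordinateSample(coords, stack.data.ravel(), stack.shape)


def select_planes(n_planes: int, skip: int) -> PlaneSelection:
    """Training planes {0, skip+1, 2(skip+1), ...}; the rest are held out.

    Held-out planes after the last training plane are trailing (would need
    extrapolation) and are excluded from evaluation.
    """
    if skip < 0:
        raise ValueError("skip must be >= 0")
    if n_planes < skip + 2:
        raise ValueError(f"n_planes={n_planes} too small for skip={skip}")
    if skip > 7:
        import warnings
        warnings.warn(f"skip={skip} exceeds the evaluated range (1-7)")
    train = np.arange(0, n_planes, skip + 1)
    all_idx = np.arange(n_planes)
    held = np.setdiff1d(all_idx, train)
    last_train = train[-1]
    evaluated = held[held < last_train]
    trailing = held[held > last_train]
    return PlaneSelection(train, evaluated, trailing, skip, n_planes)


def subsample_pixels(sample: CoordinateSample, fraction: float,
                     seed: int) -> CoordinateSample:
    """Uniform random subset (without replacement) of round(fraction*N) pairs."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(sample)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    return CoordinateSample(sample.coords[idx], sample.targets[idx],
                            sample.grid_shape)
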