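"""Interplane prediction: the omit-every-n protocol.

A SIREN is fitted on every (skip+1)-th z-plane only, with z coordinates laid
out on the full-grid frame, then queried at the omitted planes.  Predictions
are compared to the true omitted planes with MSE/SSIM/PSNR (and the
Fourier-spectrum MSE).  Linear interpolation between the two flanking
training planes is the reference method.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .metrics import PlaneMetrics, plane_metrics
from .preprocessing import (CoordinateSample, NormalizationParams,
                            PlaneSelection, apply_normalizer, fit_normalizer,
                            invert_normalizer, make_grid, select_planes)
from .siren import Siren, SirenConfig, SirenFit
from .stacks import ImageStack

__all__ = ["InterplaneResult", "run_interplane", "linear_interpolate",
           "sweep_skips", "results_to_csv"]


@dataclass
class InterplaneResult:
    """Predicted held-out planes for one (stack, skip, method) run."""

    skip: int
    method: str                                  # siren | siren+denoiser | linear
    selection: PlaneSelection
    predicted_planes: Optional[ImageStack]       # held-out z only; None if empty
    metrics: Optional[PlaneMetrics]              # indexed by held-out planes
    fit_report: Optional[SirenFit] = None

    @property
    def held_out_indices(self) -> np.ndarray:
        return self.selection.held_out_plane_indices


def _fit_on_training_planes(stack_norm: ImageStack, selection: PlaneSelection,
                            siren_config: SirenConfig,
                            normalization: NormalizationParams):
    nz, ny, nx = stack_norm.shape
    train_idx = selection.train_plane_indices
    train_data = stack_norm.data[train_idx]
    coords = make_grid((len(train_idx), ny, nx), z_indices=train_idx,
                       n_z_total=nz)
    sample = CoordinateSample(coords, train_data.ravel(),
                              (len(train_idx), ny, nx))
    model = Siren(siren_config, normalization=normalization)
    report = model.fit(sample)
    return model, report


def run_interplane(stack: ImageStack, skip: int,
                   siren_config: Optional[SirenConfig] = None,
                   denoiser=None, max_planes: Optional[int] = 20
                   ) -> InterplaneResult:
    """Fit on training planes only; predict and score the omitted planes.

    The stack is percentile-normalized first; metrics are computed in
    acquisition units against the true omitted planes.  ``max_planes``
    restricts evaluation to the first N planes of deeper stacks (default
    20, i.e. 20 um at a 1-um z-step); pass None to use the whole stack.
    If ``denoiser`` is given, predictions additionally pass through it
    (in normalized space) and the method tag becomes 'siren+denoiser'.
    """
    siren_config = siren_config or SirenConfig()
    work = stack
    if max_planes is not None and stack.shape[0] > max_planes:
        work = ImageStack(stack.data[:max_planes], stack.voxel_size_um,
                          stack.provenance + f" [first {max_planes} planes]")
    nz, ny, nx = work.shape
    selection = select_planes(nz, skip)
    params = fit_normalizer(work)
    norm = apply_normalizer(work, params)

    if len(selection.held_out_plane_indices) == 0:
        return InterplaneResult(skip, "siren", selection, None, None)

    model, report = _fit_on_training_planes(norm, selection, siren_config, params)
    held = selection.held_out_plane_indices
    coords = make_grid((len(held), ny, nx), z_indices=held, n_z_total=nz)
    pred_norm = model.predict_grid(coords, (len(held), ny, nx),
                                  work.voxel_size_um)
    method = "siren"
    if denoiser is not None:
        from .denoiser import apply_denoiser
        pred_norm = apply_denoiser(denoiser, pred_norm)
        method = "siren+denoiser"
    pred = invert_normalizer(pred_norm, params)
    pred.provenance = f"interplane {method} skip={skip}"
    truth = work.data[held]
    metrics = plane_metrics(pred.data, truth, plane_indices=held)
    return InterplaneResult(skip, method, selection, pred, metrics, report)


def linear_interpolate(stack: ImageStack, selection: PlaneSelection,
                       max_planes: Optional[int] = None) -> InterplaneResult:
    """Reference method: linear interpolation between flanking training planes.

    The k-th omitted plane between training planes A (below) and B (above),
    k = 1..skip, is (1 - k/(skip+1)) * A + (k/(skip+1)) * B.
    """
    work = stack
    if max_planes is not None and stack.shape[0] > max_planes:
        work = ImageStack(stack.data[:max_planes], stack.voxel_size_um,
                          stack.provenance)
    held = selection.held_out_plane_indices
    if len(held) == 0:
        return InterplaneResult(selection.skip, "linear", selection, None, None)
    train = selection.train_plane_indices
    step = selection.skip + 1
    preds = np.empty((len(held), *work.shape[1:]), dtype=np.float64)
    for i, z in enumerate(held):
        below = train[train < z].max()
        above = train[train > z].min()
        k = z - below
        w = k / step
        preds[i] = (1.0 - w) * work.data[below] + w * work.data[above]
    pred = ImageStack(preds, work.voxel_size_um,
                      f"linear interpolation skip={selection.skip}")
    truth = work.data[held]
    metrics = plane_metrics(preds, truth, plane_indices=held)
    return InterplaneResult(selection.skip, "linear", selection, pred, metrics)


def sweep_skips(stack: ImageStack, skips: Sequence[int] = range(1, 8),
                siren_config: Optional[SirenConfig] = None, denoiser=None,
                methods: Sequence[str] = ("siren", "linear"),
                max_planes: Optional[int] = 20) -> List[InterplaneResult]:
    """One InterplaneResult per (skip, method); fresh SIREN init per run."""
    results: List[InterplaneResult] = []
    for skip in skips:
        if "siren" in methods:
            results.append(run_interplane(stack, skip, siren_config,
                                          denoiser=None, max_planes=max_planes))
        if ("siren+denoiser" in methods or (denoiser is not None
                                            and "siren" in methods)):
            results.append(run_interplane(stack, skip, siren_config,
                                          denoiser=denoiser,
                                          max_planes=max_planes))
        if "linear" in methods:
            nz = stack.shape[0] if max_planes is None else min(stack.shape[0],
                                                               max_planes)
            selection = select_planes(nz, skip)
            results.append(linear_interpolate(stack, selection,
                                              max_planes=max_planes))
    return results


def composite_stack(stack: ImageStack, result: InterplaneResult,
                    max_planes: Optional[int] = 20) -> ImageStack:
    """Full stack with held-out planes replaced by the method's predictions.

    Training (and trailing) planes keep their acquired data; this is the
    stack a user would actually obtain from an omit-every-n acquisition,
    and the input to whole-stack evaluations such as spine recovery.
    """
    work = stack.data
    if max_planes is not None and stack.shape[0] > max_planes:
        work = work[:max_planes]
    out = work.copy()
    if result.predicted_planes is not None:
        out[result.held_out_indices] = result.predicted_planes.data
    return ImageStack(out, stack.voxel_size_um,
                      f"composite {result.method} skip={result.skip}")


def results_to_csv(results: Sequence[InterplaneResult], path) -> None:
    """Per-plane metric rows for the skip-sweep curves (one row per
    held-out plane per method); aggregates are mean over planes then
    mean +- sd per skip."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["skip", "method", "plane", "mse", "ssim", "psnr",
                         "fourier_mse"])
        for res in results:
            if res.metrics is None:
                continue
            m = res.metrics
            for i, z in enumerate(m.plane_indices):
                writer.writerow([res.skip, res.method, int(z),
                                 f"{m.mse[i]:.8g}", f"{m.ssim[i]:.8g}",
                                 f"{m.psnr[i]:.8g}", f"{m.fourier_mse[i]:.8g}"])
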