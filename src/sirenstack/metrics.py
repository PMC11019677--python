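"""Image-quality metrics and the phantom spine-recovery proxy.

MSE, PSNR and SSIM follow the standard full-reference definitions (SSIM via
scikit-image with a 7x7 Gaussian-weighted window, K1=0.01, K2=0.03).  The
Fourier-spectrum MSE compares per-plane 2-D DFT magnitude arrays, which is
translation-invariant by the shift theorem — it measures spectral content,
not spatial alignment.

Spine recovery is a phantom-ground-truth proxy: Laplacian-of-Gaussian blob
candidates above a percentile-derived intensity threshold are greedily
matched one-to-one to the true spine centers within a voxel radius.  It is
a geometric detection score on synthetic ground truth, not a trained
spine-segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.metrics import structural_similarity

from .stacks import ImageStack

__all__ = ["PlaneMetrics", "SpineRecoveryReport", "mse", "psnr", "ssim",
           "fourier_mse", "plane_metrics", "spine_recovery", "detect_blobs"]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, ImageStack) else np.asarray(x, dtype=np.float64)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _default_range(a: np.ndarray, b: np.ndarray) -> float:
    """Joint max-min of the pair; normalized-space images are unbounded."""
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    return float(hi - lo) if hi > lo else 1.0


def mse(a, b) -> float:
    a, b = _as_array(a), _as_array(b)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, data_range: Optional[float] = None) -> float:
    """10*log10(data_range^2 / mse); +inf for identical images."""
    a, b = _as_array(a), _as_array(b)
    _check_shapes(a, b)
    if data_range is None:
        data_range = _default_range(a, b)
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    err = np.mean((a - b) ** 2)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range ** 2 / err))


def ssim(a, b, data_range: Optional[float] = None) -> float:
    """Mean SSIM, 7x7 Gaussian-weighted window, K1=0.01, K2=0.03.

    2-D inputs are scored directly; 3-D stacks are averaged per plane.
    """
    a, b = _as_array(a), _as_array(b)
    _check_shapes(a, b)
    if data_range is None:
        data_range = _default_range(a, b)
    side = min(a.shape[-2:])
    win = min(7, side if side % 2 == 1 else side - 1)
    kwargs = dict(win_size=win, gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, K1=0.01, K2=0.03,
                  data_range=data_range)
    if a.ndim == 2:
        return float(structural_similarity(a, b, **kwargs))
    if a.ndim == 3:
        return float(np.mean([structural_similarity(a[z], b[z], **kwargs)
                              for z in range(a.shape[0])]))
    raise ValueError("ssim expects 2-D planes or 3-D stacks")


def fourier_mse(pred, ref) -> np.ndarray:
    """Per-plane MSE between 2-D DFT magnitude spectra.

    The spectrum is the linear magnitude |F| of the unshifted 2-D DFT.
    Returns one value per z-plane (a single value for 2-D inputs).
    """
    a, b = _as_array(pred), _as_array(ref)
    _check_shapes(a, b)
    if a.ndim == 2:
        a, b = a[None], b[None]
    out = np.empty(a.shape[0])
    for z in range(a.shape[0]):
        fa = np.abs(np.fft.fft2(a[z]))
        fb = np.abs(np.fft.fft2(b[z]))
        out[z] = np.mean((fa - fb) ** 2)
    return out


@dataclass
class PlaneMetrics:
    """Per-plane MSE/SSIM/PSNR/Fourier-MSE plus mean +- sd aggregates."""

    mse: np.ndarray
    ssim: np.ndarray
    psnr: np.ndarray
    fourier_mse: np.ndarray
    plane_indices: np.ndarray

    def aggregate(self) -> dict:
        out = {}
        for name in ("mse", "ssim", "psnr", "fourier_mse"):
            v = getattr(self, name)
            finite = v[np.isfinite(v)]
            out[name] = {"mean": float(np.mean(finite)) if len(finite) else float("nan"),
                         "sd": float(np.std(finite)) if len(finite) else float("nan")}
        return out


def plane_metrics(pred, ref, plane_indices=None,
                  data_range: Optional[float] = None) -> PlaneMetrics:
    """All metrics, computed per z-plane of a stack pair."""
    a, b = _as_array(pred), _as_array(ref)
    _check_shapes(a, b)
    if a.ndim == 2:
        a, b = a[None], b[None]
    nz = a.shape[0]
    if plane_indices is None:
        plane_indices = np.arange(nz)
    m = np.array([mse(a[z], b[z]) for z in range(nz)])
    s = np.array([ssim(a[z], b[z], data_range) for z in range(nz)])
    p = np.array([psnr(a[z], b[z], data_range) for z in range(nz)])
    f = fourier_mse(a, b)
    return PlaneMetrics(m, s, p, f, np.asarray(plane_indices))


# ------------------------------------------------------- spine recovery

@dataclass
class SpineRecoveryReport:
    """Greedy matching of detected blobs to true spine centers."""

    n_true_spines: int
    n_detections: int
    n_recovered: int
    recovery_fraction: float
    matches: List[Tuple[Tuple[int, int, int], Tuple[float, float, float], float]] \
        = field(default_factory=list)  # (true center, detection, distance)


def detect_blobs(stack, sigma: float = 0.8,
                 intensity_percentile: float = 98.0,
                 min_distance: int = 1) -> np.ndarray:
    """Laplacian-of-Gaussian local maxima above a percentile threshold.

    Returns (K, 3) candidate coordinates (z, y, x).  The threshold is set
    from the response volume's own percentiles, so detection adapts to the
    prediction's intensity scale.
    """
    vol = _as_array(stack)
    # -LoG: positive response at bright blobs of scale ~sigma
    resp = -ndimage.gaussian_laplace(vol, sigma=sigma)
    thr = np.percentile(resp, intensity_percentile)
    peaks = peak_local_max(resp, min_distance=min_distance,
                           threshold_abs=thr, exclude_border=False)
    return peaks


def spine_recovery(pred, truth, match_radius_vox: float = 3.0,
                   sigma: float = 0.8,
                   intensity_percentile: float = 98.0) -> SpineRecoveryReport:
    """Fraction of true spine centers recovered by blob detection on `pred`.

    Matching is greedy nearest-first and one-to-one within
    ``match_radius_vox``.  With zero true spines the recovery fraction is
    1.0 by convention (nothing to miss); detections are still reported.
    """
    centers = [tuple(int(v) for v in c) for c in truth.spine_centers]
    detections = detect_blobs(pred, sigma=sigma,
                              intensity_percentile=intensity_percentile)
    n_true = len(centers)
    if n_true == 0:
        return SpineRecoveryReport(0, len(detections), 0, 1.0, [])
    if len(detections) == 0:
        return SpineRecoveryReport(n_true, 0, 0, 0.0, [])

    det = detections.astype(float)
    ctr = np.asarray(centers, dtype=float)
    d = np.linalg.norm(ctr[:, None, :] - det[None, :, :], axis=2)
    matches = []
    used_true, used_det = set(), set()
    order = np.argsort(d, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > match_radius_vox:
            break
        if i in used_true or j in used_det:
            continue
        used_true.add(i)
        used_det.add(j)
        matches.append((centers[i], tuple(det[j]), float(d[i, j])))
    n_rec = len(matches)
    return SpineRecoveryReport(n_true, len(det), n_rec, n_rec / n_true, matches)
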