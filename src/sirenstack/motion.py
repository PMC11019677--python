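"""Unsupervised motion correction of repeated acquisitions with SIRENs.

Two training-set constructions from R repetitions of one stack:

* ``all``     — every repetition contributes its full coordinate grid with
  identical coordinates (repetition identity is NOT an input dimension), so
  the network sees R conflicting targets per coordinate and regresses their
  conditional mean; artifact suppression comes from the continuous field's
  spectral bias, not from averaging per se.
* ``sampled`` — one target per voxel, drawn uniformly from the R repetition
  values at that voxel; 1/R the training data, hence proportionally faster.

Baselines: voxelwise averaging (optionally restricted to artifact-free
repetitions per plane — on phantoms that mask comes from the injected
ArtifactRecords) and a small supervised 3-layer CNN trained on
(corrupt plane, clean plane) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._autodiff import Tensor, SGD
from .preprocessing import (CoordinateSample, NormalizationParams,
                            apply_normalizer, fit_normalizer,
                            invert_normalizer, make_grid)
from .siren import Siren, SirenConfig, SirenFit
from .stacks import ImageStack, RepetitionSet

__all__ = ["CorrectionConfig", "BaselineCnnConfig", "BaselineCnn",
           "build_training_set_all", "build_training_set_sampled",
           "correct_stack", "average_repetitions",
           "train_baseline_cnn", "apply_baseline_cnn"]


@dataclass
class CorrectionConfig:
    """Strategy + SIREN hyperparameters for one correction run."""

    strategy: str = "sampled"
    siren: SirenConfig = field(default_factory=SirenConfig)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("all_repetitions", "all", "random_sample",
                                 "sampled"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def canonical_strategy(self) -> str:
        return "all" if self.strategy in ("all", "all_repetitions") else "sampled"


def build_training_set_all(reps: RepetitionSet) -> CoordinateSample:
    """Stack every repetition's grid with identical coordinates.

    N = R * Z * Y * X pairs; the per-coordinate target multiset equals the
    R repetition values at that voxel.
    """
    r = reps.n_reps
    grid = make_grid(reps.stack_shape)
    coords = np.tile(grid, (r, 1))
    targets = reps.data.reshape(r, -1).reshape(-1)
    return CoordinateSample(coords, targets, reps.stack_shape)


def build_training_set_sampled(reps: RepetitionSet, seed: int = 0) -> CoordinateSample:
    """Per-voxel random choice among the R repetition values (N = Z*Y*X)."""
    r = reps.n_reps
    flat = reps.data.reshape(r, -1)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, r, size=flat.shape[1])
    targets = flat[pick, np.arange(flat.shape[1])]
    coords = make_grid(reps.stack_shape)
    return CoordinateSample(coords, targets, reps.stack_shape)


def correct_stack(reps: RepetitionSet, config: CorrectionConfig,
                  params: Optional[NormalizationParams] = None,
                  return_fit: bool = False):
    """Fit a SIREN on the chosen training set and predict the full grid.

    Normalization is fitted pooled over all repetitions (unless params are
    supplied), training happens in normalized space, and the returned stack
    is de-normalized back to acquisition units.
    """
    if params is None:
        params = fit_normalizer(reps.data)
    norm = RepetitionSet(apply_normalizer(reps.data, params),
                         reps.voxel_size_um, reps.provenance)
    if config.canonical_strategy == "all":
        sample = build_training_set_all(norm)
    else:
        sample = build_training_set_sampled(norm, seed=config.seed)
    model = Siren(config.siren, normalization=params)
    fit_report = model.fit(sample)
    grid = make_grid(reps.stack_shape)
    pred = model.predict_grid(grid, reps.stack_shape, reps.voxel_size_um)
    corrected = invert_normalizer(pred, params)
    corrected.provenance = (f"SIREN motion correction "
                            f"(strategy={config.canonical_strategy})")
    if return_fit:
        return corrected, fit_report
    return corrected


def average_repetitions(reps: RepetitionSet,
                        clean_mask: Optional[Sequence[Sequence[int]]] = None
                        ) -> ImageStack:
    """Voxelwise mean over repetitions.

    Without ``clean_mask`` this is the naive average of all repetitions.
    ``clean_mask[z]`` lists the repetition indices to include for plane z
    (each must be non-empty) — the reference construction that excludes
    artifact-afflicted repetitions plane by plane.
    """
    if clean_mask is None:
        return ImageStack(reps.data.mean(axis=0), reps.voxel_size_um,
                          "average of all repetitions")
    nz = reps.stack_shape[0]
    if len(clean_mask) != nz:
        raise ValueError("clean_mask must list included repetitions per plane")
    out = np.empty(reps.stack_shape, dtype=np.float64)
    for z, include in enumerate(clean_mask):
        include = list(include)
        if not include:
            raise ValueError(f"empty inclusion set for plane {z}")
        out[z] = reps.data[include, z].mean(axis=0)
    return ImageStack(out, reps.voxel_size_um, "average of clean repetitions")


def clean_mask_from_records(records, n_reps: int, n_planes: int):
    """Per-plane inclusion lists excluding (rep, plane) pairs with artifacts."""
    corrupted = {(rec.repetition_index, rec.plane_index) for rec in records}
    mask = []
    for z in range(n_planes):
        include = [r for r in range(n_reps) if (r, z) not in corrupted]
        mask.append(include if include else list(range(n_reps)))
    return mask


# ------------------------------------------------------- baseline CNN

@dataclass
class BaselineCnnConfig:
    """3-layer supervised artifact-correction CNN.

    64 and 64 filters with ReLU in the first two layers, one linear filter
    in the last; all kernels 5x5 with 'same' padding; SGD at lr 0.01 on MSE.
    """

    n_layers: int = 3
    filters: tuple = (64, 64, 1)
    kernel: int = 5
    learning_rate: float = 0.01
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.n_layers != len(self.filters):
            raise ValueError("filters must list one count per layer")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd ('same' padding)")


class BaselineCnn:
    """Weights + forward pass of the baseline correction CNN."""

    def __init__(self, config: BaselineCnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        chans = (1,) + config.filters
        self.weights, self.biases = [], []
        for i in range(config.n_layers):
            fan_in = chans[i] * k * k
            bound = np.sqrt(6.0 / fan_in)  # He-style uniform init
            w = rng.uniform(-bound, bound, size=(chans[i + 1], chans[i], k, k))
            self.weights.append(w.astype(np.float32))
            self.biases.append(np.zeros(chans[i + 1], dtype=np.float32))
        self.loss_trace: List[float] = []

    def _forward_graph(self, x: Tensor, params) -> Tensor:
        n = self.config.n_layers
        ws, bs = params[:n], params[n:]
        h = x
        for i in range(n):
            h = h.conv2d(ws[i], bs[i])
            if i < n - 1:
                h = h.relu()
        return h

    def forward(self, plane: np.ndarray) -> np.ndarray:
        x = np.asarray(plane, dtype=np.float32)[None, None]
        params = [Tensor(w) for w in self.weights] + \
                 [Tensor(b) for b in self.biases]
        return self._forward_graph(Tensor(x), params).data[0, 0].astype(np.float64)


def train_baseline_cnn(pairs: Sequence, config: Optional[BaselineCnnConfig] = None
                       ) -> BaselineCnn:
    """Supervised training on (corrupt plane, clean plane) pairs.

    One SGD update per plane pair per epoch (stochastic gradient descent in
    its literal sense); raises FloatingPointError on divergence.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")
    config = config or BaselineCnnConfig()
    model = BaselineCnn(config)
    for a, b in pairs:
        if np.asarray(a).shape != np.asarray(b).shape:
            raise ValueError("paired planes must share a shape")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    params = [Tensor(w, requires_grad=True) for w in model.weights] + \
             [Tensor(b, requires_grad=True) for b in model.biases]
    opt = SGD(params, lr=config.learning_rate)
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        epoch_loss = 0.0
        for idx in order:
            x, y = pairs[idx]
            xt = Tensor(np.asarray(x, dtype=np.float32)[None, None])
            opt.zero_grad()
            pred = model._forward_graph(xt, params)
            loss = pred.mse_to(np.asarray(y, dtype=np.float32)[None, None])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"baseline CNN diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        model.loss_trace.append(epoch_loss / len(pairs))
    n = config.n_layers
    model.weights = [p.data for p in params[:n]]
    model.biases = [p.data for p in params[n:]]
    return model


def apply_baseline_cnn(model: BaselineCnn, plane: np.ndarray) -> np.ndarray:
    """Apply the trained CNN to one plane; output shape == input shape."""
    return model.forward(plane)
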