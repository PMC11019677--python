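"""Encoder-decoder post-processor for SIREN predictions.

A small U-Net-style 2-D network (filter count doubling per level, 2x2 max
pooling, nearest-neighbour upsampling, skip connections, final 1x1
single-filter linear projection) trained on pairs of (SIREN-reconstructed
plane, originally rendered plane).  The targets are the noisy acquired
planes, not the clean signal: the network learns to map the overly smooth
SIREN output back toward acquisition-like statistics, which is what
improves downstream structure detection.

Training: Adam at a constant learning rate 0.01 on MSE, mini-batches of 10
planes for 100 epochs (defaults); batches fall back to the whole set when
fewer pairs than a batch exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._autodiff import Tensor, Adam
from .preprocessing import apply_normalizer, fit_normalizer
from .siren import Siren, SirenConfig
from .stacks import ImageStack

__all__ = ["DenoiserConfig", "DenoiserModel", "TrainingPairSet",
           "build_denoiser_pairs", "train_denoiser", "apply_denoiser"]


@dataclass
class DenoiserConfig:
    """Architecture/training hyperparameters of the denoiser.

    ``base_filters`` doubles per level (64, 128, ... by default); the output
    layer is a linear 1x1 convolution with a single filter.  ``n_levels``
    counts encoder scales (n_levels - 1 poolings); input planes are
    reflect-padded to a multiple of 2**(n_levels-1) and cropped back.
    """

    base_filters: int = 64
    n_levels: int = 3
    kernel: int = 3
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.base_filters < 1 or self.n_levels < 1:
            raise ValueError("base_filters and n_levels must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd")


@dataclass
class TrainingPairSet:
    """Paired (SIREN-reconstructed plane, originally rendered plane) arrays."""

    inputs: np.ndarray    # (N, H, W)
    targets: np.ndarray   # (N, H, W)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.targets = np.asarray(self.targets, dtype=np.float32)
        if self.inputs.shape != self.targets.shape:
            raise ValueError("inputs/targets shape mismatch")

    def __len__(self) -> int:
        return len(self.inputs)


class DenoiserModel:
    """Weights + forward pass of the encoder-decoder network."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel
        self.layers: List[dict] = []   # ordered conv specs
        self.loss_trace: List[float] = []

        def conv_spec(name, c_in, c_out, kk):
            fan_in = c_in * kk * kk
            bound = np.sqrt(6.0 / fan_in)
            return {"name": name,
                    "w": rng.uniform(-bound, bound,
                                     (c_out, c_in, kk, kk)).astype(np.float32),
                    "b": np.zeros(c_out, dtype=np.float32)}

        f = config.base_filters
        # encoder: one conv+relu per level, pooling between levels
        c_in = 1
        enc_channels = []
        for lvl in range(config.n_levels):
            c_out = f * (2 ** lvl)
            self.layers.append(conv_spec(f"enc{lvl}", c_in, c_out, k))
            enc_channels.append(c_out)
            c_in = c_out
        # decoder: upsample, concat skip, conv+relu
        for lvl in range(config.n_levels - 2, -1, -1):
            c_skip = enc_channels[lvl]
            c_out = f * (2 ** lvl)
            self.layers.append(conv_spec(f"dec{lvl}", c_in + c_skip, c_out, k))
            c_in = c_out
        # final linear 1x1 single-filter projection
        self.layers.append(conv_spec("out", c_in, 1, 1))

    # ------------------------------------------------------------ params
    def _param_tensors(self, requires_grad: bool):
        params = []
        for spec in self.layers:
            spec["wt"] = Tensor(spec["w"], requires_grad=requires_grad)
            spec["bt"] = Tensor(spec["b"], requires_grad=requires_grad)
            params += [spec["wt"], spec["bt"]]
        return params

    def _sync_from_tensors(self):
        for spec in self.layers:
            spec["w"] = spec["wt"].data
            spec["b"] = spec["bt"].data

    def _layer(self, name: str) -> dict:
        for spec in self.layers:
            if spec["name"] == name:
                return spec
        raise KeyError(name)

    # ----------------------------------------------------------- forward
    def _forward_graph(self, x: Tensor) -> Tensor:
        cfg = self.config
        skips = []
        h = x
        for lvl in range(cfg.n_levels):
            spec = self._layer(f"enc{lvl}")
            h = h.conv2d(spec["wt"], spec["bt"]).relu()
            if lvl < cfg.n_levels - 1:
                skips.append(h)
                h = h.maxpool2()
        for lvl in range(cfg.n_levels - 2, -1, -1):
            spec = self._layer(f"dec{lvl}")
            h = h.upsample2().concat_channels(skips[lvl])
            h = h.conv2d(spec["wt"], spec["bt"]).relu()
        out = self._layer("out")
        return h.conv2d(out["wt"], out["bt"])

    def _pad_amounts(self, h: int, w: int):
        m = 2 ** (self.config.n_levels - 1)
        return (-h) % m, (-w) % m

    def forward(self, planes: np.ndarray) -> np.ndarray:
        """Apply to (N, H, W) planes; pad-and-crop to the pooling multiple."""
        x = np.asarray(planes, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        n, h, w = x.shape
        ph, pw = self._pad_amounts(h, w)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        self._param_tensors(requires_grad=False)
        out = self._forward_graph(Tensor(x[:, None])).data[:, 0]
        out = out[:, :h, :w].astype(np.float64)
        return out[0] if single else out


def build_denoiser_pairs(phantoms: Sequence, siren_config: Optional[SirenConfig] = None,
                         seed: int = 0, noise_seed_base: int = 9000
                         ) -> TrainingPairSet:
    """SIREN-reconstruct each phantom's noisy render; pair with the render.

    For every phantom: render one noisy acquisition, percentile-normalize,
    fit a SIREN on the full grid, predict all planes.  The predictions are
    the inputs; the normalized noisy planes themselves are the targets, so
    the denoiser learns acquisition statistics.  All planes are collected
    into one TrainingPairSet.  Deterministic per (seed, phantom order).
    """
    from .phantom import render_noisy
    from .preprocessing import make_grid, stack_to_sample
    if len(phantoms) == 0:
        raise ValueError("need at least one phantom")
    siren_config = siren_config or SirenConfig()
    inputs, targets = [], []
    for i, truth in enumerate(phantoms):
        noisy = render_noisy(truth, seed=noise_seed_base + 131 * i + seed)
        params = fit_normalizer(noisy)
        norm = apply_normalizer(noisy, params)
        cfg_i = SirenConfig(**{**siren_config.__dict__,
                               "seed": siren_config.seed + 17 * i + seed})
        model = Siren(cfg_i, normalization=params)
        model.fit(stack_to_sample(norm))
        pred = model.predict_grid(make_grid(norm.shape), norm.shape)
        inputs.append(pred.data)
        targets.append(norm.data)
    return TrainingPairSet(np.concatenate(inputs, axis=0),
                           np.concatenate(targets, axis=0))


def train_denoiser(pairs: TrainingPairSet,
                   config: Optional[DenoiserConfig] = None) -> DenoiserModel:
    """Mini-batch Adam on MSE; loss trace stored per epoch on the model."""
    config = config or DenoiserConfig()
    if len(pairs) == 0:
        raise ValueError("empty TrainingPairSet")
    model = DenoiserModel(config)
    n = len(pairs)
    batch = min(config.batch_size, n)   # small-data fallback: batch = all
    ph, pw = model._pad_amounts(*pairs.inputs.shape[1:])
    x = pairs.inputs
    y = pairs.targets
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
        y = np.pad(y, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    params = model._param_tensors(requires_grad=True)
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch):
            idx = order[lo:lo + batch]
            opt.zero_grad()
            pred = model._forward_graph(Tensor(x[idx][:, None]))
            loss = pred.mse_to(y[idx][:, None])
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"denoiser diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.loss_trace.append(float(np.mean(losses)))
    model._sync_from_tensors()
    return model


def apply_denoiser(model: DenoiserModel, stack_or_planes):
    """Per-plane 2-D application; deterministic, shape-preserving."""
    if isinstance(stack_or_planes, ImageStack):
        out = model.forward(stack_or_planes.data)
        return ImageStack(out, stack_or_planes.voxel_size_um,
                          stack_or_planes.provenance + " [denoised]")
    return model.forward(np.asarray(stack_or_planes))
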