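# sirenstack

Implicit neural representations for fluorescence microscopy z-stacks.

Three-dimensional two-photon or confocal stacks of neuronal anatomy are
slow to acquire, photobleach the sample, and — in awake animals — suffer
intra-frame motion artifacts.  `sirenstack` addresses both problems by
fitting a **SIREN** (a multilayer perceptron with sine activations) to each
stack, turning the discrete voxel grid into a continuous field
Φ: ℝ³ → ℝ:

    Φ(x) = W_n (φ_{n-1} ∘ … ∘ φ_0)(x) + b_n,   φ_i(x_i) = sin(ω0 · W_i x_i + b_i)

* **Motion correction, unsupervised.**  Each plane is acquired R times
  (R = 4 typical).  A SIREN fitted to all repetitions — or to a stack
  random-sampled from them — regresses the consistent underlying signal and
  rejects uncorrelated line-shift artifacts, with no manual curation and no
  training corpus.  Baselines: repetition averaging and a supervised
  3-layer correction CNN.
* **Interplane prediction.**  Fit the SIREN on every (n+1)-th plane only
  and query it at the omitted z-positions, trading acquisition time and
  photobleaching for reconstruction error.  Baseline: linear interpolation
  between flanking planes.
* **Denoiser post-processing.**  A small U-Net-style encoder–decoder maps
  the overly smooth SIREN predictions back toward acquisition-like
  statistics, which improves downstream structure detection.
* **Synthetic phantoms with ground truth.**  A seeded generator produces
  two-photon-like dendrite stacks (tubular shafts, spine head+neck
  protrusions, Gaussian PSF, Poisson+Gaussian noise, repetitions,
  line-shift motion artifacts) with masks, spine centers and artifact
  records, so every claim is tested against known truth.

Everything runs on plain numpy/scipy (the networks use a small built-in
autodiff core); no GPU is required.  See `docs/methods.md` for the model
details and the desk-scale parameter profile.

## Worked example

```python
import numpy as np
from sirenstack import (PhantomSpec, generate_phantom, make_repetitions,
                        CorrectionConfig, SirenConfig, correct_stack,
                        average_repetitions)

# a 16-plane dendrite phantom, 4 repetitions, ~25% of planes hit by motion
truth = generate_phantom(PhantomSpec(shape=(16, 32, 32), seed=1))
reps, records = make_repetitions(truth, n_reps=4, artifact_prob=0.25, seed=11)
corrupted = sorted({r.plane_index for r in records})

cfg = CorrectionConfig(strategy="sampled",
                       siren=SirenConfig.for_phantom_scale(seed=3))
corrected = correct_stack(reps, cfg)
naive = average_repetitions(reps)

clean = truth.clean_stack.data
for name, stack in [("naive 4-rep average", naive), ("SIREN corrected", corrected)]:
    err = np.mean((stack.data[corrupted] - clean[corrupted]) ** 2)
    print(f"{name:22s} MSE on corrupted planes: {err:.5f}")
```

prints

```
naive 4-rep average    MSE on corrupted planes: 0.00476
SIREN corrected        MSE on corrupted planes: 0.00344
```

the SIREN beats the standard averaging approach on the artifact-afflicted
planes even though it never saw a clean reference — averaging keeps a ghost
of the displaced rows at 1/R weight, while the continuous fit regresses
the repetition-consistent signal.

The same objects drive the CLI:

```bash
sirenstack simulate --out phantom/ --seed 1
sirenstack motion-correct phantom/repetition_*.tif --out corrected.tif --strategy sampled
sirenstack interpolate corrected.tif --skip 2 --method both --out-prefix interp
sirenstack evaluate interp_siren.tif corrected.tif --out metrics.json
sirenstack pipeline --seed 1 --out run1/        # simulate -> correct -> interplane -> denoise
```

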