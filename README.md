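# cryoice

Few-shot segmentation and quantification of crystalline (non-vitrified) ice
in cryo-electron tomography micrographs.

## The problem

Cryo-ET relies on vitrification: water must freeze into amorphous ice so the
specimen is preserved in a near-native state. When vitrification fails or the
sample devitrifies, hexagonal (Iₕ), cubic (I_c) or stacking-disordered (I_sd)
ice forms and produces strong diffraction contrast that corrupts micrographs.
Screening hundreds of tilt series for these regions by eye is slow, and each
microscope session has its own optics, sample content and preparation — a new
"domain" every time. `cryoice` segments crystalline-ice regions per pixel and
reports the **percentage of non-vitrified area** per micrograph and per
dataset, adapting to a new dataset from as few as 1–10 annotated micrographs.

## The model and algorithms

The segmenter is a **feature pyramid network (FPN)**: an encoder (residual or
densely connected blocks, group-norm throughout) produces feature maps at
1/2, 1/4, 1/8 resolution; a top-down pathway upsamples the coarsest map and
sums it with 1×1 lateral projections; a small head emits one logit per pixel.
The forward pass is functional — all weights live in a flat named mapping —
so a network can be evaluated under any externally supplied parameter set.

Adaptation to a new dataset is framed as few-shot learning over tasks τ, each
split into a support set `D_support` (for adaptation) and a query set
`D_query` (for evaluation). Two strategies are implemented over the same
model:

* **Transfer baseline** — regular gradient descent: pre-train θ on pooled
  data, fine-tune on the k labeled target micrographs.
* **MAML** — bi-level optimization of the initialization itself:

  ```
  φ_τ = θ − α ∇_θ L(θ; D_support^τ)        (inner loop, repeated)
  θ  ← θ − β ∇_θ Σ_τ L(φ_τ; D_query^τ)     (outer loop)
  ```

  The outer gradient differentiates *through* the inner updates. The package
  ships its own numpy-backed reverse-mode autodiff engine
  (`cryoice.autodiff`) whose vector-Jacobian products are themselves
  differentiable, so the exact second-order meta-gradient is available (a
  first-order variant, FOMAML, is the default at FPN scale).

Training data for the full framework comes from a bundled synthetic
generator: "datasets" share latent rendering parameters (noise, background
smoothness, ice texture frequency/orientation/contrast, artifact rate), ice
patches carry oriented sinusoidal texture (1 carrier for cubic, 3 at 60° for
hexagonal, a random mixture for stacking-disordered), and dark contamination
discs / bright-rimmed bubbles are rendered but never labeled — the classic
false-positive traps.

Metrics: IoU and F1 (= 2·IoU/(1+IoU)) for model comparison; percent
non-vitrified area, aggregated as mean ± 95% normal-approximation CI over
micrographs, for end users.

## Worked example

Meta-train a ~32k-parameter FPN on the synthetic task family, then adapt to
held-out datasets from 5 annotated micrographs each:

```python
import numpy as np
from cryoice import (BackboneConfig, ConfigPrior, MetaConfig, build_model,
                     inner_adapt, make_task, meta_train,
                     sample_dataset_config)
from cryoice.meta import evaluate_pairs

prior = ConfigPrior()                       # the synthetic task distribution
theta0 = build_model(BackboneConfig(), init_seed=0)

def sampler(rng):
    ds = sample_dataset_config(prior, seed=int(rng.integers(2**31)))
    return make_task(ds, k_support=3, n_query=2, seed=int(rng.integers(2**31)))

cfg = MetaConfig(inner_steps=3, inner_lr=0.05, outer_lr=0.05,
                 meta_batch_tasks=4, meta_iterations=120, seed=7)
theta_star = meta_train(sampler, theta0, cfg)

eval_cfg = MetaConfig(inner_steps=5, inner_lr=0.05)
task = make_task(sample_dataset_config(prior, seed=50_000), 5, 2, seed=60_000)
phi = inner_adapt(theta_star, task.support, eval_cfg).phi
print(evaluate_pairs(phi, task.query))      # (IoU, F1) on the query set
```

On 20 held-out synthetic datasets this run prints a mean 5-shot query IoU of
**0.73** from the meta-trained initialization against **0.17** from the same
adaptation started at random initialization — the rapid-adaptation gap that
motivates meta-learning here. On a held-out dataset of 20 micrographs the
adapted model reported **5.98% ± 0.59%** non-vitrified area against a ground
truth of **4.83% ± 0.39%** (mean ± 95% CI).

The same pipeline is available from the shell:

```sh
cryoice simulate --out data/ --n-datasets 1 --images-per-dataset 6 --seed 5
cryoice finetune --stack data/dataset_0.mrc \
    --annotations data/dataset_0_annotations.xml \
    --checkpoint theta.npz --out tuned.npz --shots 5 --epochs 20
cryoice infer --stack data/dataset_0.mrc --checkpoint tuned.npz --out out/
cryoice analyze --report out/report.json --max-percent 5 --out passlist.json
```

`infer` writes per-image masks (PNG), `report.csv` and `report.json`;
`analyze` writes the pass/fail list of micrographs under the crystallinity
cutoff.

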