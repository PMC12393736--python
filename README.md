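# spadama

Cell-type deconvolution of spatial transcriptomics (ST) spots by
domain-adversarial masked-autoencoder learning.

Sequencing-based ST platforms (Visium, Stereo-seq, ...) measure expression
at capture spots that each contain several cells, so every spot profile is
a mixture of cell-type signatures. Given a cell-type-labelled scRNA-seq
reference from the same tissue, `spadama` estimates the proportion matrix
`Y_t` (spots × cell types, rows on the simplex). It is aimed at
computational biologists analysing tissue architecture who have a matched
reference and want per-spot composition without single-cell resolution.

## Method

Supervision comes from **pseudo-spots**: simulated mixtures of reference
cells whose proportions are known exactly. An encoder `E` embeds both the
(randomly masked) real ST matrix and the pseudo-spots into a shared latent
space; training alternates three sub-steps per iteration:

1. **Masked reconstruction + alignment** — encoder and decoder minimize
   `λ‖(X̂_r − X_r) ⊙ M‖²/|M| + (1−λ)(L_C + L_D)`, where `M` is a fresh
   Bernoulli(ρ) mask;
2. **Adversarial heads** — a classifier on the first half of the latent
   columns learns correct domain labels while a discriminator on the second
   half is trained with flipped labels,
   `L_C = BCE(C(H_R1),1) + BCE(C(H_S1),0)`,
   `L_D = BCE(D(H_R2),0) + BCE(D(H_S2),1)`;
3. **Proportion prediction** — encoder and a softmax-headed predictor
   minimize `‖Y − Y_r‖²` on the labelled pseudo-spots.

Inference is `Y_t = P(E(X_r))` on the unmasked data. Defaults: 200 epochs,
batch 2048, learning rate 0.01, ρ = 0.3, λ = 0.5, latent 128 split 1:1.
Evaluation ships the standard deconvolution suite: per-type PCC, SSIM,
RMSE, base-2 Jensen-Shannon divergence, a rank-composite Accuracy Score
across methods, and region AUC. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Everything below is synthetic, so it runs with no downloads:

```python
from spadama import *
from spadama.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="demo_run", seed=11,
    fixture={"K": 5, "G": 200, "markers_per_type": 20,
             "cells_per_type": 200, "n_spots": 500},
    pseudo={"n_spots": 2000},
    training={"epochs": 50, "batch_size": 256},
)
out = run_pipeline(cfg)          # writes demo_run/
```

The run log ends with:

```
INFO shared gene panel: 200 genes
INFO mean metrics: {'pcc': 0.9609751353899089, 'ssim': 0.9324721809167922,
                    'rmse': 0.0887828456936532, 'js': 0.03203553509549179}
```

meaning the inferred proportions correlate with the known ground truth at
mean per-type Pearson r ≈ 0.96, with RMSE ≈ 0.09 proportion units and a
small Jensen-Shannon divergence between true and predicted spatial
distributions. `demo_run/` contains `pseudo.h5ad`, `model.ckpt`,
`trace.csv` (per-iteration losses), `proportions.csv` (spot × type, rows
sum to 1), `report.json` and `run.log`, each traceable to the config hash
in `manifest.json`.

The same pipeline is available from the shell:

```bash
spadama simulate --out-ref ref.h5ad --out-st st.h5ad --out-truth truth.csv --seed 11
spadama run --config run.yaml
spadama evaluate --truth truth.csv --pred demo_run/proportions.csv --out report.json
```

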