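# spotdecon

Cell-type deconvolution for spot-based spatial transcriptomics (ST).

Spot-based platforms (10x Visium and kin) measure expression at capture
spots that each mix transcripts from several cells. `spotdecon` estimates
the per-spot cell-type composition with a multitask autoencoder trained
jointly on two domains:

* **pseudo-spots** simulated from a single-cell reference — sums of
  sampled cell profiles whose composition labels Y_prop are known exactly
  — which carry the deconvolution supervision;
* **real spots**, which contribute reconstruction of their expression,
  an auxiliary spot-pathology classification task, and an adversarial
  domain-matching signal.

Real spots are embedded through *spot correlation encoding*: a k-nearest-
neighbor graph over spot coordinates, propagated by symmetric-normalized
graph convolutions H(l+1) = ReLU(D̂^(−1/2)ÂD̂^(−1/2) H(l) W(l)). The paired
H&E image enters through *spot-level feature extraction*: multi-scale
patches (150/100/50 px, resized to 224²) are token-encoded, attention-
pooled per scale, and fused into a perceptual embedding f_perc that
conditions every decoder layer through cross-modal attention, alongside a
sinusoidal positional encoding of the spot coordinates. A gradient-
reversal domain discriminator aligns the latent spaces of the two
domains. The training objective is

    L_total = L_deconv + λ1·L_hist + λ2·L_recon + λ3·L_match,

with categorical cross-entropies for deconvolution and pathology, MSE for
reconstruction, and a binary cross-entropy through the gradient-reversal
layer for domain matching (defaults λ = 0.1, 0.1, 0.01).

Everything needed to exercise the pipeline is generated in-package: a
marker-structured single-cell reference, labelled pseudo-spots (normal
cells-per-spot and types-per-spot draws, abundance-weighted sampling,
binomial depth thinning), a region-structured synthetic slide with
tinted histology, and in-silico H&E artifacts (cracks, folds, stain
irregularities). No downloads, GPUs, or pretrained weights are required;
the default patch encoder is a deterministic stub behind the same
interface a pretrained pathology foundation model would use.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from spotdecon.config import RunConfig
from spotdecon.pipeline import simulate_run, train_run
from spotdecon.training import deconvolve
from spotdecon.metrics import evaluate_matrices

cfg = RunConfig({"seed": 7})
study = simulate_run(cfg)                 # reference, pseudo-spots, slide
model, curves = train_run(cfg, study, epochs=150, batch_size=64)
props = deconvolve(model, model._trained_real)

report = evaluate_matrices(study.real_truth.values, props.values,
                           study.real.coords.xy)
acc = np.mean(props.values.argmax(1) == study.dominant_type)
print(f"mean per-spot PCC  {report.pcc_mean:.4f}")
print(f"mean per-type SSIM {report.ssim_mean:.4f}")
print(f"RMSE               {report.rmse:.4f}")
print(f"dominant-type acc  {acc:.4f}")
```

Output (about a minute on one CPU):

```
mean per-spot PCC  0.8724
mean per-type SSIM 0.6989
RMSE               0.1856
dominant-type acc  0.9570
```

The study plants a dominant cell type per tissue region (70 % of the
sampling mass), so the numbers read: predicted composition vectors
correlate 0.87 with the exact sampled per-spot ratios, the planted
dominant type is the argmax for 96 % of spots, per-type spatial abundance
maps resemble the truth at SSIM 0.70, and the root-mean-square proportion
error per entry is about 0.19.

The same pipeline is available from the shell:

```sh
spotdecon simulate   --config cfg.yaml --out run/
spotdecon train      --config cfg.yaml --out run/
spotdecon deconvolve --config cfg.yaml --model run/model.npz \
                     --expression run/real_expression.csv \
                     --coordinates run/real_coordinates.csv --out run/
spotdecon evaluate   --truth run/real_true_proportions.csv \
                     --prediction run/predicted_proportions.csv \
                     --coordinates run/real_coordinates.csv
spotdecon perturb    --image run/slide.png --kind crack_fold_stain \
                     --severity 0.3 --out run/slide_perturbed.png
```

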