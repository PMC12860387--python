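# Methods

## Problem

Spot-based spatial transcriptomics (Visium-class platforms) measures gene
expression at capture locations ("spots") that each aggregate transcripts
from several adjacent cells. Deconvolution estimates, for every spot, the
proportions of the constituent cell types. `spotdecon` does this with a
multitask autoencoder trained jointly on two domains:

* **simulated pseudo-spots** built from a single-cell reference, which
  carry exact composition labels and supply the deconvolution supervision;
* **real spots**, which carry spatial coordinates, a paired H&E image and
  (optionally) spot-level pathology annotations, and supply
  reconstruction, classification and domain-matching signals.

## Model

A shared three-layer encoder E (G → 512 → d_f, ReLU; d_f = 256 by
default) embeds expression rows from both domains. Simulated rows enter E
directly. Real rows are first passed through **spot correlation encoding
(SCE)**: a k-nearest-neighbor graph over the spot coordinates (k = 5,
Euclidean distance in pixel units, ties broken by lower index, symmetrized
by OR) with self-loops Â = A + I, degrees D̂_ii = Σ_j Â_ij, and two graph
convolution layers

    H(l+1) = ReLU( D̂^(−1/2) Â D̂^(−1/2) · H(l) · W(l) ).

The GCN maps G → 512 → G so that both domains present the same gene-space
width to the shared encoder. Its weights are initialized near identity
(identity blocks plus small Glorot noise), so propagation starts as pure
two-hop neighborhood smoothing of expression and departs from it only as
training dictates; this keeps the two encoder inputs on one scale from the
first epoch.

**Spot-level feature extraction (SFE)** turns the histology image into one
perceptual embedding f_perc per spot: square patches at scales 150/100/50
px are cropped centered on the spot (white padding outside the image),
resized to 224×224, encoded to 16 tokens of dimension 64, self-attention
pooled per scale (scores = tokens·w/√d, softmax weights), concatenated,
and fused by a three-layer ReLU MLP back to dimension 64. The default
token encoder is a deterministic stub — a 16×16 block-mean grayscale
summary followed by a frozen seeded random projection — so no pretrained
weights or downloads are ever required; a pretrained pathology foundation
model can be plugged in through the same patch → tokens interface. With
the stub the whole perceptual pathway (tokens, pooling weights, fusion
MLP) is a frozen function of its seeds; what trains is how the decoder
*uses* f_perc, via its value/output projections.

The **conditional decoder** D mirrors the encoder (d_f → 512 → G). Every
decoding layer adds a projected sinusoidal positional encoding of the
min-max-normalized spot coordinates (base frequency 1, geometric growth to
100, sin/cos interleaved per axis; entries in [−1, 1]) and a cross-modal
attention term with a residual connection: queries come from the hidden
state, keys and values from the spot's own f_perc. With the default one
key per spot the attention weight is identically 1, so the attended value
reduces to the projected perceptual row; a neighborhood-of-keys mode
(spot plus graph neighbors) is available in `image_features`. The
simulated branch has no coordinates or image, so both injections are
skipped identically (pure residual path).

A shared three-layer extractor F_shared (d_f → 256 → d_s, d_s = 128)
feeds two linear-softmax heads: C_prop (cell-type proportions) and C_hist
(pathology class). A domain discriminator M (d_f → 64 → 1, sigmoid) is
reached through a gradient-reversal layer: identity forward, gradient
scaled by −1.0 backward, pushing the encoder toward domain-invariant
latents.

## Losses and training

    L_total = L_deconv + λ1·L_hist + λ2·L_recon + λ3·L_match

L_deconv and L_hist are categorical cross-entropies summed over spots and
classes (probabilities clamped to [1e-12, 1−1e-12]); L_recon is the
squared error between normalized real expression and the decoder output
(mean reduction during training for scale stability; the summed form is
available and tested); L_match is the binary cross-entropy of the domain
discriminator averaged over all rows of both domains. Default weights
λ = (0.1, 0.1, 0.01); a simulated-only configuration uses (0.0, 0.1, 0.0).
Optimization is Adam at learning rate 1e-3. Each epoch pairs shuffled
simulated batches with real batches drawn by cycling a permutation of the
real spots (so every real spot is visited evenly); one optimizer step is
taken per paired batch on the full objective. Forward passes are
deterministic; all randomness flows from the config seed through a
splitmix64 fan-out, one derived stream per module.

Evaluation follows a K-fold protocol (K = 10 by default): spots are
randomly partitioned, each fold is predicted once by a model trained
without that fold's real-side gradients, predictions are concatenated, and
PCC / SSIM / RMSE are computed once on the aggregate. PCC and RMSE are
per-spot (across genes or types) then averaged; SSIM is per-gene on maps
rasterized to the lattice implied by the spot coordinates, using global
means/variances/covariance (no sliding window), per-gene max-normalized,
with C1 = 0.01², C2 = 0.03². The graph is transductive across folds by
default; an inductive mode rebuilds it per fold.

## Synthetic data

The generator emulates the standard pseudo-spot benchmark construction:

* **Reference**: Poisson counts, cells assigned round-robin to P1 types,
  genes split evenly into marker blocks; a marker's rate is
  `marker_fold × base_rate` in its own type, `base_rate` elsewhere.
* **Pseudo-spots**: per spot, cells-per-spot N_c ~ Normal(10, 3) rounded
  and truncated to ≥ 1, types-per-spot N_t ~ Normal(3, 1) truncated to
  [1, P1]; N_t types chosen uniformly; cells of those types sampled with
  replacement proportionally to reference abundance; expression is the sum
  of sampled rows, and the label is the exact per-type sampled-cell ratio.
* **Slide**: a regular spot grid with seed-grown contiguous regions, a
  region-tinted RGB image with mild noise, and one-hot region labels. Each
  region is assigned a dominant cell type (region index mod P1) holding
  0.7 of the sampling mass, so the planted dominant type is known.
* **Depth**: the slide's expression — the stand-in for real ST data — is
  binomially thinned entrywise (default fraction 0.1, ≈560 counts per
  spot), emulating the much shallower depth of spot-based platforms
  relative to summed single-cell profiles. Training pseudo-spots stay at
  full depth; this depth gap is exactly what the domain matcher must
  bridge and what spatial smoothing helps denoise.
* **Artifacts**: cracks (dark polyline band), folds (shifted translucent
  band), stain irregularities (hue/saturation shift in random blobs), and
  their combination, all deterministic in their seed.

What the generator does **not** emulate: platform optics (spot diameter,
bead geometry), gene-length or capture biases, batch chemistry, spatial
expression gradients within a region, and real H&E texture. Passing tests
therefore demonstrate correct mechanics and recoverability under a
controlled, marker-separated regime — not performance on real tissue.

## Reference study and measured behavior

The reference synthetic study (the configuration the acceptance script
and the end-to-end tests run) uses a 4-type, 200-gene, 2 000-cell
reference with 8-fold markers; 500 pseudo-spots; a 16×16-spot slide with
4 regions; 150 epochs at batch 64. These sizes were chosen so a complete
run takes about a minute on one CPU while leaving the recovery problem
non-trivial. Because proportion prediction consumes only expression and
coordinates at inference, artifact robustness is measured on the model
output that does consume the image: the mean per-spot PCC between
normalized expression and its conditioned reconstruction, clean versus
perturbed image.

## Numerical choices and limitations

* All computation is float64 on an in-package reverse-mode autodiff core
  (`spotdecon.autodiff`) that implements exactly the operator set the
  model needs, including the gradient-reversal op and Adam.
* Softmaxes are max-shifted; sigmoids use the sign-split stable form;
  cross-entropy probabilities are clamped at 1e-12.
* KNN ties are broken by lower spot index; gene-variance ties in
  `align_genes` by gene order — both for determinism.
* All-zero expression rows pass through normalization unchanged; constant
  vectors make PCC raise rather than return NaN.
* The positional-encoder width question (how to tie it to the gene
  dimension) is resolved as a fixed pos_dim = 64 encoding linearly
  projected into each decoder layer's width.
* Limitations: dense adjacency (fine to a few thousand spots, not for
  bead-level platforms); no dropout, LR schedules or early stopping; the
  stub image backend captures region tint, not histomorphology; the
  10-fold protocol retrains per fold and is priced accordingly.
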