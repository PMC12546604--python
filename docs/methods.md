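# Methods

## The problem

Image-based profiling screens (Cell Painting) measure compound-induced
morphology through five fluorescence channels. The measurements are
confounded: the source laboratory, the batch/plate, and the well position
influence which compound is screened where (incomplete plate-map
randomization), the underlying cell state, and the imaging process itself.
Naive per-compound profile averages therefore mix the compound's causal
effect with technical variation, degrading downstream mechanism-of-action
(MoA) and target identification.

`cpcausal` implements a confounder-aware generative pipeline around an
explicit structural causal model (SCM) with variables

- `C` — confounders (source, plate-level batch, well position),
- `T` — compound treatment (conditioned as a SMILES-derived embedding),
- `P` — the true, unobserved phenotype,
- `O` — the observed 5-channel image,

and edges `C -> T`, `C -> P`, `C -> O`, `T -> P`, `P -> O`. The average
compound effect is the interventional quantity

    p(O | do(T = t)) = ∫ p(O | T = t, C) p(C) dC,

estimated by Monte-Carlo backdoor adjustment (g-estimation): draw N
confounder combinations `c_i` uniformly from the training support, sample
images from the conditional generator at `(t, c_i)`, extract image-level
profiles, and average the N per-combination profiles. Averaging happens in
feature space, after profiling, never at the pixel level.

## The synthetic experiment generator

The SCM's mechanisms are linear-Gaussian, chosen so that the
interventional mean has the closed form `E[P | do(T=t)] = A e_t + B E[c]`
(`A` the T->P matrix applied to the compound embedding `e_t`, `B` the C->P
matrix applied to the mean one-hot confounder code). Every Monte-Carlo
estimate in the package is testable against this oracle.

- **Design / C->T.** Plates are organized source -> batch -> plate with a
  serpentine well grid; default desk scale is 2-3 sources, 2 batches per
  source, 1-2 plates per batch, 24-96 wells, 1-2 fields of view — a few
  hundred to a few thousand images in minutes of CPU. Treatment wells draw
  compounds with probability `softmax(allocation_bias * w[batch, compound])`
  over i.i.d. standard-normal affinities `w`; `allocation_bias = 0` is
  uniform allocation, larger values concentrate compounds in few batches.
  Every compound is guaranteed at least one well (placed with the same
  biased batch preference, so the C-T dependence survives the guarantee),
  and every plate carries DMSO control wells.
- **Compound library.** SMILES-like strings are assembled from a fragment
  grammar: compounds of one MoA class share 3 class fragments plus 1-3
  random filler fragments. This gives hashed n-gram embeddings a
  within-class cosine margin of roughly +0.3 over between-class pairs —
  the structural signal that lets a conditional generator generalize to
  held-out compounds. Each compound carries one MoA and 1-3 targets from a
  class-linked target pool. Three class fragments (not fewer) are used
  because the noise-free classification ceiling with two fragments is low
  enough (~0.6-0.8 AUC) to confound benchmark interpretation.
- **Phenotype / T->P, C->P.** `P = A e + B c + ε`, `ε ~ N(0, 0.3² I)`,
  `dim(P) = 7`. Effect scales default to `compound_scale = 2.0` and
  `confounder_phenotype_scale = 0.6` (raised to 1.2 in the confounded
  benchmark; see below). Phenotypes are drawn once per well — cells in a
  well share biology; fields of view are independent renders.
- **Renderer / P->O, C->O.** Monotone transforms map `P[0]` to cell count,
  `P[1]` to nucleus radius, `P[2..6]` to per-channel intensity. Each cell
  is a soft-edged elliptical nucleus (DNA channel) inside a larger body
  (ER/RNA/AGP/Mito) with a dimmer nuclear shadow. Confounders act on the
  image only through four drivers `W c`: x/y illumination gradient slopes,
  a background offset, and a Gaussian blur width; plus pixel noise
  (sd 0.02) and clipping to [0, 1]. Default images are 64x64 (48x48 in the
  heavier benchmarks); float32, channel order (DNA, ER, RNA, AGP, Mito).

What the generator deliberately does **not** emulate: realistic cell
texture and organelle structure, cell-cycle and density-dependent
morphology, dose-response (one implicit dose), plate-edge effects beyond
the quadrant code, segmentation-hostile artifacts (debris, clumping beyond
ellipse overlap). Passing tests therefore demonstrate the *statistical*
correctness of the adjustment and evaluation machinery under a known
causal structure — not image realism, and not performance on real screens.

## Profiling

A reduced CellProfiler-style pipeline, applied identically to simulated
and generated images:

1. **Illumination correction** — per channel, divide by a median-filter
   estimate of the illumination field (computed on a 2x block-reduced
   copy for speed, Gaussian-smoothed, floor-clipped at 5% of its maximum)
   and rescale to preserve the channel mean.
2. **QC** — blur score (variance of a Laplacian response), saturation
   fraction (pixels >= 0.99), intensity mean/sd. Defaults are permissive
   (saturation < 0.5); failing images never reach feature extraction.
3. **Segmentation** — global Otsu on DNA, area bounds, declumping by
   watershed on the distance transform seeded at its local maxima
   (minimum seed separation = expected radius); cell bodies by watershed
   expansion around nuclei on the AGP channel, constrained to foreground
   ∪ nuclei so every nucleus is contained in its cell; cytoplasm = cell
   minus nucleus.
4. **Features** — per cell and per region (Nucleus/Cytoplasm/Cell): area,
   perimeter, minor/major axis ratio, and per channel mean, median,
   integrated, sd intensity plus a local-variance texture score: 84
   region-prefixed features (vs. thousands in a full CellProfiler export;
   the naming convention is kept so downstream code is schema-compatible).
5. **Aggregation** — cells -> image by per-feature median; image -> well
   and well -> treatment by mean.
6. **Normalization** — robust z-score against same-plate DMSO controls,
   `(x - median) / (1.4826 * MAD)`; features with zero control MAD are set
   to 0 and flagged. Feature selection drops non-finite columns, variance
   < 1e-6, and the later-named member of any pair with |r| > 0.95.
7. **Batch baseline** — per-batch centering/unit-scaling, a deliberately
   simple location/scale correction used as the batch-corrected
   comparison arm.

## The conditional generator

A miniature latent diffusion model, written in numpy:

- **Latent space.** The five channels exceed a 3-channel autoencoder, so
  they are split into two groups — (DNA, ER, RNA) and (AGP, Mito, DNA),
  duplicating DNA — each encoded to 4 latent channels and concatenated to
  8. The encoder is a linear autoencoder fit by PCA on space-to-depth
  pixel vectors (factor 4: 64x64 -> 16x16 spatial), with an exact
  identity mode (factor 1, zero-padded) for tests. Decoding averages the
  two DNA reconstructions. Latent channels are standardized to unit scale.
- **Schedule.** Scaled-linear: betas are the squares of a linear ramp from
  sqrt(0.0015) to sqrt(0.0205); 250 training steps at desk scale (the
  full-scale reference is 1000).
- **Objective.** v-prediction: the network regresses
  `v = sqrt(ᾱ_t) ε − sqrt(1 − ᾱ_t) x₀`, whose algebra is exact and tested
  independently of training (x₀ and ε are recoverable from (x_t, v) by
  the inverse rotation).
- **Denoiser.** A conditional residual MLP on the flattened latent:
  input projection with a FiLM gate from the sinusoidal time embedding
  (v is a t-dependent rotation of its input, which purely additive
  conditioning cannot represent), additive time and context projections,
  two residual ReLU blocks (hidden width 384), linear output. Training is
  MSE on v with hand-written backpropagation (gradients verified against
  finite differences to 1e-8) and AdamW (lr 1e-3, weight decay 1e-4),
  fully seeded.
- **Conditioning.** The context vector concatenates the compound embedding
  (L2-normalized hashed character 2-/3-gram counts of the SMILES string,
  dim 64 — deterministic, defined for unseen compounds) with fixed
  per-category embedding vectors for source, plate-level batch (each
  plate is its own batch for conditioning), well position, and field of
  view. MoA/target labels and hidden phenotypes are absent from the
  context by construction. Sampling refuses ids outside the training
  vocabulary.
- **Sampling.** Deterministic DDIM-style reverse pass over 50 inference
  steps; a fixed seed fixes the initial noise and hence the images bit-
  exactly.

This generator trades fidelity for testability: it demonstrates the
conditioning architecture and the estimation machinery at desk scale, not
photorealistic synthesis.

## Adjustment (g-estimation)

`adjust_dataset` draws one shared list of N confounder combinations
(uniform over plate-level batches — each implying its source — well
positions, and fields of view), reuses it for every compound and for the
DMSO reference, generates `images_per_combination = 1` image per
(compound, combination), profiles each image to its per-cell-median
feature vector, averages the N per-combination profiles arithmetically,
then normalizes against replicated generated DMSO profiles and applies
feature selection. Sharing the combination list across compounds enforces
C ⟂ T exactly and removes between-compound Monte-Carlo variance from the
contrasts. QC-failing generated images are resampled once, then the
combination is dropped with a warning. The reference analysis uses N = 10
(N = 100 at larger budgets); convergence to the closed-form oracle scales
as N^(-1/2) (measured log-log slope ≈ −0.52 over N ∈ {4, 16, 64, 256}).

The oracle path (`adjust_with_oracle`) runs the identical control flow
with the simulator's true conditional in place of the trained generator,
separating Monte-Carlo estimation error from generative-model error.

## Subprofile classification

For each class (MoA or target), 5 reference compounds (desk default 3)
define a consensus subprofile: a feature is retained only if its
normalized value has the same sign in strictly more than 85% of the
reference profiles (exact zeros count toward neither sign); retained
values are medians. Queries are scored against every class by
Biosimilarity — the centered cosine of the two vectors over the
subprofile's feature subset, algebraically the Pearson correlation — and
the full ranked score list feeds the metrics. Folds re-sample references
(10-fold default); classes under the minimum size (default 10 compounds;
4 at desk scale) are dropped with a warning; compounds held out of
generator training appear only in the "unseen" query split.

## Evaluation

- **mAP** — per-sample average precision summed over descending unique
  score thresholds (ties grouped into one step), averaged over samples.
- **Macro ROC-AUC** — per-label trapezoidal area under the (FPR, TPR)
  curve, averaged over labels with both classes present (single-class
  labels are excluded with a warning). Both match independent oracles
  (precision-recall summation; Mann-Whitney U) to 1e-10 and are invariant
  under monotone score transforms.
- **Label-shuffle control** — permutes the sample-to-relevance assignment
  with scores fixed; the null mean sits at chance (≈ 0.50 macro ROC-AUC).
- **Batch diagnostics** — silhouette over batch labels in profile space
  (UMAP-space optional), and the UMAP -> HDBSCAN within-cluster
  compound-count variance, min-max normalized across the datasets
  compared in one run, averaged over 5 seeds (UMAP: 15 neighbors,
  min_dist 0.1, 2 components; HDBSCAN: min_cluster_size 5).
- **Group comparison** — one-way ANOVA plus Tukey HSD adjusted p-values
  in a two-column comparison layout, via statsmodels.

## The confounded-screen benchmark

The package's standard demonstration that adjustment recovers compound
effects: 20 compounds in 4 MoA classes; 2 sources x 2 batches x 1 plate
(6x8 wells), 48x48 images; `allocation_bias = 6`, C->P scale 1.2, C->O
scale 1.0 — a strongly confounded, poorly randomized multi-site screen,
the regime the adjustment exists for. Naive profiles come from the
confounded dataset through the full profiling pipeline; adjusted profiles
from the oracle conditional with N = 8. Over 20 seeded replicates,
oracle-adjusted profiles beat naive profiles at MoA classification
(mean macro ROC-AUC over 6 folds, 3 references per class) in 19/20
replicates, with typical margins of +0.1 to +0.25 AUC.

## Numerical choices and degenerate inputs

- Ties in both ranking metrics are grouped per unique score threshold.
- Biosimilarity raises on constant vectors (zero denominator); per-class
  scores with a feature intersection below 2 are flagged missing.
- Zero-MAD features normalize to 0 (flagged); zero channels pass through
  illumination correction unchanged (warned); empty segmentation masks
  yield empty (not failing) feature tables; single-profile batches are
  centered only.
- Stage seeds derive from `crc32(f"{global_seed}:{stage}") & 0x7fffffff`;
  every stochastic routine takes an explicit seed or Generator, and all
  pipelines are bit-reproducible for a fixed seed.
- Problem sizes throughout (hundreds to ~1000 images per experiment,
  250-step schedules, 8-10 training epochs) are desk-scale choices that
  keep full runs in minutes on one CPU; full-scale reference values are
  noted in the configuration comments.

## Known limitations

- The linear-Gaussian SCM and blob renderer are intentionally simple;
  conclusions transfer to real Cell Painting data only at the level of
  procedure correctness, not effect sizes.
- The numpy denoiser is an MLP with FiLM/additive conditioning, not a
  residual U-Net with cross-attention; at desk scale it demonstrates
  conditioning sensitivity and reproducible sampling, not image fidelity.
- The PCA latent autoencoder is linear; reconstruction blurs fine texture.
- Harmony-style iterative batch correction is out of scope; the per-batch
  location/scale baseline stands in as the comparison arm.
- FoV is an auxiliary condition with no causal effect in the simulator
  (configurable); whether framing should vary with FoV is left open.
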