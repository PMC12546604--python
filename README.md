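# cpcausal

Confounder-aware generative profiling for Cell Painting-style screens,
at desk scale and fully synthetic. The package is aimed at computational
biologists and method developers who want to study — with a known ground
truth — how technical confounders (source lab, batch/plate, well
position) bias morphological profiling, and how generative backdoor
adjustment recovers compound effects.

## What it does

High-content screens observe cell morphology `O` only through a causal
chain contaminated by confounders `C`: plate maps are not fully
randomized (`C -> T`), batches shift cell state (`C -> P`), and imaging
conditions vary (`C -> O`). `cpcausal` implements the full loop:

1. **Synthetic SCM screens** — confounded Cell-Painting-like experiments
   (5-channel TIFF stacks + ground-truth tables) from an explicit
   linear-Gaussian structural causal model with a closed-form
   interventional oracle `E[P | do(T=t)] = A e_t + B E[c]`.
2. **Profiling** — a compact CellProfiler-style pipeline: illumination
   correction, QC, Otsu/watershed segmentation, 84 region-prefixed
   per-cell features, and the median (cells -> image) / mean (image ->
   well -> treatment) aggregation hierarchy, with robust-z normalization
   against same-plate DMSO.
3. **Conditional latent diffusion** — a miniature generator with the
   two-group 8-channel latent encoding (DNA duplicated into the second
   group), scaled-linear schedule (β from 0.0015 to 0.0205),
   v-prediction, and conditioning on a SMILES n-gram embedding plus
   source/batch/well/FoV embeddings.
4. **g-estimation** — Monte-Carlo backdoor adjustment
   `p(O | do(T=t)) ≈ (1/N) Σ p(O | T=t, C=c_i)` with `c_i` uniform over
   the training support, averaging in feature space after profiling;
   generic over the trained generator or the simulator's true
   conditional (the oracle path).
5. **Subprofile classification** — MoA/target identification by
   Biosimilarity `B(u,v) = (u-ū)·(v-v̄) / (‖u-ū‖‖v-v̄‖)` against class
   consensus subprofiles (features sign-consistent in > 85% of reference
   compounds, valued at their medians), with re-sampled references over
   cross-validation folds and seen/unseen compound splits.
6. **Evaluation** — mAP and macro ROC-AUC on the full ranked score
   lists, a label-shuffling chance control, silhouette-by-batch and
   UMAP/HDBSCAN clustering diagnostics, and an ANOVA + Tukey HSD
   comparison harness.

No external data or pretrained weights are required; everything runs on
one CPU in minutes. See `docs/methods.md` for the model, assumptions,
and design choices, and `docs/config.md` for configuration.

## Worked example

Simulate a strongly confounded screen (20 compounds, 4 MoA classes,
biased plate maps, batch effects on both phenotype and imaging), then
compare naive profiles against Monte-Carlo-adjusted profiles for MoA
identification:

```python
import warnings; warnings.simplefilter("ignore")
import numpy as np
import pandas as pd
import cpcausal as cp
from cpcausal.gestimation import AdjustmentConfig, adjust_with_oracle, make_image_profiler
from cpcausal.metrics import RankingScores, macro_roc_auc, mean_average_precision
from cpcausal.render import RenderParams
from cpcausal.subprofile import classify_dataset, make_folds

# a confounded screen: 20 compounds / 4 MoA classes, 2 sources x 2 batches
library = cp.make_compound_library(n_compounds=20, n_moa_classes=4, n_target_labels=8, seed=0)
design = cp.make_design(2, 2, 1, 6, 8, 1, library, allocation_bias=6.0, seed=100)
params = cp.ScmParams.random(
    7, 64, cp.confounder_code_dim(design), seed=200,
    confounder_phenotype_scale=1.2, confounder_observation_scale=1.0,
    allocation_bias=6.0,
)
render = RenderParams(height=48, width=48, base_count=8, base_radius=3.5)

# naive arm: profile the confounded images and aggregate
records, metadata = cp.generate_dataset(design, params, library, render, rng=300)
profiler = make_image_profiler(illumination_radius=7, expected_radius=3.5)
rows = []
for rec, (_, m) in zip(records, metadata.iterrows()):
    profile = profiler(rec.image)
    if profile is not None:
        rows.append({**{c: m[c] for c in metadata.columns if c.startswith("Metadata_")},
                     **profile.to_dict()})
wells = cp.aggregate(pd.DataFrame(rows), "well")
naive = cp.select_features(cp.aggregate(cp.normalize_profiles(wells), "treatment"))
naive = naive[naive.Metadata_Compound != cp.CONTROL_COMPOUND]

# adjusted arm: Monte-Carlo backdoor adjustment through the oracle conditional
adjusted = adjust_with_oracle(
    params, design, library, AdjustmentConfig(n_combinations=8, seed=400),
    render_params=render,
).drop(columns=["N", "seed", "n_images_used"])
adjusted = adjusted[adjusted.Metadata_Compound != cp.CONTROL_COMPOUND]

# MoA identification via subprofile Biosimilarity, 6 folds
folds = make_folds(library, "moa", n_ref_per_class=3, n_folds=6, min_class_size=4, rng=500)
for name, profiles in (("naive", naive), ("adjusted", adjusted)):
    aucs, maps = [], []
    for res in classify_dataset(profiles, library, folds):
        ranking = RankingScores(np.nan_to_num(res.scores.to_numpy(), nan=-1.0),
                                res.relevance.to_numpy())
        aucs.append(macro_roc_auc(ranking)); maps.append(mean_average_precision(ranking))
    print(f"{name:9s} macro ROC-AUC {np.mean(aucs):.3f} +/- {np.std(aucs):.3f}   "
          f"mAP {np.mean(maps):.3f}")
```

Output (≈15 s on one CPU):

```
naive     macro ROC-AUC 0.587 +/- 0.059   mAP 0.549
adjusted  macro ROC-AUC 0.847 +/- 0.051   mAP 0.830
```

Naive profiles sit near chance because the biased plate maps entangle
compound identity with batch effects; averaging the same compounds over
uniformly sampled confounder combinations recovers the class structure.

## Command line

The `cpcausal` entry point chains the stages — `simulate`, `profile`,
`train` (diffusion generator), `generate`, `debias`, `classify`,
`evaluate`, `report`, or everything via:

```bash
cpcausal run-all --seed 3 --outdir runs/demo
```

Each stage logs its derived seed, writes its outputs (TIFF stacks,
Parquet profile tables, a JSON metrics report) plus a manifest with
content digests under `--outdir`.

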