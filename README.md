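# octdr

Computer-assisted diagnosis and grading of **nonproliferative diabetic
retinopathy (NPDR)** from macular OCT B-scans.

Diabetic retinopathy screening today relies on dilated fundus exams and
largely subjective OCT reading. Yet diabetic eyes show quantifiable,
layer-resolved OCT changes — thinning of the retinal nerve fiber and
ganglion cell layers, thickening of the inner nuclear and outer plexiform
layers, altered reflectivity — some of which precede any visible fundus
lesion ("subclinical DR"). `octdr` implements a complete pipeline that
turns a macular B-scan into a graded diagnosis, together with a synthetic
phantom generator with exact ground truth so every stage can be validated
end to end. It is aimed at researchers studying OCT-based screening
pipelines and at anyone who needs a fully reproducible, dependency-light
reference implementation of this class of CAD system.

## The pipeline

Three steps run in sequence:

1. **Layer segmentation.** Each B-scan is labelled over a 14-symbol
   alphabet (vitreous, 12 retinal layers, sub-RPE background) by
   maximising a joint model:

   - a *shape prior* `P_sh(ℓ | x, y)` — per-pixel label frequencies from
     gold-standard maps, aligned by foveal column and ILM row;
   - an *intensity model* — a linear combination of discrete Gaussians
     (LCDG) fitted to the scan histogram by EM: one dominant positive
     component per class plus signed subordinate refinements;
   - a *spatial model* — a second-order (8-neighbour) Markov–Gibbs random
     field with Potts potential γ penalising unequal neighbour labels.

   The MAP label field `argmax_ℓ Σ log p(I|ℓ) + log P_sh(ℓ) − γ·Σ[ℓ_p≠ℓ_q]`
   is found by iterated conditional modes over a 2×2 block colouring
   (energy provably nonincreasing), and 13 ordered boundary curves are
   extracted with isotonic repair and lateral median filtering.

2. **Feature extraction.** Per layer: reflectivity on a 0–1000 scale
   (vitreous median → 0, RPE median → 1000), sampled in two parafoveal
   windows; curvature κ = |y″| / (1 + y′²)^{3/2} of the layer's upper
   boundary in physical units; thickness in µm at axial correspondence.
   Each feature is summarised as an empirical CDF on a fixed global grid:
   12 layers × 3 features = **36 CDF vectors per eye**.

3. **Two-stage deep fusion classification network (DFCN).** 36 stacked
   autoencoders (one per CDF slot, 64→32→8, nonnegativity-penalised
   weights) are pretrained unsupervised; their concatenated codes feed a
   softmax head. Stage 1 screens normal vs DR; stage 2 grades DR eyes as
   subclinical vs mild/moderate. Evaluation supports leave-one-subject-out
   (LOSO) and stratified 2-/4-fold cross-validation with accuracy,
   sensitivity, specificity, rank-based AUC and bootstrap 95% CIs.

## Worked example

```python
from octdr import (PhantomConfig, generate_bscan, build_shape_atlas,
                   segment_bscan, mean_layer_dice, boundary_error_um)
from octdr.synthetic import generate_cohort

atlas_records, _ = generate_cohort(6, (1.0, 0, 0), PhantomConfig(), seed=99)
atlas = build_shape_atlas([r.truth.layer_map for r in atlas_records])

cfg = PhantomConfig(noise_sd=0.05, seed=11)
scan, truth = generate_bscan(cfg)
layer_map, boundaries, _ = segment_bscan(scan, atlas)
print(mean_layer_dice(layer_map, truth.layer_map))
print(boundary_error_um(boundaries, truth.boundaries,
                        cfg.axial_um_per_px).mean())
```

prints

```
0.9955115732449298
0.9859874966886075
```

i.e. a mean Dice overlap of **0.996** across the 12 layers and a mean
boundary error of **0.99 µm** (a quarter of an axial pixel) against the
phantom's exact ground truth at speckle noise σ = 0.05. The
`examples/` directory has one short script per capability (phantom
generation, segmentation, features, training/diagnosis, cross-validation,
full pipeline); each prints the numbers it computes with a line on what
they mean. The same chain is available from the shell:

```bash
octdr run-all --seed 1 --out-dir runs/demo
```

## Layout

- `src/octdr/synthetic.py` — phantom generator (cohorts, grades, truth)
- `src/octdr/segmentation.py` — atlas, LCDG, MGRF/ICM, boundaries, Dice
- `src/octdr/features.py` — reflectivity/curvature/thickness CDFs
- `src/octdr/classifier.py` — autoencoders, fusion heads, diagnosis
- `src/octdr/evaluation.py` — folds, CV driver, metrics, bootstrap
- `src/octdr/io.py`, `src/octdr/pipeline.py`, `src/octdr/cli.py` — formats,
  end-to-end driver, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
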