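# Methods

This note documents the models implemented in `octdr`, the assumptions
behind them, the parameters that matter, and what validation on synthetic
phantoms does and does not establish.

## 1. The synthetic phantom generator

### What it emulates

A macular OCT B-scan is modelled as a laminar stack: vitreous above the
inner limiting membrane (ILM), 12 retinal layers, and sub-RPE background
below the outermost boundary. Thirteen boundary curves are smooth,
closed-form functions of the lateral coordinate:

- a **foveal pit**: a Gaussian depression (depth `fovea_depth_um`,
  lateral sigma `fovea_width_px` columns) that compresses every layer in
  proportion to its thickness, so the outer retina stays flat while the
  inner retina thins toward the foveal centre;
- a **shared sinusoidal undulation** (`undulation_amp_um`,
  `undulation_cycles`) added to all 13 boundaries. Because it is shared,
  it perturbs boundary *curvature* without perturbing layer *thickness* —
  which keeps closed-form oracles for both features.

Pixels between consecutive boundaries take the layer's mean intensity;
additive Gaussian noise (`noise_sd`, default 0.03 of full scale) and an
optional multiplicative speckle term are applied and the image clipped to
[0, 1]. Default geometry: 160 × 256 px at 4.0 µm axial / 23.4 µm lateral
spacing (a 6 mm macular line scan), total retina ≈ 326 µm, layer
intensities alternating bright/dark as in spectral-domain OCT with the
RPE brightest.

### Disease model

Three grades are generated. Relative to normal, `mild_moderate` applies
the full effect vector and `subclinical` a configurable fraction of it
(default 0.5, encoding "intermediate between normal and overt disease"):

| axis | default mild/moderate effect |
|---|---|
| thickness | RNFL −18%, GCL −18%, INL +15%, OPL +15% |
| reflectivity | RNFL −10%, GCL −10%, IPL −5% |
| boundary undulation | amplitude ×2 |

The thickness directions follow the established electrophysiology/OCT
picture of early diabetic neuropathy (inner-layer thinning, INL/OPL
thickening). The magnitudes are free parameters chosen once to produce a
separable-but-noisy cohort: subject-level biological variation is
log-normal with σ = 4% (thickness) and 3% (reflectivity), with an
additional 1.5%/1% independent per-eye jitter, so the subclinical effect
(≈ 9%) sits roughly two subject-level standard deviations from normal.
Cohorts assign grades by largest-remainder apportionment (80 subjects at
mix 0.5/0.25/0.25 gives exactly 40/20/20) and both eyes of a subject
share the grade and the subject-level latent effect.

### What phantoms do not model

No vascular shadowing, motion artifacts, physical speckle statistics,
layer-specific texture, or pathology other than the three global effect
axes. Consequently, passing the phantom suites shows the *algorithms* are
implemented correctly and are robust at realistic geometry and noise — it
does not certify clinical performance on device images.

## 2. Layer segmentation

The label field over the 14-symbol alphabet maximises

```
Σ_p [ log p(I_p | class(ℓ_p)) + log P_sh(ℓ_p | p) ] − γ Σ_{p~q} [ℓ_p ≠ ℓ_q]
```

with an 8-neighbour pair system.

**Shape prior.** Per-pixel label frequencies (add-one smoothing) over
gold-standard maps aligned by two 1-D translations: lateral (foveal
columns in register) and axial (ILM rows in register). Translation-only
registration is sufficient for macular scans centred on the fovea; it is
the first thing to revisit for off-centre real data.

**LCDG intensity model.** The gray-level histogram is fitted with one
dominant Gaussian per class by EM on the binned data. EM is initialised
by deterministic weighted k-means whose centres are seeded at uniform
quantiles of the *distinct occupied levels* (not of the mass), so small,
well-separated modes each attract a centre; the log-likelihood trace is
monotone by the standard EM guarantee. Up to `max_subordinate` (default
4) signed Gaussians are then fitted greedily to the residual between the
empirical and dominant densities; each is folded into the nearest class
and the per-class discrete densities are clipped at zero and
renormalised. The sd floor is a quarter of the level spacing so a
noise-free single-level class keeps its mass on its own level after
discretisation. A single-occupied-level histogram returns a flagged
single-class fallback.

**Tying labels to intensity classes.** Each anatomical label is mapped to
the LCDG class whose mean is closest to the *median* scan intensity over
the label's atlas-argmax region. The median matters: a translation-only
atlas can misregister a 3-px layer by a row or two, and a mean would
blend in the neighbouring layer's intensity and mis-tie thin layers.
Several labels may share a class; the shape prior then disambiguates
them. With a completely uninformative (uniform) prior this map — and any
anatomical labelling — is undefined; the noise-free-limit test therefore
uses a minimal two-map atlas.

**Optimisation.** ICM seeded at the atlas argmax, swept over a 2×2 block
colouring: pixels of one colour are mutually non-adjacent in the
8-neighbourhood, so each vectorised colour update is exact coordinate
descent and the Gibbs energy never increases (asserted in tests).
Termination: `icm_max_iters` (12) sweeps or < `icm_tol` (1e-4) fraction
of pixels changed. Ties in the argmax go to the lowest label index.

**Potts potential γ = 4.0 (default).** The model class fixes only the
neighbourhood order, not the potential. On phantoms, γ ≈ 1
leaves isolated speckle labels in the vitreous that corrupt the
first-transition boundary extraction; γ ≥ ~5 begins to erode the thinnest
(3 px) layers under heavy noise. γ = 4 removes isolated labels at the
default noise level while keeping noiseless segmentation exact. It is a
config parameter (`MGRFParams.potts_potential`).

**Boundary extraction.** Boundary k at a column is the transition
midpoint before the first pixel with label ≥ k+1; ordering is enforced by
a running-maximum (isotonic) projection down the boundary stack, then
each curve is median-filtered laterally (window 5; the median is monotone
so ordering survives). Columns where consecutive boundaries coincide
(zero-thickness layer) are flagged.

**Metrics.** Dice = 2|A∩B|/(|A|+|B|) per label (defined 1.0, with a
warning, when the label is empty in both maps); boundary error is the
mean absolute row difference per boundary × axial spacing, reported per
boundary and averaged over all 13.

## 3. Feature extraction

- **Reflectivity**: affine map sending the median vitreous intensity to 0
  and the median RPE intensity to 1000, clipped to [−100, 1100]. Medians
  (not means) make the anchors robust to speckle outliers; a non-positive
  contrast (RPE ≤ vitreous) raises, signalling failed segmentation.
  Samples are drawn only from two 60-column windows centred on the
  thickest retina on each side of the fovea (centre of the maximal-
  thickness plateau, which is symmetric for symmetric scans and
  deterministic under ties), never crossing the foveal column.
- **Curvature**: the layer's *upper* boundary is converted to µm using
  both pixel spacings, smoothed with a Savitzky–Golay quadratic (window
  7), differentiated by central differences (one-sided at the ends), and
  κ = |y″| / (1 + y′²)^{3/2} evaluated per column. Physical units matter:
  anisotropic pixels (4 vs 23.4 µm here) would otherwise distort κ.
  Closed-form oracles: a circle of radius r gives κ = 1/r within 2%; a
  sinusoid A·sin(ωx) peaks at A·ω² within 3% at default smoothing.
- **Thickness**: lower minus upper boundary at the same column × axial
  spacing ("axial correspondence"); the 12 per-layer thicknesses
  telescope exactly to the ILM–outer-boundary distance.
- **CDF descriptors**: each feature's per-layer samples are reduced to an
  empirical CDF on a fixed global grid — reflectivity: 64 points on
  [−100, 1100]; curvature: 64 on [0, 0.05] /µm; thickness: 64 on
  [0, 300] µm. Fixed grids make descriptors comparable across eyes.
  Slot order is layer-major, feature-minor (reflectivity, curvature,
  thickness). Empty sample sets yield flagged all-zero vectors.

Curvature and thickness are sampled across the full scan width; only
reflectivity is restricted to the parafoveal windows (the windows are
where reflectivity is measured clinically; thickness and curvature are
meaningful everywhere and the text basis for restricting them is absent).

## 4. The two-stage fusion classifier

Each of the 36 slots owns a stacked autoencoder (default 64 → 32 → 8,
sigmoid codes, linear reconstruction) pretrained greedily and
unsupervised on that slot's CDF vectors. Two preprocessing choices are
part of the architecture:

- **per-slot mean centring** before the first layer: across-eye variation
  of a CDF slot is ~1% of its mean shape; without centring the sigmoid
  codes saturate on the mean and carry no discriminative signal;
- **z-scoring of the fused 288-dim code** (training-set statistics,
  stored in the model) before the softmax head, for conditioning.

The nonnegativity penalty (keyword parameter `nonnegativity_weight`,
default 1e-3) is an L1 penalty on the negative part of every weight
matrix, applied as a proximal step — so a large penalty drives negative
weights *exactly* to zero in finitely many steps, unlike a quadratic
penalty whose fixed point keeps an asymptotically small negative part.

All training is deterministic full-batch gradient descent with a
backtracking ("bold driver") step size: a step is accepted only if the
objective does not increase, the rate grows ×1.5 on success and halves on
failure. Loss traces are therefore monotone, and identical seeds give
bit-identical weights (per-slot RNG streams are spawned from one seed
sequence). Encoders are frozen during head training by default; a joint
fine-tuning pass (`fine_tune=True`) is available but off, since freezing
is cheaper, deterministic in fewer steps and sufficient on the synthetic
cohorts.

Stage 1 (screen) trains on all eyes with labels {normal, dr}; stage 2
(grade) trains only on DR eyes with labels {subclinical, mild_moderate}
and rejects normals. Diagnosis thresholds the stage-1 DR probability
(default 0.5) and consults stage 2 only for positives.

## 5. Evaluation

- **Folds** are assigned per subject, never per eye; LOSO gives one fold
  (and one training run) per subject; stratified k-fold shuffles within
  grade (seeded) and deals round-robin, reproducing the cohort mix in
  every fold (80 subjects at 40/20/20, k = 2 → two folds of 20/10/10).
- **Subject-level metrics** by default: a subject's DR score is the max
  over its two eyes (screening convention — one bad eye makes the subject
  a case); eye-level reporting is available (`aggregate="eye"`).
  Sensitivity takes DR (stage 1) and mild/moderate (stage 2) as the
  positive class. Stage-2 metrics are computed over subjects whose true
  label is DR.
- **Leakage guard**: per fold, the train and test subject-id sets must be
  disjoint and the plan must cover every subject; violations raise.
  Encoders are pretrained inside each fold on training eyes only; CDF
  grids and all hyperparameters are fixed a priori.
- **AUC** by the rank (Mann–Whitney) formulation with half-credit ties;
  verified against brute-force pairwise comparison.
- **Bootstrap 95% CI**: percentile method over 2000 resamples of whole
  subject records (not eyes), so intra-subject correlation is respected.

## 6. Problem sizes used in validation

The automated suites run: 20 noiseless + 20 noisy phantoms for
segmentation recovery; n = 50 000 samples for LCDG recovery; LOSO on the
default 80-subject cohort (160 eyes, 160 fold-trainings) for both
classifier stages; and a 20-permutation label-shuffle null on a
20-subject cohort with a shortened training schedule — the null
hypothesis (chance-level accuracy when labels are permuted) does not
depend on cohort size, so the smaller cohort is used for it. Classifier
suites build descriptors from the phantoms' ground-truth segmentation,
isolating classification from segmentation error; the end-to-end pipeline
(`octdr run-all`, `examples/06`) segments every eye instead.

## 7. Numerical conventions and degenerate inputs

- Coordinates are 0-based; row 0 is the vitreous side; boundary values
  are fractional rows, so sub-pixel boundary errors in µm are meaningful.
- Rasterisation: pixel row r gets label `#{k : boundary_k ≤ r}`; the
  extractor's transition-midpoint estimate is therefore within 0.5 px of
  the continuous truth by construction.
- Intensity scaling on load is fixed by container bit depth, never
  per-image, so the reflectivity calibration is the only intensity
  normalisation in the pipeline.
- Degenerate inputs fail loudly: scans under 100 px a side, non-positive
  spacings, missing sidecar metadata, boundary files with missing
  boundaries/columns or ordering violations, phantoms whose layers cannot
  fit the image, single-class training labels.
- All writers are byte-deterministic (fixed field order, fixed float
  formats, sorted JSON keys); the pipeline writes a sha256 manifest of
  every artifact and embeds a provenance block (config hash, seed,
  package version) in each report. One global seed fans out to per-stage
  seeds by fixed offsets.

## 8. Known limitations

- The phantom's laminar geometry cannot produce layer dropout, cysts,
  detachments or other focal pathology; the segmentation model has no
  mechanism for topology changes.
- Translation-only atlas registration assumes fovea-centred scans of a
  single size; real data would need at least a scaling degree of freedom.
- The label→class tie is scan-adaptive but assumes the atlas argmax bands
  overlap the true layers substantially; grossly decentred scans would
  break it before anything else.
- Classifier hyperparameters (code dimension 8, two hidden layers, fixed
  schedules) were chosen for determinism and desk-scale cohorts, not
  tuned for maximal accuracy.
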