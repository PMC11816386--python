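# Methods

This note records the models implemented in `nirtrace`, the defaults and
numerical choices behind them, and what the synthetic data can and cannot
establish.

## Synthetic spectra

Real origin-labeled NIR spectra of produce are rarely deposited, so the
package ships a generator whose default configuration mirrors a realistic
study design: five origin classes sized (100, 100, 100, 96, 94) — 490
fruit — three replicate scans per fruit, 1556 grid points spanning
10,000 → 4000 cm⁻¹ (descending, the FT-NIR export convention), and ~2.5%
gross outliers.

Each scan is built as

```
x(ν) = g · [ baseline(ν) + Σ_b (A_b + Δ_b,class + j_b) · G_b(ν + δ) ]
       + o + s·u(ν) + c·u(ν)² + wander(ν) + ε(ν)
```

with, per sample: multiplicative gain `g ~ N(1, 0.03)`, offset
`o ~ N(0, 0.05)`, linear/quadratic drift coefficients `s, c`, a smooth
baseline *wander* (40 cosine modes with 1/j-decaying coefficients, sd
0.02), a global peak shift `δ ~ N(0, 4 cm⁻¹)`, and per-band constituent
jitter `j_b` (sd 0.019, scaled by each band's class sensitivity); per scan,
white noise `ε ~ N(0, 0.006)`, so averaging three scans reduces the noise
sd by √3. The twelve Gaussian bands sit at the constituent wavenumbers of
citrus fruit (water 5200/6890/8500, vitamin C 5370/8270, fructose
6365/6536, fruit acid 6238/7223/8700, dry matter 4450/5965 cm⁻¹). Class
identity enters only through the band-amplitude offsets `Δ_b,class`, which
combine an ordered "rank" component (mean absorbance ordered
ZG > FJ > XG > XF > XW in the 4000–5230 and 5380–7100 cm⁻¹ zones) with a
fixed idiosyncratic pattern per class. Outliers are samples whose gain or
offset is perturbed by 10 standard deviations.

Each noise term exists to exercise one pipeline stage: white noise is what
SG smoothing removes; offset, drift and the multi-mode wander are what the
first derivative removes; gain scatter is what MSC removes; the
amplitude-like rank component is what MSC *wrongly* normalizes away
(penalizing MSC-containing strategies); constituent jitter sets the
irreducible class overlap; peak shifts add a nonlinearity no amplitude-
linear model can capture. The levels were calibrated once, against the
frozen default seed, so that a PLS-DA probe on SG+FD spectra lands in the
realistic 80–90% band while the CNN exceeds it, and then frozen; they are
not re-tuned per experiment.

What the generator does **not** emulate: radiative-transfer physics of
diffuse reflectance, non-Gaussian band shapes (Lorentzian wings,
saturation), wavelength-dependent scatter, instrument drift between
sessions, or biological covariance between constituents. Passing tests on
this generator therefore demonstrate that the algorithms behave correctly
under the stated noise model — not that any particular accuracy will be
reached on real fruit.

## Outlier screening

The sample covariance of ~490 spectra in 1556 dimensions is singular, so
Mahalanobis distances are computed on PCA scores retaining 99% of variance,
capped at 10 components. The threshold is `mean(d) + 3·sd(d)`, one pass;
both the multiplier and the component cap are arguments. Screening runs
before the train/test split, on replicate-averaged samples.

## Preprocessing

- SG defaults: window 11, polynomial order 2 (quoted nowhere in the source
  literature for this problem class; both exposed).
- The first derivative is taken with respect to the wavenumber *values*
  (absorbance per cm⁻¹), so a descending grid does not silently flip signs.
  Default kernel: the SG first-derivative filter with the same window/order
  (standard chemometric practice and the natural reading of "SG+FD");
  central differences are available as a cross-check, and are used
  automatically on non-uniform grids.
- MSC regresses each spectrum on a reference and returns `(x − b)/a`; the
  reference is the **training-set** column mean only, frozen into the
  `FittedPreprocessor` and reused on test data — fitting it on all data
  would leak.
- Combined strategies compose SG → MSC → FD, matching the order the names
  are written in.

## PLS-DA

NIPALS PLS2 of the one-hot class matrix on column-centered spectra;
centering statistics live in the model. Coefficients are
`B = W (PᵀW)⁻¹ Qᵀ`; prediction is `argmax` over the K continuous outputs
with ties broken toward the lower class index (numpy's argmax convention,
documented). The latent-variable count is the *smallest* count attaining
the maximal stratified k-fold CV accuracy (default 10 folds, cap 20
components); one NIPALS fit per fold at the cap supplies every truncated
model because the factors are nested. Convergence: inner-loop tolerance
1e-10 on the score vector, 500 iterations max.

## Classical baselines

LDA runs on PCA scores with the component count chosen by CV; SVM and
random forest are tuned by exhaustive grid search (scikit-learn
`GridSearchCV`, seed-fixed folds); the BPNN is a single-hidden-layer MLP
(64 units, learning rate 0.001, up to 500 epochs) behind a standard
scaler. Two grid sets ship: `DEFAULT_GRIDS` (the full candidate sets) and
`COMPACT_GRIDS` (same knobs, fewer candidates) used by the comparison
tests and the acceptance script so a full model comparison finishes in
minutes on one CPU. All grids are overridable per run.

## The 1-D CNN

Architecture: `n` blocks of conv1d (32 filters, odd kernel, stride 1,
same-padding) → batch normalization → ReLU → max-pool(2), then flatten and
one fully connected softmax layer; defaults `n = 3`, kernel 3, batch 16,
learning rate 1e-4, 25 epochs. Forward and backward passes are implemented
directly in numpy (im2col convolution, batch-norm with running statistics
at momentum 0.1 and eps 1e-5, argmax-routed pooling) and verified against
central-difference gradients in the test suite. Choices the architecture
itself does not pin down:

- **Optimizer** Adam (β₁ 0.9, β₂ 0.999, eps 1e-8): the de-facto default at
  learning rates of this magnitude.
- **Loss** multiclass cross-entropy on the softmax outputs.
- **Initialization** He-normal for conv and dense weights.
- **Input scaling**: per-wavenumber mean-centering with one *pooled*
  standard deviation (`scaler="global"`, stored with the model). A full
  per-wavenumber z-score is available, but it rescales nuisance-only
  channels (flat regions between bands) to unit variance, which measurably
  degrades generalization on every fixture we tested; preserving relative
  channel magnitudes is the better prior for derivative spectra.
- **No dropout** by default; a `dropout` config flag exists.
- **Determinism**: one `numpy` generator, seeded from the config, drives
  initialization and the per-epoch shuffler; reruns on one platform are
  bit-identical. Training is float32; gradient checks use a float64
  instantiation of the same layers.
- A non-finite training loss aborts with a diagnostic rather than
  returning a half-trained model.

The hyperparameter sweep trains one model per candidate value along a
single axis — layers {2,3,4}, kernel {3,5,7}, batch {8,16,32}, learning
rate {5e-5, 1e-4, 5e-4} — holding everything else (and the seed) fixed.

## Wavelength selection

All regression-based selectors code the classes as a one-hot matrix and
average RMSECV over its columns; the multiclass encoding is otherwise
arbitrary and is stated here because no convention dominates.

- **LAR**: least-angle path per class column (scikit-learn `lars_path`),
  variables merged by earliest entry position (ties: lower column, then
  lower index); the retained prefix length is chosen by PLS-DA CV accuracy
  over a ~12-point geometric ladder of prefix sizes.
- **CARS**: 50 Monte-Carlo runs, 80% row subsampling; run *i* keeps the top
  `r_i = a·e^(−k·i)` fraction of variables by PLS coefficient magnitude
  (L2 norm over class columns), calibrated so `r_1 = 1` and
  `r_N = 2/p`; adaptive reweighted sampling then draws 5× the scheduled
  count with replacement, so heavily weighted variables almost surely
  survive while low-weight ones may drop out and the survivor count tracks
  the schedule. Winner = minimal 5-fold RMSECV.
- **UVE**: appends `p` uniform-noise columns, collects PLS coefficients
  over 10-fold resampling (k-fold rather than leave-one-out for desk-scale
  speed), stability `c_j = mean/sd` maximized over class columns; keeps
  real variables whose stability exceeds the best noise column's.
- **SPA**: from every candidate start column, greedily adds the column with
  the largest component orthogonal to the span of the chain; chains are
  scored by 5-fold RMSECV of an intercepted multiple linear fit. Duplicate
  or rank-deficient columns have zero orthogonal norm and stop the chain.
- **GA**: binary chromosomes, population 64, 30 generations, tournament
  size 3, one-point crossover at rate 0.8, bit-flip mutation at rate 1/p,
  elitism 1. Fitness = stratified CV accuracy of PLS-DA on the active
  columns minus `0.1 ×` active fraction; all-zero chromosomes score −∞.
  Fitness CV uses 5 folds and a 5-component cap (exposed) so a run
  completes in about a minute at p = 400; chromosomes initialize at 10%
  density, which both speeds fitness evaluation and matches the sparse
  subsets the penalty targets.

Subset sizes are outcomes, never forced to any reference count.

## Evaluation

Precision/recall/F1 are macro-averaged (unweighted over classes; weighted
averaging would be a one-line change but macro matches the reporting
convention of origin-traceability studies with near-balanced classes).
Percentages print to two decimals. Cross-validation is stratified, runs on
the training partition only, and refits all train-derived preprocessing
state inside each fold — the no-leakage contract is itself tested with a
memorizing model. The comparison harness isolates failing cells: one
model's exception flags its row and the rest of the table still fills.

## Problem sizes

The test suite and acceptance script run the full study-scale pipeline
(490 samples × 1556 wavenumbers, 25-epoch CNN) once per session and reuse
it across checks; unit tests use a 256-point grid with 60–125 samples. The
selector benchmark uses 200 samples × 400 variables with 20 informative,
median enrichment over 5 seeds. These sizes keep a complete run in minutes
on a single CPU core while preserving every qualitative contrast the
package is designed to reproduce.

## Known limitations

- The calibrated orderings (SG+FD best strategy; CNN above every baseline)
  are regression properties of the frozen default seed, not laws; at other
  seeds the 96-sample test set gives ±4-point swings and close competitors
  can swap ranks.
- The outlier screen is a single-pass global rule; per-class screening and
  robust covariance (MCD) estimators are out of scope.
- PLS-DA assumes the argmax decision rule; no probability calibration is
  attempted for any model.
- The CNN trains on CPU; no GPU path exists or is needed at these sizes.
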