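# Methods

`ramanced` implements a complete diagnostic-classification pipeline for
plasma Raman spectra of celiac disease (CeD) versus healthy controls:
synthetic cohort generation, spectral cleanup, PCA exploration, four 1-D
deep classifiers with two classical baselines, and a patient-level
cross-validated evaluation harness. The clinical spectra that motivated
the pipeline are not publicly available, so every stage is developed and
validated against synthetic cohorts whose statistical structure matches
what the analysis assumes.

## Synthetic cohort model

A cohort has `n_ced = 29` and `n_control = 30` patients with
`replicates_per_patient = 3`, giving 87 + 90 = 177 spectra on a uniform
wavenumber grid over 500–2500 cm⁻¹ (step 2 cm⁻¹, 1001 channels; the grid
span is the acquisition range, and the step is a package choice — the
digitized point count of the instrument is not modeled, only informed by
its ≈6 cm⁻¹ optical resolution through the default line widths).

Each spectrum is

```
I(ν) = s_p · Σ_k A_k · e_k^{[group=CeD]} · L(ν; c_k, w_k)  +  B(ν)  +  η_p(ν)  +  ε_{p,r}(ν)
```

* **Peaks** `L` are Lorentzian by default (the natural Raman line shape;
  Gaussian available), unit height at the center `c_k`, half-width at
  half-maximum `w_k` (default 6–12 cm⁻¹, i.e. FWHM 12–24 cm⁻¹).
* **Class effects** `e_k` multiply peak amplitudes for CeD only. The seven
  differential bands follow the reported direction of change in CeD
  plasma: higher at 1402 (methyl bending), 1477 (calcium oxalate), 1518
  (cytosine), 1545 (NADH/tryptophan), 1715 and 1772 cm⁻¹ (C=O lipids) —
  defaults e = 1.15–1.20 — and lower at 1445 cm⁻¹ (e = 0.85). Effect
  sizes of ±15–20% are in the range of relative band-intensity changes
  reported for biofluid Raman disease studies, large enough for a deep
  model to exploit after preprocessing and small enough that the classes
  overlap heavily at most channels. Sixteen class-neutral bands at
  standard plasma positions (phenylalanine 1002, amide I 1655, amide III
  1250, tyrosine/tryptophan lines, …) ensure no single channel trivially
  separates the classes.
* **Background** `B` is a shared cubic polynomial (in the normalized grid
  coordinate) plus one broad Gaussian (center 1100 cm⁻¹, σ = 400 cm⁻¹,
  amplitude 3) mimicking fluorescence; amplitudes put the background at
  roughly 4–8× the peak scale, as in real biofluid spectra.
* **Patient variability**: a log-normal global intensity scale `s_p`
  (σ_log = 0.1 — plausible pipetting/focus variation; no inter-patient
  variance model is available to copy) and a per-patient channel offset
  `η_p` (SD 0.02) shared by that patient's replicates, so patient identity
  carries irreducible information beyond the class label.
* **Replicate noise** `ε` is i.i.d. Gaussian per channel (SD 0.05 by
  default; a shot-noise-like heteroscedastic mode is available). The
  default SD was calibrated once so the generator reproduces the
  replicate-QC property the cohort description states — mean
  within-patient pairwise Pearson correlation ≈ 0.99 (measured ≈ 0.999).
  The source text is ambiguous about whether the 0.99 figure refers to
  within-patient or between-patient correlation; the generator targets
  the within-patient reading, which is the quantity its own QC figures
  display.

Draw order is fixed and everything derives from a single integer seed, so
a `CohortSpec` reproduces its cohort bit for bit.

### What the generator does not emulate

Cosmic-ray spikes, wavenumber miscalibration/drift, detector etaloning,
water/substrate bands, class-conditional covariance structure beyond the
seven band effects, demographic confounders, and instrument response.
Consequently, passing benchmarks here demonstrates that the pipeline and
models are implemented correctly and can exploit class structure of the
stated kind at the stated noise level — not that comparable accuracy
would be obtained on clinical spectra.

## Preprocessing

Stage order: airPLS baseline subtraction → Savitzky–Golay smoothing →
Fourier filtering (per spectrum) → replicate averaging → normalization
(per spectrum). Each output spectrum carries a stage log with the exact
parameters applied.

* **airPLS** (adaptive iteratively reweighted penalized least squares)
  solves the weighted Whittaker system `(W + λD′D) z = W x` with a
  second-difference penalty; after each solve, weights become 0 where the
  residual `x − z` is non-negative (peaks) and `exp(t·|d_i|/|d|₋)` where
  negative. Defaults λ = 1e5, 15 iterations, convergence ratio 1e-3 —
  standard airPLS practice; λ = 1e5 tracks the synthetic cubic + broad
  Gaussian background to within 2% relative RMS on the 1001-point grid.
* **Savitzky–Golay**: window 5, order 2 (as stated for the study), via
  `scipy.signal.savgol_filter` with polynomial boundary handling, so
  polynomials up to the fit order pass through exactly.
* **Fourier filter**: the study's description of this step is
  self-contradictory (noise elimination versus "removing low-frequency
  components"). Default here is a **low-pass** at 0.15 of Nyquist —
  noise suppression, with the slowly varying background already handled
  by airPLS; a high-pass mode is retained for the literal reading, plus a
  band-pass. Stop-band bins of the real FFT are zeroed outright; note
  that for even-length signals the Nyquist bin sits at normalized
  frequency exactly 1 and is therefore removed by any cutoff < 1.
* **Averaging** of each patient's replicates happens after filtering and
  before normalization by default; the position is configurable
  (`after_filter` / `after_normalize` / `off`) because the original
  ordering is unstated, and the choice is recorded in the stage log.
* **Normalization** is min–max to [0, 1] per spectrum by default (the
  method used in the study is unstated); unit-vector and unit-area
  normalization are selectable. Min–max is undefined for constant input
  and raises.

## Exploration

Z-score standardization is per wavenumber with the unbiased (ddof = 1)
SD; zero-spread columns are left centered and flagged. PCA is an SVD of
the centered matrix; the number of retained components is the smallest k
whose cumulative explained-variance ratio reaches the target (default
0.85, exposed as a parameter). Loading signs follow a fixed convention —
the largest-magnitude element of each loading is made positive — so
scores and loadings are reproducible. The per-wavenumber SD profile is
computed on unstandardized data (standardized columns all have SD 1).
PCA is exploratory only; no PCA-based classifier is built, because the
low-dimensional separation of the two groups is poor and classification
is delegated to the deep models.

## Classifiers

All four deep families are implemented in numpy with explicit
backpropagation (every layer is finite-difference gradient-checked), run
on (batch, channels, length) arrays, and end in a 2-unit softmax head.
CeD is class 1.

* **CNN** — four conv stages with 32/64/64/32 filters (fixed by the study
  design) and max-pool 2 after each; flatten → dense 64 → dropout →
  dense 2. Kernel size 9 and the pooling schedule are package choices.
* **MCNN** — three parallel branches with 16/32/64 filters and kernel
  sizes 4/8/16, stride 1, 'same' padding, leaky rectifiers (α = 0.01) and
  max-pool 4, concatenated along channels, then one conv (32 filters,
  kernel 9) + pool and a dense head. A flatten head is used rather than
  global pooling: the discriminative signal lives at specific
  wavenumbers, and global average pooling after so shallow a stack
  destroys that positional information (measured as a drop from perfect
  to chance accuracy on the default benchmark).
* **ResNet** — initial conv(32, k9) + batch norm + max-pool 4, then three
  residual units (32/64/64 filters; strides 1/2/2) of two conv+BN blocks
  each with a projection (1×1 conv + BN) shortcut when shapes change,
  dropout after each unit, global average pooling, dense 2.
* **DRSN** — identical topology plus a channel-wise shrinkage gate after
  the second BN of every residual unit, so the DRSN-vs-ResNet comparison
  isolates the shrinkage mechanism. The gate computes the per-channel
  mean absolute activation `a_c`, squeezes the vector through a two-layer
  fully connected bottleneck (reduction 4, batch norm + rectifier in
  between; the second layer has one sigmoid output per channel), and soft
  thresholds each channel at `τ_c = sigmoid(·)·a_c ∈ [0, a_c]`:
  `y = sign(x)·max(|x| − τ_c, 0)`.
* **SVM / KNN** — scikit-learn, RBF kernel with C = 1 and k = 5 (the
  baselines are named in the study without settings). SVM scores are a
  monotone sigmoid of the decision margin rather than Platt scaling,
  which is unreliable (and can invert rankings) at n ≈ 40.

**Training** (all deep families): Adam at 1e-3, batch size 8,
cross-entropy, dropout 0.5, up to 200 epochs with early stopping
(patience 20, min-delta 1e-4) on the loss of a stratified 20% validation
carve-out, best weights restored. Everything is seeded (weight init,
shuffling, dropout, the carve-out), so a seed reproduces a training run
exactly. Because dropout inflates activation variance, batch-norm running
statistics collected during training systematically overestimate the
inference-time variance and shift eval-mode logits; the trainer therefore
recalibrates all BN statistics with one dropout-free full-training-set
pass before each validation evaluation and after the final weight
restore.

## Evaluation

Splits operate on patient identities only (each patient's spectra are
averaged to one trace before modeling, and the harness refuses any plan
where a patient appears on both sides). The default 7:3 split takes
⌈0.3·59⌉ = 18 test patients (41 train), stratified to within one patient
per class. The study prints 40/19 for the same ratio; that allocation is
not what ceiling-on-test (or floor-on-test, 42/17) rounding produces, so
the harness exposes `test_fraction` and the rounding mode explicitly and
documents the discrepancy rather than forcing 40/19. Five-fold CV
round-robins the training patients by class; fold sizes differ by at most
one.

Metrics follow the standard confusion-matrix definitions with CeD
positive: accuracy, sensitivity TP/(TP+FN), precision TP/(TP+FP), and
specificity TN/(TN+FP). A `literal` specificity mode computing TN/(TN+FN)
is kept behind a flag because that variant (actually negative predictive
value) circulates in the applied literature; the standard definition is
the default. Zero-denominator metrics are reported as missing, never as
0. ROC curves come from a full threshold sweep with tied scores grouped
into single steps; AUC is the trapezoidal area and equals the
Mann–Whitney U statistic over n₊n₋ (asserted to 1e-10 in tests).

`run_comparison` reports, per family, the five-fold CV mean ± SD on the
training patients and the held-out test-set metrics from a final model
refit on the full training set — the held-out numbers are the headline,
CV the dispersion context — plus seeded percentile-bootstrap (1000
resamples) 95% intervals. Since every family's hyperparameters are fixed,
CV selects nothing; it is reporting.

## Benchmark protocol and problem sizes

The surrogate headline benchmark trains the DRSN on the default
59-patient cohort through the full pipeline and scores the held-out 18
patients; `scripts/acceptance.py` averages accuracy and AUC over five
seeded repetitions of the entire protocol (generation through scoring)
and reports the replicate-QC Pearson mean. The script trains the final
model directly on the full training split — re-running the five-fold CV
inside it would alter no result (nothing is selected) and is exercised
separately by `run_comparison` and its tests.

The DRSN-versus-ResNet paired comparison (five seeds, doubled replicate
noise — SD 0.10) runs at full size: it is a paired ≥ over seed means, and
individual seeds can go either way at n_test = 18, so it is not scaled
down. The label-permutation control, by contrast, is a symmetric
chance-band check and runs on 40 single-replicate patients over a
128-channel grid with a short epoch budget. One caution for anyone
re-scaling the benchmark: the Fourier cutoff is a fraction of Nyquist, so
on a coarser grid the same fraction removes proportionally more physical
bandwidth — a faithful miniature must scale the cutoff with the grid step
(e.g. 0.6 on an 8 cm⁻¹ grid matches 0.15 on the 2 cm⁻¹ grid), and the
filtering regime materially changes what the models can learn.

## Known limitations

* Single-threaded numpy training is the speed bottleneck; the
  architectures are sized for hundreds-of-channels spectra and dozens of
  patients, not for large cohorts.
* Binary classification only; no calibration analysis; no hyperparameter
  search.
* The synthetic benchmark's difficulty is set by generator defaults;
  absolute accuracies on it say nothing quantitative about clinical data
  (see the generator's non-goals above).
* Determinism holds for a fixed BLAS/thread configuration; bit-identical
  results across different BLAS builds are not guaranteed.
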