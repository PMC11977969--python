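# Methods

This note documents the models and procedures implemented in `specfuse`,
the parameter defaults and why they were chosen, what the synthetic
benchmarks emulate (and what they do not), and the numerical decisions a
maintainer should know about.

## Data model

A `SpectrumSet` is a wide matrix of spectra on one shared, strictly
increasing channel axis (cm⁻¹ for Raman/SERS, nm for NIR) with one
concentration label (mol/L) per sample. Axis units are metadata only; no
nm↔cm⁻¹ conversion or resampling is performed, and fusing modalities never
mixes axes — fused matrices carry a per-column provenance map instead.

The calibration/prediction split is stratified by concentration level:
exactly `n_cal_per_level` replicates of every level go to calibration
(default 6 of 10, giving the 36/24 split used throughout), the rest to
prediction. Selection within a level is uniform at random under a seed.

The modelled response is log₁₀ concentration by default. The benchmark
concentration grid spans 10⁻⁶–10⁻³ M in 6 log-spaced levels; on a
three-decade grid a linear-concentration response would be dominated
entirely by the top level, while the log response weights all levels
equally. Linear response mode is available.

## Preprocessing

Operators: AirPLS baseline estimation, multiplicative scatter correction
(MSC), standard normal variate (SNV), Savitzky–Golay smoothing, and
min–max scaling. Pipelines are ordered step lists whose stateful steps
(the MSC reference spectrum, per-set min–max bounds) are fitted on the
calibration set only and applied unchanged to prediction data, so no
information leaks across the split.

* **AirPLS** is the iteratively reweighted Whittaker smoother with a
  second-order difference penalty: points above the running baseline get
  exponentially vanishing weight (`wᵢ = exp(t·|dᵢ|/Σ|d⁻|)` at iteration t
  for negative residuals, 0 otherwise); iteration stops when the residual
  mass below the baseline falls under 0.1 % of the signal mass, or at 30
  iterations. Default smoothness λ = 10⁵ for NIR, 10⁴ recommended for
  SERS (sharper peaks tolerate a stiffer baseline than they need; these
  values keep a linear ramp fully removable while a Gaussian peak of unit
  height loses < 5 %).
* **Savitzky–Golay** defaults: window 11, polynomial order 2, derivative 0;
  edges are handled by polynomial fit on the truncated window.
* **Min–max** scales to [0, 1] either per spectrum or per set. The shipped
  presets use per-set mode: the point of the normalization step is to bring
  the two modalities' intensities to a common scale, and per-spectrum
  rescaling destroys exactly the intensity information that encodes
  concentration whenever the analyte peak is the largest feature of its
  spectrum. Per-spectrum mode remains the operator's own default for
  standalone use.
* Presets: `sg-snv-msc` (default; smoothing → SNV → MSC → min–max) and
  `airpls-msc-sg` (baseline-first chain); both orders appear in practice,
  and the pipeline is fully configurable.

## PLSR

Univariate NIPALS (PLS1) with mean-centered X and y. For a single
response the algorithm is non-iterative: each component's weight vector is
the normalized covariance `w = X'y/‖X'y‖`, with rank-one deflation after
each component. Models expose per-component regression vectors, so the
RMSECV curve over 1..L components costs one fit per fold. Component
extraction stops early if the residual covariance vanishes (‖X'y‖ <
10⁻¹⁴). Fitted models agree with an independent NIPALS implementation to
well below 10⁻⁸ on random data (verified in the test suite).

K-fold cross-validation uses a seeded random partition with fold sizes
differing by at most one; held-out squared errors are pooled over folds
before the root. Ties in the best component count break toward fewer
components (parsimony).

**Metrics.** RMSE on the response scale; R² = 1 − SSres/SStot; RPD
defaults to sample sd(y)/RMSE (the standard chemometrics ratio of
performance to deviation, with the n−1 standard deviation). The closed
form 1/√(1−R²) is available as an option; the two differ by the factor
√((n−1)/n) and by the difference between prediction-set bias and variance,
and published tables in this field are frequently inconsistent between
them at the third decimal. Perfect fits report RPD = ∞ rather than
raising.

## HSIC

The biased empirical estimator `HSIC = (n−1)⁻² tr(KHLH)` with
`H = I − n⁻¹ee'`. Default kernels are Gaussian RBF,
`k(x,x′) = exp(−‖x−x′‖²/2s²)`, with the median pairwise distance as
bandwidth s; a linear kernel is provided for closed-form oracle tests.
Centering makes the statistic exactly zero when either argument is
constant; tiny negative round-off (> −10⁻¹⁰) is clamped to zero, anything
more negative raises. The estimator equals the literal double-loop
evaluation to 10⁻¹⁰ and, under independence, stays below the
permutation-null 99th percentile at the expected rate (both verified in
the suite).

## The HSIC-VSIO selector

Per run:

1. **Importance (once).** For each channel m, `WIₘ = HSIC(y, εₘ)/HSIC(y,
   ε_full)` from leave-one-channel-out PLSR residuals. Residuals are
   **cross-validated** (out-of-fold predictions) by default: with n ≪ p a
   PLSR's training residuals are dominated by overfitting and carry no
   predictive signal, and the importance ratio computed from them is
   empirically indistinguishable from noise. `residual_mode="training"`
   restores training residuals for comparison. The ratios are averaged
   over `n_repeats` (default 2) independent fold partitions; `T′ = T/max T`.
2. **Iteration.** Weights start at 0.5. Each iteration samples an `M × p`
   binary matrix (column i holds exactly `round(M·wᵢ)` ones; an all-zero
   row is repaired by moving one 1 from a row holding at least two, which
   preserves every column count), scores each row's channel subset by the
   minimum of its 1..L RMSECV curve, records the iteration minimum,
   computes top-σ frequencies `Q` (denominator `round(M·σ)`, tie at the
   cutoff broken by row index), and sets `W = 0.5T′ + 0.5Q`. The CV fold
   partitions are drawn once per run and reused in every iteration, so
   subset ranking and the RMSECV trace are not perturbed by partition
   noise — without this the iteration-best trace stalls on partition luck
   after one or two rounds.
3. **Stop and output.** The loop stops at the first iteration whose
   minimum RMSECV fails to improve (or at 50 iterations); the selection is
   the K largest final weights, ties toward the lower channel index. The
   best sampled model's channel set and the full trace are reported.

Defaults M = 1000, σ = 0.10, K = 20, L = 10, 5 folds. The desk-scale
benchmarks below use M = 200 (planted recovery, where p = 200) and M = 500
(fusion comparison, where p is 500–700 and subset-frequency statistics at
M = 200 were visibly unstable).

## Fusion

Direct fusion concatenates the two full preprocessed matrices (NIR block
first); feature-level fusion concatenates the per-modality selections.
Sample alignment is enforced by id equality, and fusing unscaled inputs is
an error (overridable). The four-way comparison (NIR, SERS, direct,
feature-level) picks each model's component count from a grid by 5-fold
RMSECV on calibration data, then reports calibration fit (RMSE1, Rc²) and
prediction metrics (RMSE2, Rp², RPD). Calibration-set numbers are training
fits, not cross-validated.

## Synthetic benchmarks

The generator composes, per sample: analyte peaks (Gaussian or Lorentzian;
height = response × log₁₀(c/c_ref) by default, c_ref = 10⁻⁷ M, or linear
in c), fixed background bands with per-band height jitter, a fixed
polynomial baseline plus a per-sample random quadratic drift, optional
high-rank "clutter" (many minor bands at fixed random positions whose
amplitudes vary independently per sample), an affine scatter distortion
(multiplicative and additive draws), and white channel noise. Ground truth
records the informative channels (within ±2 widths of an analyte peak
center) and the per-sample scatter draws.

Both default modalities respond log-linearly in concentration. A strictly
linear SERS response was rejected for the benchmark: against a log-scale
response spanning three decades it makes the bottom half of the
concentration grid invisible to any linear calibration and caps
single-modality SERS far below the performance regime this method operates
in; physically, SERS peak heights saturate with substrate surface coverage
and are closer to log-linear over a wide concentration range.

* **SERS (sharp):** 400–1800 cm⁻¹, 700 channels; Lorentzian analyte bands
  at 609/990 (chlorpyrifos-like) and 558/990 cm⁻¹ (pymetrozine-like),
  width 8 cm⁻¹; solvent bands at 740/910/1040/1370 cm⁻¹ comparable in
  height to the analyte signal; 10 % per-sample enhancement jitter per
  analyte (the well-known SERS reproducibility limit); 38 clutter bands
  (width 12, amplitude sd 0.055).
* **NIR (broad):** 1000–2500 nm, 500 channels; Gaussian analyte bands
  (width ≥ 60 nm) overlapped by strong, per-sample-variable matrix bands —
  a moisture band at 1450 nm and interferents directly on the analyte
  regions — plus pronounced baseline drift, scatter, and 15 broad clutter
  components.

The error structures are deliberately asymmetric and mutually independent:
SERS is the stronger single modality (sharp, specific, limited by
enhancement jitter), NIR the weaker (trace signal under variable matrix
absorption), and their fusion can average independent errors. The
high-rank clutter matters: interference spanned by a handful of directions
is simply absorbed by one or two extra PLSR components, leaving nothing
for channel selection to do; with more variable directions than components
the selector's ability to avoid contaminated channels is what
feature-level fusion's advantage rests on. These magnitudes were chosen so
the benchmark reproduces the qualitative structure of a real mixed-residue
study (single-modality RPD ≈ 2.5–3.5, fusion above singles,
selection-based fusion best); they are not fitted to any measured dataset,
and passing benchmarks on them demonstrates correct mechanics and the
expected ordering, not performance on real instruments. Real spectra
additionally contain wavelength-dependent detector response, peak shifts,
cosmic-ray spikes and nonlinear detector saturation, none of which are
modelled.

* **Planted recovery benchmark:** 200 channels with eight single-channel
  analyte bands at characteristic positions (558/609/627/673/990/1095/
  1166/1294 cm⁻¹), Gaussian width ¼ channel spacing so exactly one channel
  per band is informative; channel noise sd 0.15 so no single channel
  suffices and every recovered channel measurably improves prediction.
  This makes "which channels does the selector find" well-posed: with the
  default 8 cm⁻¹ peak widths ~50 channels are informative and a top-20
  selection could never contain 75 % of them, and with near-noiseless
  channels all planted channels are mutually redundant and no selector
  (nor the leave-one-out importance) can distinguish them from their
  neighbours. Recovery is measured on the raw simulated spectra; the
  smoothing/normalization chain exists for realistic band-shaped data and
  smears single-channel plants by construction.

## Numerical choices and edge cases

* NIPALS inner tolerance is irrelevant for PLS1 (non-iterative); component
  extraction stops at ‖X'y‖ < 10⁻¹⁴.
* `evaluate` raises on zero-variance reference values; perfect fits return
  RPD = ∞, not an error.
* `wavelength_importance` raises when the full-spectrum HSIC is exactly
  zero (perfect fit leaves nothing to rank).
* Subset models whose PLS fit degenerates score NaN; more than 50 % NaN in
  one iteration raises an instability error.
* CSV round-trips are bit-exact: floats are written in shortest
  round-trip representation and parsed with round-trip precision.
* All randomness flows through `numpy.random.SeedSequence` spawning, so
  every public entry point is reproducible from a single integer seed and
  identical CLI invocations produce byte-identical outputs.

## Known limitations

* The selector's frequency signal needs channels with partially
  independent information; sets of mutually near-duplicate channels (e.g.
  one noiseless analyte band sampled by many channels) are interchangeable
  to it, and which representative gets selected is arbitrary.
* Leave-one-channel-out importance is blind to redundancy by construction
  (removing one of two duplicates changes nothing); it contributes ranking
  signal only for channels that are individually load-bearing.
* Supplementary figure-source spreadsheets are read by auto-detecting the
  strictly monotone numeric column as the axis; workbooks with several
  monotone columns (e.g. an index column) need manual handling.
* `compare_methods` evaluates one response; multi-analyte calibration with
  separate responses per analyte is out of scope.
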