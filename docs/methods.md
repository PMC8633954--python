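# Methods

This note documents the models, conventions and design choices behind
`pkmetab`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Non-compartmental analysis

NCA is model-free: every parameter is a functional of the sampled
profile.

* **Cmax/Tmax** — maximum quantifiable concentration and its sampling
  time. Ties go to the earliest time: a deterministic stand-in for the
  "visual inspection" of practice, and the only choice that makes the
  operation a pure function of the data.
* **AUC₀₋ₜ** — linear trapezoidal rule in every segment. No log-down
  variant is offered; on the dense grids and monotone tails simulated
  here the difference is far below the assay noise, and a single rule
  keeps results comparable across subjects.
* **Ke** — ordinary least squares of log₁₀C on t over the last
  `n_points` (default 3, minimum 2) quantifiable samples, multiplied by
  −ln 10. The conversion uses ln 10 at full precision rather than the
  conventional 4-digit 2.303, so that exact log-linear data recover the
  generating constant to machine precision; t₁/₂ deliberately keeps the
  conventional printed constant 0.693 (not ln 2), because half-life
  values are compared against hand calculations in validation reports.
* **AUC₀₋∞** = AUC₀₋ₜ + C_last/Ke with C_last the *observed* last
  quantifiable concentration, not a regression prediction.
* **Cohort summary** — per-parameter mean and sample SD (n−1), the mean
  of per-subject AUC₀₋ₜ/AUC₀₋∞ ratios ×100 flagged against the 80%
  regulatory extrapolation floor, and max/min fold ranges of AUC and
  Cmax.

**Below-LLOQ (BLQ) handling.** BLQ entries are carried as flags, never
numbers. Flagged values before the first quantifiable sample are treated
as 0 (pre-absorption); all flagged values after that point — whether
after Tmax or interspersed — are excluded from both the AUC and the
terminal regression. The second half of this rule extends the natural
post-Tmax convention to interior BLQ values, which are unspecified in
standard practice; zeroing them would bite into the absorption-phase
area, while exclusion merely bridges the gap linearly.

## Assay-validation statistics

Calibration is weighted least squares of the analyte/IS response ratio
on nominal concentration, minimizing Σwᵢ(yᵢ−axᵢ−b)² with w ∈ {1, 1/x,
1/x²}; 1/x² is the default because bioanalytical assays show
concentration-proportional error over a 250-fold range. The coefficient
of determination of a weighted fit uses the same weights in both the
residual and total sums of squares — otherwise r² of a 1/x² fit is not
a fraction of explained (weighted) variation.

Acceptance conventions, all configurable: ±15% bands for QC levels and
±20% at the LLOQ, applied to both RE% and RSD%; stability fails when
|100 − %of-nominal| exceeds 15 strictly (the boundary passes); carryover
passes when every post-ULOQ blank is ≤ 20% of the LLOQ response,
boundary inclusive (the 20% figure is the regulatory convention for
analyte carryover). Inter-batch statistics pool all replicates of a
level across batches, which is the definition under which a single
batch's intra- and inter-batch blocks coincide exactly.

## Feature-table QC chain

Canonical order: IS normalization → pooled-QC quotient normalization →
QC-RSD filter → dilution-trend filter → cube-root transform → robust
scaling. Filters run on the normalized but untransformed scale, so an
"RSD > 25%" threshold keeps its usual meaning; the transform and scaling
come last because they exist for the regression, not for QC.

* **IS normalization** divides every sample by its internal-standard
  area. The IS feature becomes identically 1 and is retained; as a known
  spiked control it is exempt from all later filters.
* **Pooled-QC quotient normalization** is probabilistic quotient
  normalization with the feature-wise mean of the pooled-QC injections
  as reference: each sample is divided by the median over
  positive-reference features of sample/reference. It is applied to
  study and QC samples only. Dilution-series samples pass through
  unchanged — their whole purpose is a deliberate per-sample
  concentration trend, which the per-sample quotient would cancel
  exactly, blinding the next filter.
* **QC-RSD filter** drops features whose RSD (100·SD/mean, n−1) across
  pooled-QC injections strictly exceeds 25%; a feature at exactly the
  threshold is kept. Zero-QC-mean features are dropped and logged.
* **Dilution-trend filter** keeps features whose Pearson correlation
  with relative concentration (1/dilution factor) is ≥ 0.8 over ≥ 3
  distinct dilution levels. Constant features have undefined r and are
  dropped. With no dilution series acquired, the step logs a warning
  and passes through, since the series is optional in practice. The 0.8
  default is our choice; no standard value exists.
* **Robust scaling** subtracts the median and divides by the IQR
  (Q3−Q1, linear-interpolation quantiles — stated because scaled values
  depend on the quantile rule), with statistics computed on study
  samples only and applied to all samples. Zero-IQR features are
  centered, left unscaled, and flagged.

Every step appends exactly one entry (name + parameters) to the table's
processing log; `feature_qc.replay` re-applies a log to the raw table
and reproduces the processed table bit for bit. Positive- and
negative-ionization tables are processed as independent pipeline runs;
no cross-mode merging.

## Prediction model

The estimator is the elastic net

(1/2n)‖y − β₀ − Xβ‖² + αλ‖β‖₁ + (α(1−λ)/2)‖β‖₂²,

delegated to scikit-learn's coordinate-descent solver (and verified in
the test suite against an independently written coordinate-descent
implementation to 1e-6; α = 0 falls back to an OLS solve, where the
elastic-net solver is undefined). Failure to converge raises an error
rather than returning a silently unconverged fit. The target y is left
in natural units (ng·h/ml for AUC, ng/ml for Cmax) so RMSE is directly
interpretable; all feature scaling happens upstream in the QC chain.

**Metrics.** Explained variance uses the variance form
R² = 1 − Var(y−ŷ)/Var(y), which tolerates a constant offset in the
predictions — this is the "explained variance" score, distinct from the
sum-of-squares R². MAPE = 100·mean(|y−ŷ|/|y|); RMSE in target units.

**Feature refinement.** The nonzero coefficients of an all-feature fit
are ranked by |coefficient| (coefficients being the selection currency
of a linear penalized model; ties break by column order for
determinism). For k = 1…K the top-k subset is refit and LOOCV-evaluated;
the chosen k maximizes LOOCV explained variance, ties to the smallest k.
LOOCV metrics drive the choice because training metrics increase
monotonically in k by construction.

**Evaluation modes.** `replicate-paper` performs this selection once on
the full data and then cross-validates on the chosen subset — the
common published workflow. Because every held-out sample took part in
the selection, its cross-validated metrics are optimistically biased,
and the pipeline logs a warning saying so. `nested` repeats the entire
selection inside every LOOCV fold; a fold whose initial fit selects
nothing falls back to the training-mean prediction. On pure-noise data
the nested mode's mean explained variance stays at chance level — the
test suite and acceptance script verify this null guard — while the
replicate mode may not. Both modes are first-class and labeled in every
output.

**Hyperparameter search.** `grid_tune` exhaustively scores every
combination of a parameter grid by LOOCV explained variance. The
shipped default grid — 20 log-spaced penalty strengths × 10 L1
fractions × 4 tolerances × 6 iteration caps — spans 4,800 combinations;
its individual values are ordinary practitioner choices and are fully
config-overridable. When no explicit penalty is given, the pipeline
picks α by LOOCV over fractions (0.3, 0.1, 0.03, 0.01) of α_max, the
smallest penalty that zeroes all coefficients.

**Diagnostics.** Residuals r = y − ŷ are regressed (OLS) on the
predictions — against predictions rather than true values, configurable,
since a residual-vs-fitted plot is the standard diagnostic — with R²
defined as 0 for zero-variance residuals; histogram counts and normal
probability-plot pairs (ordered residuals vs Φ⁻¹((i−0.5)/n)) complete
the bundle.

## Synthetic cohort generator

**PK model.** One-compartment, first-order absorption:
C(t) = (D/(V/F))·ka/(ka−ke)·(e^(−ke·t) − e^(−ka·t)), sampled on a
20-point 0–72 h grid, multiplied by lognormal assay noise, censored at
the LLOQ (0.2 ng/ml) as explicit BLQ flags. Subject parameters are
lognormal: ka median 0.7/h (CV 30%), ke median 0.0462/h (CV 50%), V/F
median 850 L (CV 30%), dose 20 mg. These medians put the analytic Tmax
near 4.2 h, t₁/₂ near 15 h and Cmax near 20 ng/ml — the scale of a
20-mg oral statin study — and the clearance CV gives a roughly
seven-to-twelve-fold AUC spread across 40 subjects. A draw with ka = ke
(the flip-flop singularity) is redrawn. One deliberate limitation: with
single-compartment kinetics the AUC/Cmax ratio is tied to the terminal
half-life, so matching Cmax and t₁/₂ leaves the absolute AUC scale
higher than a multiphasic real profile would give; conclusions should
rest on the relative spread and recovery behaviour, not the absolute
AUC level.

**Feature tables.** Default 2,609 features per positive-mode table and
2,446 per negative-mode table (typical per-mode counts after raw
processing). A planted subset (default 10) carries
log-abundance = baseline + effect·z + noise with z the standardized
log-clearance, alternating effect sign (effect 1.0, feature noise CV
20%): clearance is the biological determinant of AUC = D/CL, so both
AUC and Cmax inherit correlated signal, and the sign alternation
mirrors metabolites positively and negatively associated with
elimination. All other features are independent lognormal noise.
Pooled-QC injections are the feature-wise study mean times a
multiplicative drift per acquisition-order unit (default 0.2%) times
injection noise (CV 5%); optional "unstable" features get CV 200% QC
noise so that the RSD filter has a well-separated true-positive class.
The five-level dilution series halves concentration per level; optional
"non-diluting" features scale with, not against, the dilution factor.
An internal standard is spiked at constant level (CV 2%) into every
sample. Clinical covariates (default 44) are lognormal with correlation
~0.25 (alternating sign) to standardized log-clearance, so the
clinical-only model is weakly but not entirely uninformative.

**What the generator does not emulate:** multiphasic disposition,
enterohepatic recirculation, transporter saturation, retention-time
drift or m/z miscalibration, correlated metabolite modules, missing
values, or batch-to-batch extraction effects. Passing tests therefore
demonstrate that the *pipeline machinery* is correct and honest under
known truth — not that real predose profiles predict real exposure.

## Problem sizes and numerical conventions

The shipped tests and acceptance script use deliberately modest sizes —
40 subjects × 500 features for the planted-signal run, 20 subjects × 80
features × 20 seeds for the nested null guard, 8 subjects × 20 seeds
for NCA recovery, and a 12-sample dataset for the full 4,800-point grid
sweep — chosen so the whole suite completes in minutes while still
exercising every code path at realistic subject counts.

Other conventions: sample SD (n−1) everywhere except the population
variance inside explained variance (where the ratio makes the
convention cancel); seeds fixed at every stochastic call site;
`numpy.random.default_rng` throughout; quantiles by linear
interpolation; strict-inequality drop rules at filter boundaries;
errors (never silent NaNs) for empty/degenerate inputs.
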