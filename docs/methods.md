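# Methods

## The analysis problem

A hybrid spectrometer records two views of the same sample spot: a LIBS
spectrum (atomic/molecular plasma emission, 2000 wavelength channels over
350–625 nm at 0.33 nm resolution) and a Raman spectrum (molecular
scattering, 600 shift channels over 750–2800 cm⁻¹ relative to a 532 nm
excitation laser). The analysis task is supervised classification of
class-labelled spectra — e.g. distinguishing 16 cheese products or 7
coffee brands — and the question of interest is how much accuracy is
gained by *fusing* the two modalities compared with using either alone.

The chain implemented here is: spectral-axis handling → synthetic data
generation → preprocessing → interfering-line subtraction → fusion →
ANOVA + elastic-net feature selection → repeated cross-validated
classification.

## Axis conversions

Wavelength and Raman shift are linked by `shift = 10⁷(1/λ₀ − 1/λ)` with
λ in nm and λ₀ the excitation wavelength. Conversions use the vacuum
convention with no air-refractive-index correction (a < 0.02 % effect,
irrelevant at 0.33 nm channels). Only the Stokes side is supported. The
overlap of the two modalities on the detector is computed from the
configured spans, not hard-coded: 750–2800 cm⁻¹ at 532 nm maps to
554.1–625.1 nm, intersecting the LIBS span at [554.1, 625.0] nm.

## Synthetic data generator

Real food spectra from hybrid instruments are not publicly available, so
the pipeline is exercised on a generator that reproduces their key
statistical structure. A spectrum is

```
y(x) = baseline(x) + g · Σ_p  A_p · M_cp · J_rp · f_p(x) + ε(x)
```

* `f_p` — unit-height peak profiles: Lorentzian lines for LIBS (CN 388.2,
  Ca II 393.4, Ca I 422.7, C₂ 516.2, Na 588.9 nm; FWHM 0.7 nm ≈ 2
  channels), Gaussian bands for Raman (cheese-like family: 890, 1287,
  1432, 1670 cm⁻¹; coffee-like family: 1440, 1570, 1650 cm⁻¹; FWHM
  12 cm⁻¹). The Ca line positions are the canonical strong Ca II/Ca I
  lines in this range.
* `A_p` — base amplitudes putting the elemental Ca/Na lines well above
  the molecular bands, as observed in organic targets.
* `M_cp` — frozen per-class log-normal multipliers encoding class
  identity. All classes in a family share peak *positions*; they differ
  only in amplitudes, mimicking foods whose dominant features look alike.
* `J_rp` — per-replicate, per-peak log-normal jitter (shot-to-shot plasma
  chemistry and sampling-spot variation). This term, not the global
  factor, controls within-class difficulty: the global factor is removed
  exactly by area normalization, so without per-peak jitter every class
  would be almost perfectly separable.
* `g` — global multiplicative shot-to-shot fluctuation (log-normal,
  σ = 0.10), emulating plasma-energy variability.
* `ε` — additive detector noise, σ = 1 % of the largest peak amplitude.
* `baseline` — a smooth cubic fluorescence background at ≈ 30 % of the
  largest band for Raman; a constant offset for LIBS.

All log-normal shot factors are drawn mean-one, so class means converge
to the noise-free class template (a tested invariant).

**Complementarity.** Half of the classes carry their identity mostly in
the LIBS multipliers (between-class σ = 0.15 there, a smaller σ in
Raman), the other half mostly in Raman. This is the mechanism that makes
fusion demonstrably useful: either modality alone resolves only part of
the class structure.

**Calibration.** The free σ values were calibrated once so that
single-modality cross-validated macro accuracy lands near the 80 %
regime where fusion gains are observable, for *both* family sizes:

| parameter | 16-class | 7-class | rationale |
|---|---|---|---|
| weak-group between-class σ | 0.15 | 0.08 | more classes sharing a weak group need more separation to reach the same accuracy |
| Raman σ scale | 1.3 | 2.0 | Raman carries fewer, broader bands than LIBS (3–4 vs 5) and needs proportionally larger between-class spread |
| per-peak jitter σ | 0.035 | 0.045 | within-class difficulty, slightly tighter for the crowded 16-class family |

In simultaneous acquisition mode the Na emission line additionally leaks
into the Raman window at its shift-equivalent position (≈ 1816 cm⁻¹),
with FWHM converted through the local derivative 10⁷/λ² and amplitude
tied to the same plasma shot as the LIBS Na line.

What the generator does **not** model: physical plasma effects
(Saha/Boltzmann equilibria, self-absorption, matrix effects), detector
nonlinearity, wavelength-calibration drift, cosmic rays, or peak-position
shifts between classes. Passing tests therefore demonstrate that the
*pipeline* behaves correctly under the assumed signal model, not that the
specific accuracy numbers transfer to real food spectra.

## Preprocessing

Fixed order: baseline → denoise → normalize → transform.

* **Baseline** — asymmetric least squares (smoothness 10⁵, asymmetry
  0.01, 10 reweighting iterations) for Raman, which has a strong
  fluorescence background; LIBS gets its per-spectrum minimum subtracted
  as a constant offset.
* **Denoise** — Savitzky–Golay, window 11, order 3, both modalities.
* **Normalize** — scale to unit total intensity, removing the
  multiplicative shot-to-shot plasma factor exactly.
* **Transform** — channel-wise square root, a variance-stabilizing
  choice; `log1p` and `identity` are available by configuration. Negative
  residuals left by baseline subtraction are clipped to zero first (the
  clip count is logged).

## Interfering-line subtraction

In simultaneous mode the strong Na line is removed from Raman spectra
*before* the preprocessing chain (the Lorentzian model is additive in raw
intensity space): peaks are detected with prominence thresholds and
3-point parabolic sub-channel refinement, a Lorentzian plus constant
local background is fitted by nonlinear least squares over a narrow
window, and only the Lorentzian term is subtracted; channels outside the
window are untouched.

## Fusion strategies

* **Fusion 1 (late)** — each modality is independently ANOVA-filtered and
  elastic-net-selected; only the surviving channels are concatenated, so
  the fused feature count is exactly the sum of the per-modality counts.
* **Fusion 2 (early)** — the full 2000-channel LIBS and 600-channel Raman
  vectors are assembled into one 2600-channel hybrid per specimen before
  any selection; filtering and selection then act jointly.

Each modality is normalized per-spectrum before fusion so neither block
dominates by raw scale. An optional overlap coaddition (summing both
signals on a common wavelength grid inside the 554–625 nm overlap) is
provided for sensitivity analysis and off by default.

## Feature selection and classifier

**ANOVA filter.** One-way F statistic per channel; the 200 largest-F
channels are kept (ties broken toward lower channel index). Channels with
zero within-class variance but between-class spread are kept first with a
warning.

**Elastic-net multinomial model.** The classifier and multivariate
selector are the same object: a multinomial logistic regression with the
penalty `λ[α‖β_k‖₁ + ½(1−α)‖β_k‖₂²]` summed over classes. Channels with
any nonzero coefficient across classes constitute the selected feature
set. Features are standardized internally (zero mean, unit variance;
constant channels excluded); coefficients are reported on the
standardized scale; intercepts are unpenalized. The symmetric
parameterization is over-parameterized; the penalty resolves it, and a
`symmetry_gap()` diagnostic reports the per-feature class sums (exactly
zero only for ridge-type fits — with an ℓ₁ term the optimal shift is a
median, not a mean, so sum-to-zero is a diagnostic, not a constraint).

**Solver.** Block coordinate descent over classes. Each block builds a
penalized weighted least-squares subproblem with IRLS weights
`p(1−p)` (floored at 10⁻⁶) and solves it by cyclic soft-thresholding,
revisiting zero coefficients only on periodic full sweeps (active-set
strategy). Because exact curvature is not globally majorizing, every
block step is safeguarded by halving back toward the previous iterate
until the objective is non-increasing — the objective is therefore
monotone by construction. Convergence: maximum coefficient change < tol
(10⁻⁶ by default), with an additional objective-stall exit for
near-unpenalized fits on separable data whose parameters drift along
flat directions. λ_max (the smallest penalty with an all-zero solution)
has the closed form `max_{j,k} |⟨x_j, 1(y=k) − π_k⟩|/(n·α)`; λ paths are
log-spaced from λ_max downward and warm-started.

**Tuning.** (α, λ) are chosen by cross-validated deviance. The library's
`enet_select` uses repeated stratified k-fold (10-fold × 3 repeats by
default) over α ∈ {0.1, 0.3, 0.5, 0.7, 0.9, 1.0} and 50 λ values; the
minimum-deviance winner is refit on all data (no one-standard-error
rule — the simpler default). Inside the evaluation protocol (below) a
faster variant is the default: a single stratified 80/20 inner split, a
reduced grid (3 α × 20 λ), the search set capped at 40 training samples
per class (validation on the full inner split, winner refit on the full
training fold), the λ path truncated once a fit activates more than 100
channels, and looser iteration caps for search-phase fits than for the
final refit. These are efficiency choices for the tuning *search* only;
the model actually used is always refit on the complete training fold.

**SVM benchmark.** A linear-kernel SVM (one-vs-rest decision function),
C tuned over {0.1, 1, 10} by inner 5-fold CV, provides a reference
classifier with the same interface; the kernel choice is this package's
benchmark convention.

## Evaluation protocol

Ten independent sessions, each a stratified 10-fold cross-validation with
its own seed (defaults 1…10). *All* data-dependent steps — ANOVA,
elastic-net tuning and selection, classifier training — are refit inside
every training fold; nothing fitted ever sees a test fold (a
hook-instrumented test asserts this). Fold predictions are pooled into
one confusion matrix per session. The headline statistic is **macro
accuracy** — the mean of the confusion diagonal expressed as per-class
recall — with the SD taken across the 10 session-level values (ddof 1);
overall (micro) accuracy is reported alongside. Because selection is
refit inside folds, absolute accuracies from this protocol are not
directly comparable to summaries produced by selecting features once on
all data.

## Problem sizes used in the shipped tests

The acceptance suite runs the full study design: 16 × 100 and 7 × 100
spectra, 10 sessions of 10-fold CV for LIBS-only, Raman-only and
early-fused inputs, with the reduced 3 α × 20 λ tuning grid. Null
calibration (label permutation) uses 5 sessions with a fixed-(α, λ)
pipeline; unit tests use smaller synthetic instances throughout.

## Known limitations

* Fused accuracies on the synthetic families run higher (≈ 0.95–1.0)
  than single modalities by design; the generator is calibrated for the
  *single-modality* regime and makes the fused problem comparatively
  easy. The fusion-gain property, not the absolute fused accuracy, is
  the tested claim.
* The elastic-net solver targets dense problems up to a few hundred
  features after ANOVA filtering; it is not tuned for p ≫ 10⁴ without
  prior filtering.
* Anti-Stokes scattering, Voigt line shapes, multi-line deconvolution,
  and decision-level fusion are out of scope.
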