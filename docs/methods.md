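# Methods

This note documents the statistical model behind `anesgc`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the known limitations.

## Granger causality in the time domain

For two series X₁, X₂ and lag order *p*, both of these are fitted by
ordinary least squares with an intercept over the same effective samples
t = p..N−1:

* univariate: x₁(t) = a₀ + Σₖ aₖ x₁(t−k) + e(t), error variance Γ₁;
* bivariate: x₁(t) = b₀ + Σₖ bₖ x₁(t−k) + Σₖ cₖ x₂(t−k) + u(t), with the
  full 2×2 error covariance Σ.

Granger causality is the Geweke log variance ratio GC(X₂→X₁) = ln(Γ₁/Σ₁₁).
Because the fits share effective samples, the bivariate model nests the
univariate one and the ratio is ≥ 1 in exact arithmetic; round-off in
(−10⁻¹², 0) is clipped to zero. Residual variances use the
maximum-likelihood divisor N−p; GC is a ratio, so the convention cancels,
but it is fixed so that independent implementations agree to 10⁻⁸
(verified against a brute-force normal-equations oracle in the tests).
Σ₁₂ is reported as the instantaneous causality (Geweke's decomposition);
it is *not* used as a classification feature. An intercept is always
included because region averages have nonzero offsets.

Both positive directions high indicates feedback or a common driver;
instantaneous causality captures what neither past explains, which is the
signature of common input or volume conduction.

## Windowing and admission diagnostics

GC is estimated on 4-s windows sliding by 1 s (1024 samples at 256 Hz):
long enough for a stable order-6 fit, short enough for local stationarity
and a fast-reacting monitor. Awake windows come from before the induction
marker (LOC) and after the recovery marker (ROC); anesthetized windows
start 5 min after LOC (intubation artifacts, full unconsciousness) and end
at ROC, capped at 300 windows per condition (earliest eligible at LOC,
latest at ROC). Windows are half-open sample intervals; none straddles a
marker.

A window is admitted into feature extraction only if all four gates pass:

* **Artifact rule** — no sample deviates from the segment median by more
  than 8 scaled MADs, per region. The amplitude rule is a minimal proxy
  for manual diathermy exclusion; residual outliers are further damped by
  the moving-average smoother.
* **KPSS** level stationarity at the 1% critical value, with the short lag
  rule ⌊4(n/100)^¼⌋ for the long-run variance (7 lags at n = 1024). The
  short rule is deliberate: the 12-based rule drops the test's power
  against a random walk from ~99% to ~87% at this window length. An
  exactly constant window counts as stationary (statistic 0) and is left
  for the variance-based bad-channel logic to handle.
* **Durbin–Watson** on the *bivariate* fit residuals of each checked pair
  (both equations). The decision rule is sample-size aware: flag when the
  implied lag-1 autocorrelation |1 − DW/2| exceeds 2/√n (an approximate
  95% band) rather than a table lookup. Whiteness is checked on the
  bivariate fits on purpose: the univariate model of a series that is
  genuinely driven by another region is misspecified *by construction* —
  its autocorrelated residuals are the causal effect being measured, not a
  window defect. Gating on univariate residuals would systematically
  discard exactly the coupled (anesthetized) windows.
* **Consistency ≥ 70%** — how much of the data's covariance structure the
  fitted model captures. The model's one-step predictions are compared
  with the data through the stacked auto/cross covariances up to lag
  max(20, p): consistency = 100·(1 − ‖R_pred − R_data‖/‖R_data‖), clipped
  to [0, 100]. This prediction-based form is deterministic and behaves
  like a variance-explained measure: well-specified fits of structured
  signals score in the high 90s, under-ordered fits score lower, and fits
  to structureless noise score near zero. A variant that free-simulates
  the fitted VAR once and compares sample correlations was implemented
  and rejected: its single-replicate Monte Carlo noise pins the statistic
  near ~70% for any signal, which is incompatible both with a 70%
  admission threshold and with the high consistencies reported for
  well-fitted EEG. The horizon (20 lags) exceeds any fitted order used
  here so that an under-ordered model is penalized for long-range
  structure it cannot reproduce. An unstable fitted VAR scores 0.

The fixed order p = 6 is the pipeline default; `select_order_bic` sums the
bivariate BIC (n·ln det Σ + k·ln n) over a sample of windows and minimizes
over p when data-driven selection is wanted. Per-gate attrition is counted
hierarchically (artifact → KPSS → DW → consistency, each window charged to
the first gate it fails) so admitted + excluded sums to the total.

No frequency filtering is applied anywhere in the default path — filtering
introduces causal artifacts that corrupt GC. The optional 50-Hz notch
(second-order IIR, Q = 30, applied causally) exists only to reproduce the
filtered-vs-unfiltered comparison; outputs are flagged `filtered`.

## Surrogate controls

**Significance.** Each window's per-direction significance level is the
maximum GC over 19 phase-randomized surrogates of both series (amplitude
spectra preserved, independent uniform phases, conjugate symmetry with
real DC/Nyquist bins). Under the independence null the real value is
exchangeable with the surrogates, so the exceedance probability is
1/(19+1) = 5% per direction; this calibration is verified to ±3% over 500
null windows. In the pipeline the thresholds are computed on a subsample
of windows per condition (default 25) — they are reported flags, not an
admission gate, so subsampling does not change which windows are analyzed.

**Volume conduction.** Instantaneous source mixing can masquerade as
connectivity. The control decomposes the channels with SOBI (whitening
followed by joint Jacobi diagonalization of lagged covariance matrices,
lags 1..20 — comfortably above the AR order; rotation tolerance 10⁻⁶ on
the sine, which is far below the statistical precision of the lagged
covariances, with up to 500 sweeps), circularly shifts source n by
(n−1)·T samples (T = 100 by default, well beyond the autocorrelation
time; wrap-around preserves length and second-order statistics), and
remixes with the estimated mixing matrix. Instantaneous structure
survives; lagged cross-source structure does not. Pooled window×pair GC
values of the original (x) and surrogate (y) are then scored against the
fixed line y = x by r² = 1 − SS_res/SS_tot with ŷ = x and no fitted
parameters; r² may be negative, and the verdict is "cannot exclude volume
conduction" exactly when r² ≥ 0. On the synthetic lag-coupled recording
the check produces strongly negative r², as it should for genuine lagged
interaction.

## Classification study

Features are the four smoothed fronto→posterior GC values per admitted
window (components drop out if a posterior region is absent). Smoothing is
a trailing (causal) 10-sample moving average — causal because the intended
application is a real-time monitor. Per condition (LOC, ROC), performance
is estimated over B = 200 repetitions: N_train = min(⌊0.8·N_aw⌋,
⌊0.8·N_an⌋, 100) windows per class drawn uniformly *without* replacement
(so "the remaining windows" is well defined as the test set); the B
repetitions are the resampling. Classifiers: Fisher LDA with pooled
covariance and equal priors; soft-margin linear SVM (C = 1); RBF SVM with
kernel exp(−‖u−v‖²/2), i.e. σ = 1 on features standardized by the training
mean and scale — standardization is what makes a fixed kernel width
meaningful given large between-recording GC scale differences. Awake is
the positive class: sensitivity = TruP/TotP, specificity = TruN/TotN, and
average accuracy is their mean (balanced accuracy — the monitor must not
trade one for the other). Classifier-vs-classifier and LOC-vs-ROC
comparisons use the one-way ANOVA F-test at α = 0.05 on per-repetition
values; for two groups F = t², which the tests verify.

## The synthetic generator

Five latent region sources (LF, RF, LP, RP, Z) share stable oscillatory
AR(6) dynamics built from damped-oscillator pole pairs (moduli 0.50, 0.40,
0.30 at 10, 4 and 20 Hz — alpha/theta/beta-flavored resonances).
Innovations are Gaussian (the linear-AR setting GC assumes) and are scaled
by an exact discrete-Lyapunov solve so every source has unit stationary
variance regardless of pole configuration. During the anesthetized span
the two posterior sources receive the two frontal sources' *innovations*
at lag 1, scaled by `coupling_anesth` (default 0.4; `coupling_awake`
defaults to 0); the drive switches per sample exactly at the markers.
Coupling through innovations rather than filtered source values is
deliberate: with two autocorrelated value-drivers, every *pairwise* VAR
omits one driver and its residuals are autocorrelated, so the
Durbin–Watson gate (correctly) rejects most anesthetized windows; coupling
through innovations keeps each pairwise model well specified (the omitted
second driver contributes white variance) while producing the same
switched fronto→posterior GC. Stability is checked at construction on the
equivalent VAR(p+1) companion form and rejected with the spectral radius
named.

Each electrode observes its region's source plus independent white sensor
noise (sd 0.2 in source units), so region averaging is a genuine
noise-reduction step; signals are scaled to a microvolt-like range.
Optional nuisances: a pure 50-Hz sinusoid with an independent random phase
per channel (the simplest model that motivates a notch filter);
Poisson-timed high-amplitude bursts ≤ 0.5 s across all channels, with
burst times recorded in the truth structure; bad channels emitted as
near-constant with a large DC offset (what impedance-style exclusion
should catch); an optional instantaneous mixing matrix. Same seed and
configuration give bit-identical output.

With these defaults the anesthetized fronto→posterior GC on region
averages is ≈ 0.05 versus ≈ 0.007 awake — chosen for clear state
separation, not to mimic any particular clinical effect size, which varies
strongly between subjects. The generator reproduces only the second-order
structure the analysis assumes: there is no 1/f background, no dipole
forward model, no eye/muscle artifacts, and no drug pharmacokinetics.
Passing tests therefore demonstrate that the *pipeline* recovers the
statistical structure it targets, not that real operating-room EEG is this
clean.

## Problem sizes in tests and the acceptance script

The analytic-limit check averages 200 windows of n = 1024; the surrogate
null calibration uses 500 windows × 19 surrogates; diagnostic size/power
use 200 draws each; the volume-conduction discrimination uses 3-source
systems of 8192 samples (20–50 seeds); the headline end-to-end study uses
the default recording (10-min awake spans, 16-min anesthetized span,
B = 200), and the classifier-equivalence experiment repeats a reduced
recording (2-min awake spans, 100-window anesthetized cap) over 20 seeds.
These sizes give stable estimates of every reported quantity while keeping
a full run in minutes on one CPU.

## Known limitations

* **Overlapping windows and the bootstrap.** Windows slide by 1 s (75% raw
  overlap) and the trailing MA further correlates consecutive features, so
  each class contributes far fewer effectively independent observations
  than its window count. Random train/test splits of such windows are
  optimistic: chance segment-level offsets are learned and generalize
  within the same recording, and the RBF kernel additionally exploits
  near-duplicate neighbors. Concretely, with the coupling contrast
  switched off entirely, the end-to-end study still reports ~0.55–0.66
  (linear) and ~0.65–0.79 (RBF) average accuracy instead of 0.5 — the
  classifier machinery itself is unbiased (it scores 0.5 ± 0.07 on
  exchangeable features, which the tests verify), so this is a property of
  the evaluation protocol, not of the estimators. Absolute accuracies from
  this protocol should be read accordingly; blocked or chronological
  splits would remove the optimism at the cost of departing from the
  protocol implemented here.
* Pairwise GC cannot separate direct from indirect influence or from a
  common driver; conditional/blockwise GC is out of scope.
* The admission diagnostics assume the linear AR framework; heavy-tailed
  artifacts are handled only by the amplitude rule and the smoother.
* SOBI assumes an instantaneous, square, full-rank mixing; rank-deficient
  channel covariance (e.g. duplicated channels) is rejected rather than
  handled.
* EDF output is minimal 16-bit EDF (single continuous segment, markers in
  the JSON sidecar, ~0.002 µV quantization at typical amplitude ranges).
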