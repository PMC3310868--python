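# anesgc

Pairwise time-domain Granger causality (GC) from multichannel EEG as a
feature for discriminating the **awake** from the **anesthetized** brain
state — the signal-processing core of an EEG-based depth-of-anesthesia
monitor, built as a reusable, tested Python package.

## The problem and the method

During general anesthesia the directed ("effective") connectivity between
brain regions reorganizes: coupling from frontal to posterior scalp regions
increases sharply at loss of consciousness (LOC) and reverts at recovery
(ROC). That switch is far more specific to the anesthetized state than raw
spectral features, and it can be quantified without any model of the
anesthetic agent.

For two region-averaged series X₁, X₂ and lag order *p*, fit by OLS

* a univariate AR(p) of X₁, with prediction-error variance Γ₁, and
* a bivariate VAR(p) of (X₁, X₂), with error covariance Σ (same effective
  samples, so the models nest),

then

```
GC(X₂→X₁) = ln( Γ₁ / Σ₁₁ )  ≥ 0,
```

and symmetrically for the other direction; the off-diagonal Σ₁₂ is the
instantaneous causality (residual interdependence from common drive or
volume conduction). GC is zero when X₂'s past adds nothing to the
prediction of X₁, and for the textbook system *x₁(t) = c·x₂(t−1) + e(t)*
with white x₂ it converges to ln(1 + c²).

The full pipeline mirrors how such an analysis is run on operating-room
EEG:

1. **Ingest** — 19-channel 10/20 recordings (EDF or delimited text +
   JSON sidecar); bad-electrode exclusion; averaging into five regions
   (LF, RF, LP, RP, Z); 4-s windows sliding by 1 s around the LOC/ROC
   markers, skipping the first 5 min after induction. No frequency
   filtering by default (filtering distorts the timing relations GC relies
   on); a 50-Hz notch is available as an explicit comparison path.
2. **Admission diagnostics** per window — KPSS level-stationarity at the
   1% level, Durbin–Watson residual whiteness, AR-model consistency ≥ 70%
   (fixed order 6; BIC selection available), robust amplitude artifact
   rule.
3. **GC estimation** — all 10 region pairs, both directions, plus the
   instantaneous term; 10-sample trailing moving average.
4. **Surrogate controls** — per-window significance as the maximum GC over
   19 phase-randomized surrogates; a volume-conduction control that
   SOBI-decomposes the channels, circularly shifts each source by (n−1)·T
   samples, remixes, and scores the fixed line y = x between surrogate and
   original GC by r² = 1 − SS_res/SS_tot (r² < 0 rejects volume conduction
   as the explanation).
5. **Classification** — feature vector (GC_LF→LP, GC_RF→LP, GC_LF→RP,
   GC_RF→RP) per admitted window; B = 200 bootstrap repetitions with
   N_train = min(⌊0.8·N_aw⌋, ⌊0.8·N_an⌋, 100) windows per class; LDA,
   linear SVM and RBF SVM; specificity, sensitivity and average accuracy
   (awake = positive class), with one-way ANOVA comparisons between
   classifiers and between the LOC and ROC conditions.

Because clinical recordings of this kind are not redistributable, the
package ships a first-class synthetic generator (`anesgc.simulate`): five
latent region sources with stable oscillatory AR(6) dynamics, whose
posterior sources receive a lag-1 frontal drive only while "anesthetized",
observed by 19 electrodes with sensor noise, optional 50-Hz line noise,
artifact bursts, bad channels, and channel mixing. Every stage of the
pipeline is tested against it.

## Worked example

Directed GC between two constructed series, `x1(t) = 0.5·x2(t-1) + e(t)`
with white `x2` (asymptotic GC(X₂→X₁) = ln 1.25 ≈ 0.223):

```python
import numpy as np
from anesgc import BivariateGranger

rng = np.random.default_rng(0)
e = rng.normal(size=(2048, 2))
x2 = e[:, 1]
x1 = e[:, 0].copy()
x1[1:] += 0.5 * x2[:-1]

print(BivariateGranger(x1, x2, order=6).fit().summary())
```

```
Bivariate Granger causality (OLS)
  order p:               6
  effective samples:     2042
  GC X2 -> X1:           0.248323
  GC X1 -> X2:           0.001478
  instantaneous (cov):   -3.501078e-02
  resid var X1 (uni):    1.271853e+00
  resid var X1 (biv):    9.921827e-01
  resid var X2 (uni):    9.902202e-01
  resid var X2 (biv):    9.887575e-01
```

The coupled direction is strong (0.248, near the ln 1.25 limit at this
sample size) and the uncoupled direction is near zero: adding x₂'s past
drops x₁'s prediction-error variance from 1.272 to 0.992.

End to end on a synthetic recording (2-min awake spans, anesthetized
coupling 0.4):

```python
from anesgc import PipelineConfig, SimConfig, run_pipeline
from anesgc.classify import BootstrapConfig

cfg = PipelineConfig(
    sim=SimConfig(durations=(120.0, 620.0, 120.0), seed=1),
    n_anesth_windows=100, significance_windows=6, vc_windows=10,
    bootstrap=BootstrapConfig(B=50), seed=7)
print(run_pipeline(cfg).summary())
```

```
Granger-causality state-classification study
  AR order: 6   regions: LF, RF, LP, RP, Z
  window attrition: {"total": 434, "admitted": 359, "failed_artifact_free": 0, "failed_stationary": 75, "failed_dw_ok": 0, "failed_consistent": 0}
  volume conduction: r2 = -45.759 -> volume-conduction-rejected

condition method  specificity_mean  specificity_sd  sensitivity_mean  sensitivity_sd  average_accuracy_mean  average_accuracy_sd
      LOC    LDA             0.964           0.036             1.000           0.000                  0.982                0.018
      LOC  SVM_L             0.976           0.028             1.000           0.000                  0.988                0.014
      LOC SVM_NL             0.976           0.028             1.000           0.000                  0.988                0.014
      ROC    LDA             1.000           0.000             0.957           0.028                  0.979                0.014
      ROC  SVM_L             1.000           0.000             0.977           0.021                  0.988                0.011
      ROC SVM_NL             1.000           0.000             0.980           0.021                  0.990                0.010
```

All three classifiers separate the states near-perfectly when the
fronto→posterior coupling switch is present, and the strongly negative
volume-conduction r² confirms the detected interaction is lagged, not an
instantaneous mixing artifact.

The same pipeline is available from the shell:

```
anesgc simulate --out rec.tsv --seed 1
anesgc run --input rec.tsv --out results --seed 1
anesgc check-volume-conduction rec.tsv --out vc.json
```

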