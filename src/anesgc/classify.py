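"""Feature construction and bootstrap state classification.

The classification feature of each admitted 4-s window is the vector of
smoothed fronto->posterior GC values

    f = (GC_LF->LP, GC_RF->LP, GC_LF->RP, GC_RF->RP),

with the window's state (awake / anesthetized) as label; when a posterior
region is absent its two components are dropped. Performance is estimated
per condition (LOC, ROC) over B bootstrap repetitions: each repetition draws
N_train = min(floor(0.8*N_aw), floor(0.8*N_an), 100) windows per class
without replacement for training and tests on all remaining windows of each
class. Classifiers: LDA (pooled covariance, equal priors), a linear
soft-margin SVM, and an RBF SVM with kernel exp(-||u-v||^2 / 2) (sigma = 1
on training-standardized features). Awake is the positive class;
sensitivity = TruP/TotP, specificity = TruN/TotN and average accuracy is
their mean, so a degenerate classifier scores 0.5 on balanced ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ingest import ANESTH, AWAKE
from .montage import FEATURE_PAIRS

METHODS = ("LDA", "SVM_L", "SVM_NL")


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 200
    train_fraction: float = 0.8
    train_cap: int = 100
    svm_c: float = 1.0
    rbf_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.train_cap < 1:
            raise ValueError("train_cap must be >= 1")


@dataclass
class PerformanceMetrics:
    """Confusion counts and the derived proportions for one test set."""

    tot_p: int
    tot_n: int
    tru_p: int
    tru_n: int

    @property
    def sensitivity(self) -> float:
        return np.nan if self.tot_p == 0 else self.tru_p / self.tot_p

    @property
    def specificity(self) -> float:
        return np.nan if self.tot_n == 0 else self.tru_n / self.tot_n

    @property
    def average_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def build_features(gcs) -> pd.DataFrame:
    """One feature row per admitted window from the smoothed
    fronto->posterior GC values.

    Columns: the available feature components (named like ``LF->LP``),
    ``label``, ``condition``, ``start_s``. Raises when a class has no
    admitted windows or when the series was not smoothed.
    """
    if not gcs.smoothed:
        gcs = gcs.smooth()
    pieces = []
    for src, dst in FEATURE_PAIRS:
        try:
            sub = gcs.directed(src, dst, smoothed=True)
        except KeyError:
            continue
        sub = sub[["condition", "state", "start_s", "gc"]].rename(
            columns={"gc": f"{src}->{dst}"})
        pieces.append(sub.set_index(["condition", "state", "start_s"]))
    if not pieces:
        raise ValueError("no fronto->posterior pairs available for features")
    feats = pd.concat(pieces, axis=1).reset_index()
    feats = feats.rename(columns={"state": "label"})
    feats = feats.dropna(subset=[c for c in feats.columns if "->" in c])
    for cls in (AWAKE, ANESTH):
        if not (feats["label"] == cls).any():
            raise ValueError(f"no admitted windows in class {cls!r}")
    return feats


def feature_columns(feats: pd.DataFrame) -> list[str]:
    return [c for c in feats.columns if "->" in c]


def bootstrap_split(n_aw: int, n_an: int, cfg: BootstrapConfig,
                    repetition: int) -> tuple[tuple[np.ndarray, np.ndarray],
                                              tuple[np.ndarray, np.ndarray]]:
    """Training/test window indices per class for one repetition.

    N_train distinct indices per class are drawn uniformly; all remaining
    windows of each class form its test set. Repetitions use independent
    substreams of ``cfg.seed``, so the same (seed, repetition) always yields
    the same split.
    """
    if n_aw < 5 or n_an < 5:
        raise ValueError("need at least 5 windows per class")
    n_train = min(int(cfg.train_fraction * n_aw), int(cfg.train_fraction * n_an),
                  cfg.train_cap)
    if n_train == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, repetition)))
    train_aw = np.sort(rng.choice(n_aw, size=n_train, replace=False))
    train_an = np.sort(rng.choice(n_an, size=n_train, replace=False))
    test_aw = np.setdiff1d(np.arange(n_aw), train_aw)
    test_an = np.setdiff1d(np.arange(n_an), train_an)
    return (train_aw, train_an), (test_aw, test_an)


def train_and_classify(train_x: np.ndarray, train_y: np.ndarray,
                       test_x: np.ndarray, method: str,
                       cfg: BootstrapConfig = BootstrapConfig()) -> np.ndarray:
    """Fit one classifier and return predicted labels for the test vectors."""
    classes = np.unique(train_y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if method == "LDA":
        clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        clf.fit(train_x, train_y)
        return clf.predict(test_x)
    scaler = StandardScaler().fit(train_x)
    if method == "SVM_L":
        clf = SVC(C=cfg.svm_c, kernel="linear")
    elif method == "SVM_NL":
        gamma = 1.0 / (2.0 * cfg.rbf_sigma ** 2)
        clf = SVC(C=cfg.svm_c, kernel="rbf", gamma=gamma)
    else:
        raise ValueError(f"unknown method {method!r}")
    clf.fit(scaler.transform(train_x), train_y)
    return clf.predict(scaler.transform(test_x))


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> PerformanceMetrics:
    """Confusion counts with awake as the positive class."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("length mismatch")
    pos = truth == AWAKE
    neg = truth == ANESTH
    return PerformanceMetrics(
        tot_p=int(pos.sum()), tot_n=int(neg.sum()),
        tru_p=int((predictions[pos] == AWAKE).sum()),
        tru_n=int((predictions[neg] == ANESTH).sum()),
    )


def compare(perf_a: np.ndarray, perf_b: np.ndarray) -> tuple[float, float, bool]:
    """One-way ANOVA F-test between two per-repetition performance samples.

    Identical zero-variance samples give (0, 1, False) by convention.
    """
    a = np.asarray(perf_a, dtype=float)
    b = np.asarray(perf_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
    f, p = stats.f_oneway(a, b)
    if np.isnan(f):
        return 0.0, 1.0, False
    return float(f), float(p), bool(p < 0.05)


@dataclass
class BootstrapReport:
    """Per-condition, per-classifier bootstrap performance plus comparisons.

    ``per_repetition[cond][method]`` holds arrays of specificity,
    sensitivity and average accuracy (length B); ``summary`` is the mean ±
    standard deviation table; ``classifier_comparisons`` holds the pairwise
    ANOVA results per condition and metric, ``condition_comparisons`` the
    LOC-vs-ROC ANOVA per classifier and metric.
    """

    per_repetition: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    classifier_comparisons: pd.DataFrame | None = None
    condition_comparisons: pd.DataFrame | None = None
    n_windows: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_windows": self.n_windows,
            "summary": self.summary.to_dict(orient="records"),
            "classifier_comparisons":
                self.classifier_comparisons.to_dict(orient="records"),
            "per_repetition": {
                cond: {m: {k: [float(v) for v in arr[k]] for k in arr}
                       for m, arr in by_m.items()}
                for cond, by_m in self.per_repetition.items()
            },
        }
        if self.condition_comparisons is not None:
            out["condition_comparisons"] = \
                self.condition_comparisons.to_dict(orient="records")
        return out


def run_bootstrap(feats: pd.DataFrame,
                  cfg: BootstrapConfig = BootstrapConfig(),
                  methods: tuple[str, ...] = METHODS) -> BootstrapReport:
    """The full bootstrap study on a feature table (both conditions)."""
    cols = feature_columns(feats)
    report = BootstrapReport()
    metric_names = ("specificity", "sensitivity", "average_accuracy")
    for cond, sub in feats.groupby("condition"):
        aw = sub[sub["label"] == AWAKE]
        an = sub[sub["label"] == ANESTH]
        x_aw, x_an = aw[cols].to_numpy(), an[cols].to_numpy()
        report.n_windows[cond] = {"awake": len(aw), "anesthetized": len(an)}
        per_m: dict[str, dict[str, np.ndarray]] = {
            m: {k: np.empty(cfg.B) for k in metric_names} for m in methods}
        for rep in range(cfg.B):
            (tr_aw, tr_an), (te_aw, te_an) = bootstrap_split(
                len(aw), len(an), cfg, rep)
            train_x = np.vstack([x_aw[tr_aw], x_an[tr_an]])
            train_y = np.array([AWAKE] * len(tr_aw) + [ANESTH] * len(tr_an))
            test_x = np.vstack([x_aw[te_aw], x_an[te_an]])
            test_y = np.array([AWAKE] * len(te_aw) + [ANESTH] * len(te_an))
            for m in methods:
                pred = train_and_classify(train_x, train_y, test_x, m, cfg)
                perf = evaluate(pred, test_y)
                per_m[m]["specificity"][rep] = perf.specificity
                per_m[m]["sensitivity"][rep] = perf.sensitivity
                per_m[m]["average_accuracy"][rep] = perf.average_accuracy
        report.per_repetition[cond] = per_m

    rows = []
    for cond, per_m in report.per_repetition.items():
        for m, arrs in per_m.items():
            row = {"condition": cond, "method": m}
            for k, v in arrs.items():
                row[f"{k}_mean"] = float(np.mean(v))
                row[f"{k}_sd"] = float(np.std(v))
            rows.append(row)
    report.summary = pd.DataFrame(rows)

    comp_rows = []
    for cond, per_m in report.per_repetition.items():
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                for k in metric_names:
                    f, p, sig = compare(per_m[ma][k], per_m[mb][k])
                    comp_rows.append({"condition": cond, "metric": k,
                                      "method_a": ma, "method_b": mb,
                                      "F": f, "p": p, "significant": sig})
    report.classifier_comparisons = pd.DataFrame(comp_rows)

    conds = list(report.per_repetition)
    if len(conds) == 2:
        cond_rows = []
        for m in methods:
            for k in metric_names:
                f, p, sig = compare(report.per_repetition[conds[0]][m][k],
                                    report.per_repetition[conds[1]][m][k])
                cond_rows.append({"metric": k, "method": m,
                                  "condition_a": conds[0],
                                  "condition_b": conds[1],
                                  "F": f, "p": p, "significant": sig})
        report.condition_comparisons = pd.DataFrame(cond_rows)
    return report


__all__ = [
    "METHODS", "BootstrapConfig", "PerformanceMetrics", "BootstrapReport",
    "build_features", "feature_columns", "bootstrap_split",
    "train_and_classify", "evaluate", "compare", "run_bootstrap",
]
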