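"""Time-domain pairwise Granger causality between region-averaged series.

For series X1, X2 and lag order p, let Gamma_1 be the prediction-error
variance of the univariate AR(p) model of X1 and Sigma_11 the corresponding
variance when X2's past is added (bivariate VAR(p) fitted on the same
effective samples). Granger causality from X2 to X1 is the Geweke log
variance ratio

    GC_{2->1} = ln(Gamma_1 / Sigma_11) >= 0,

and symmetrically for GC_{1->2}. The off-diagonal of the bivariate residual
covariance is the instantaneous causality (Geweke's decomposition): the
interdependence left over after both pasts are accounted for, e.g. from a
common driver or volume conduction. Nonnegativity follows from the nesting
of the two models; tiny negative round-off is clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .armodel import ARFit, SingularFitError, fit_ar, fit_var2
from .ingest import WindowSet
from .montage import all_region_pairs

_ROUNDOFF = 1e-12


@dataclass
class GCEstimate:
    """Directed GC for one ordered pair on one window (natural-log units)."""

    gc_12: float           # X1 -> X2
    gc_21: float           # X2 -> X1
    instantaneous: float   # off-diagonal bivariate residual covariance
    pair: tuple[str, str] = ("X1", "X2")
    window: int = -1
    undefined: bool = False


def _clip(v: float) -> float:
    return 0.0 if -_ROUNDOFF < v < 0.0 else v


def granger_pair(x1: np.ndarray, x2: np.ndarray, p: int = 6,
                 pair: tuple[str, str] = ("X1", "X2"),
                 window: int = -1) -> GCEstimate:
    """Bidirectional GC and instantaneous causality for one window.

    Singular fits (constant or collinear inputs) yield an estimate flagged
    ``undefined`` rather than an exception, so one degenerate window cannot
    abort a run.
    """
    try:
        uni1 = fit_ar(x1, p)
        uni2 = fit_ar(x2, p)
        biv = fit_var2(x1, x2, p)
    except SingularFitError:
        return GCEstimate(np.nan, np.nan, np.nan, pair, window, undefined=True)
    sigma = biv.residual_covariance
    gc_21 = _clip(float(np.log(uni1.residual_covariance / sigma[0, 0])))
    gc_12 = _clip(float(np.log(uni2.residual_covariance / sigma[1, 1])))
    return GCEstimate(gc_12=gc_12, gc_21=gc_21,
                      instantaneous=float(sigma[0, 1]),
                      pair=pair, window=window)


class BivariateGranger:
    """Two-series Granger-causality model (fit by OLS).

    Parameters
    ----------
    x1, x2 : equal-length 1-d arrays
    order : AR lag order p (the pipeline default is 6)

    ``fit()`` returns a :class:`BivariateGrangerResults` carrying the three
    underlying AR fits, both directed GC values, the instantaneous term and
    residual diagnostics.
    """

    def __init__(self, x1: np.ndarray, x2: np.ndarray, order: int = 6):
        self.x1 = np.asarray(x1, dtype=float)
        self.x2 = np.asarray(x2, dtype=float)
        self.order = int(order)

    def fit(self) -> "BivariateGrangerResults":
        uni1 = fit_ar(self.x1, self.order)
        uni2 = fit_ar(self.x2, self.order)
        biv = fit_var2(self.x1, self.x2, self.order)
        return BivariateGrangerResults(self, uni1, uni2, biv)


class BivariateGrangerResults:
    """Fitted results: directed GC, instantaneous causality, diagnostics."""

    def __init__(self, model: BivariateGranger, uni1: ARFit, uni2: ARFit,
                 biv: ARFit):
        self.model = model
        self.univariate = (uni1, uni2)
        self.bivariate = biv
        sigma = biv.residual_covariance
        self.gc_21 = _clip(float(np.log(uni1.residual_covariance / sigma[0, 0])))
        self.gc_12 = _clip(float(np.log(uni2.residual_covariance / sigma[1, 1])))
        self.instantaneous = float(sigma[0, 1])

    def diagnostics(self, seed: int = 0, kpss_level: float = 0.01):
        """KPSS, Durbin-Watson and consistency for this window's fits."""
        from .armodel import consistency, durbin_watson, kpss_test
        kpss1 = kpss_test(self.model.x1, kpss_level)
        kpss2 = kpss_test(self.model.x2, kpss_level)
        dw = [durbin_watson(self.bivariate.residuals[:, i]) for i in (0, 1)]
        cons = consistency(self.model.x1, self.model.x2, self.bivariate, seed)
        return {
            "kpss": (kpss1, kpss2),
            "durbin_watson": dw,
            "consistency_pct": cons,
        }

    def summary(self) -> str:
        s = self.bivariate.residual_covariance
        lines = [
            "Bivariate Granger causality (OLS)",
            f"  order p:               {self.model.order}",
            f"  effective samples:     {self.bivariate.n_effective}",
            f"  GC X2 -> X1:           {self.gc_21:.6f}",
            f"  GC X1 -> X2:           {self.gc_12:.6f}",
            f"  instantaneous (cov):   {self.instantaneous:.6e}",
            f"  resid var X1 (uni):    {self.univariate[0].residual_covariance:.6e}",
            f"  resid var X1 (biv):    {s[0, 0]:.6e}",
            f"  resid var X2 (uni):    {self.univariate[1].residual_covariance:.6e}",
            f"  resid var X2 (biv):    {s[1, 1]:.6e}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# window-set level

class GCSeries:
    """Window-indexed directed GC for every available region pair.

    ``frame`` is a long-format table with one row per admitted window x pair:
    condition, state, window (row index into the WindowSet), start_s, pair
    ("LF-LP", ordered alphabetically as stored; both directions kept as
    columns gc_ab / gc_ba with a = first region of the pair name), raw and
    (after :meth:`smooth`) smoothed values, and the instantaneous term.
    """

    def __init__(self, frame: pd.DataFrame, order: int,
                 pairs: list[tuple[str, str]], smoothed: bool = False):
        self.frame = frame
        self.order = order
        self.pairs = pairs
        self.smoothed = smoothed

    def directed(self, src: str, dst: str, smoothed: bool | None = None) -> pd.DataFrame:
        """Rows for one directed pair, with a 'gc' column for src->dst."""
        use_sm = self.smoothed if smoothed is None else smoothed
        for a, b in self.pairs:
            if (a, b) == (src, dst) or (a, b) == (dst, src):
                sub = self.frame[self.frame["pair"] == f"{a}-{b}"].copy()
                col = "gc_ab" if (a, b) == (src, dst) else "gc_ba"
                if use_sm:
                    col += "_sm"
                sub["gc"] = sub[col]
                return sub
        raise KeyError(f"pair {src}->{dst} not available")

    def smooth(self, n: int = 10) -> "GCSeries":
        """Causal moving average (length n) per condition x pair x direction."""
        frame = self.frame.copy()
        for col in ("gc_ab", "gc_ba", "instantaneous"):
            frame[col + "_sm"] = np.nan
        for (_, _), idx in frame.groupby(["condition", "pair"]).groups.items():
            sub = frame.loc[idx].sort_values("start_s")
            for col in ("gc_ab", "gc_ba", "instantaneous"):
                frame.loc[sub.index, col + "_sm"] = smooth_ma(
                    sub[col].to_numpy(), n)
        return GCSeries(frame, self.order, self.pairs, smoothed=True)

    def to_long_table(self) -> pd.DataFrame:
        """One row per (window, pair, direction) for serialization."""
        rows = []
        for _, r in self.frame.iterrows():
            a, b = r["pair"].split("-")
            for src, dst, col in ((a, b, "gc_ab"), (b, a, "gc_ba")):
                rows.append({
                    "condition": r["condition"], "state": r["state"],
                    "window_start_s": r["start_s"],
                    "pair": r["pair"], "direction": f"{src}->{dst}",
                    "gc_raw": r[col],
                    "gc_smoothed": r.get(col + "_sm", np.nan),
                    "instantaneous": r["instantaneous"],
                    "significant": r.get("significant_" + col, np.nan),
                })
        return pd.DataFrame(rows)


def regionwise_gc(ws: WindowSet, p: int = 6,
                  pairs: list[tuple[str, str]] | None = None) -> GCSeries:
    """GC for every admitted window x available region pair.

    Windows failing any QC gate are skipped (their exclusion is recoverable
    from the WindowSet attrition bookkeeping). Raises when no window is
    admitted, naming the gate that removed the most windows.
    """
    admitted = ws.admitted
    if not admitted.any():
        att = ws.attrition()
        worst = max((k for k in att if k.startswith("failed_")), key=att.get)
        raise ValueError(
            f"no admitted windows ({att['total']} total; most removed by "
            f"{worst.removeprefix('failed_')}: {att[worst]})"
        )
    regions = ws.regions.regions
    if pairs is None:
        pairs = all_region_pairs(regions)
    else:
        pairs = [pq for pq in pairs if pq[0] in regions and pq[1] in regions]

    rows = []
    for i in np.flatnonzero(admitted):
        meta = ws.table.iloc[i]
        data = ws.data(i)
        for a, b in pairs:
            est = granger_pair(data[a], data[b], p, pair=(a, b), window=i)
            rows.append({
                "condition": meta["condition"], "state": meta["state"],
                "window": i, "start_s": meta["start_s"], "pair": f"{a}-{b}",
                "gc_ab": est.gc_12, "gc_ba": est.gc_21,
                "instantaneous": est.instantaneous,
                "undefined": est.undefined,
            })
    return GCSeries(pd.DataFrame(rows), order=p, pairs=pairs)


def smooth_ma(series: np.ndarray, n: int = 10) -> np.ndarray:
    """Trailing (causal) moving average: element i is the mean of the last
    min(n, i+1) values. Length preserved; n=1 is the identity."""
    if n < 1:
        raise ValueError("n must be >= 1")
    x = np.asarray(series, dtype=float)
    if n == 1:
        return x.copy()
    c = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - n, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def plot_gc_traces(gcs: GCSeries, src: str, dst: str, markers: dict[str, int],
                   fs: float, ax=None):
    """Plot one directed smoothed GC trace against the LOC/ROC markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for cond, sub in gcs.directed(src, dst).groupby("condition"):
        sub = sub.sort_values("start_s")
        ax.plot(sub["start_s"], sub["gc"], label=f"{src}->{dst} ({cond})")
    for name, s in markers.items():
        ax.axvline(s / fs, color="k", ls="--", lw=0.8)
        ax.text(s / fs, ax.get_ylim()[1], name, ha="center", va="bottom")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("GC (nats)")
    ax.legend()
    return ax


__all__ = [
    "GCEstimate", "GCSeries", "granger_pair", "regionwise_gc", "smooth_ma",
    "BivariateGranger", "BivariateGrangerResults", "plot_gc_traces",
]
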