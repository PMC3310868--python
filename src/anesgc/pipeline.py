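"""End-to-end study orchestration.

``GrangerStateStudy`` is the top-level model object: built from a recording
(or a synthetic-generation config), its ``fit()`` runs ingestion, the
AR-diagnostic gating, regionwise GC with smoothing, surrogate significance
and the volume-conduction control, and the bootstrap classification study,
returning a ``StudyResults`` that carries every intermediate product, a
``summary()`` table and writers for the report files.

A single global seed deterministically derives all stage substreams, so the
same configuration and seed reproduce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import armodel, classify, ingest, surrogates
from .gc import GCSeries, regionwise_gc
from .ingest import Recording, WindowSet
from .montage import FEATURE_PAIRS, all_region_pairs
from .simulate import SimConfig, SyntheticRecording, generate_recording


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs.

    Either ``input_path`` (EDF or matrix+JSON file) or ``sim`` (synthetic
    generator config) must be given. ``ar_order`` is the fixed lag order, or
    the string ``"bic"`` to select it by the Bayesian information criterion
    on a sample of windows.
    """

    input_path: str | None = None
    sim: SimConfig | None = None
    ar_order: int | str = 6
    bic_max_order: int = 12
    bic_sample_windows: int = 20
    window_s: float = 4.0
    step_s: float = 1.0
    post_induction_skip: float = 300.0
    n_anesth_windows: int = 300
    smoothing: int = 10
    notch_50hz: bool = False
    all_pairs: bool = True
    surrogate: surrogates.SurrogateConfig = field(
        default_factory=surrogates.SurrogateConfig)
    significance_windows: int = 25
    compute_significance: bool = True
    compute_volume_conduction: bool = True
    vc_duration_s: float = 120.0
    vc_windows: int = 20
    bootstrap: classify.BootstrapConfig = field(
        default_factory=classify.BootstrapConfig)
    out_dir: str | None = None
    seed: int = 0

    def validate(self, require_input: bool = True) -> None:
        if require_input and self.input_path is None and self.sim is None:
            raise ValueError("config needs an input_path or a sim config")
        if isinstance(self.ar_order, str) and self.ar_order != "bic":
            raise ValueError("ar_order must be an integer or 'bic'")
        for name in ("window_s", "step_s", "smoothing", "n_anesth_windows",
                     "significance_windows", "vc_duration_s", "vc_windows"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.post_induction_skip < 0:
            raise ValueError("post_induction_skip must be non-negative")

    def echo(self) -> dict:
        d = {}
        for k, v in self.__dict__.items():
            if isinstance(v, (surrogates.SurrogateConfig,
                              classify.BootstrapConfig)):
                d[k] = dict(v.__dict__)
            elif isinstance(v, SimConfig):
                sd = dict(v.__dict__)
                if sd.get("mixing") is not None:
                    sd["mixing"] = np.asarray(sd["mixing"]).tolist()
                d[k] = sd
            else:
                d[k] = v
        return d


@dataclass
class StudyResults:
    """Everything a fitted study produced."""

    config: PipelineConfig
    recording: Recording | SyntheticRecording
    window_set: WindowSet
    order: int
    gc_series: GCSeries
    features: pd.DataFrame
    report: classify.BootstrapReport
    volume_conduction: surrogates.VolumeConductionResult | None
    attrition: dict

    def summary(self) -> str:
        lines = [
            "Granger-causality state-classification study",
            f"  AR order: {self.order}   regions: "
            f"{', '.join(self.window_set.regions.regions)}",
            "  window attrition: " + json.dumps(self.attrition),
        ]
        if self.volume_conduction is not None:
            vc = self.volume_conduction
            lines.append(f"  volume conduction: r2 = {vc.r2:.3f} -> {vc.verdict}")
        lines.append("")
        lines.append(self.report.summary.to_string(index=False,
                                                   float_format="%.3f"))
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": self.config.echo(),
            "order": self.order,
            "attrition": self.attrition,
            "bootstrap": self.report.to_dict(),
        }
        if self.volume_conduction is not None:
            payload["volume_conduction"] = self.volume_conduction.to_dict()
        (out / "report.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True))
        self.gc_series.to_long_table().to_csv(
            out / "gc_series.tsv", sep="\t", index=False, float_format="%.8g")
        with open(out / "attrition.jsonl", "w") as fh:
            for gate, count in self.attrition.items():
                fh.write(json.dumps({"gate": gate, "windows": count}) + "\n")


class GrangerStateStudy:
    """Model object over one recording; ``fit()`` returns StudyResults."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config

    @classmethod
    def from_recording(cls, recording, **kwargs) -> "GrangerStateStudy":
        cfg = PipelineConfig(**kwargs)
        cfg.validate(require_input=False)
        study = cls.__new__(cls)
        study.config = cfg
        study._recording = recording
        return study

    def fit(self) -> StudyResults:
        return run_pipeline(self.config,
                            recording=getattr(self, "_recording", None))


def _load(cfg: PipelineConfig) -> Recording | SyntheticRecording:
    if cfg.input_path is not None:
        return ingest.read_recording(cfg.input_path)
    return generate_recording(cfg.sim)


def _as_recording(rec) -> Recording:
    if isinstance(rec, Recording):
        return rec
    return Recording(signal=rec.signal, labels=rec.labels, fs=rec.fs,
                     markers=dict(rec.markers))


def run_pipeline(cfg: PipelineConfig, recording=None) -> StudyResults:
    """Execute ingest -> diagnostics -> GC -> surrogates -> classification."""
    cfg.validate(require_input=recording is None)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(4).astype(np.int64) % (2 ** 31)
    diag_seed, sig_seed, vc_seed, boot_seed = (int(s) for s in seeds)

    raw = _load(cfg) if recording is None else recording
    rec = _as_recording(raw)
    ingest.detect_bad_channels(rec)
    rs = ingest.average_regions(rec)
    if cfg.notch_50hz:
        rs = ingest.notch_50hz(rs)
    ws = ingest.extract_state_segments(
        rs, post_induction_skip=cfg.post_induction_skip,
        n_anesth_windows=cfg.n_anesth_windows,
        window_s=cfg.window_s, step_s=cfg.step_s)

    order = _resolve_order(cfg, ws)
    armodel.run_diagnostics(ws, order=order, seed=diag_seed)

    pairs = None if cfg.all_pairs else list(FEATURE_PAIRS)
    gcs = regionwise_gc(ws, p=order, pairs=pairs)
    gcs = gcs.smooth(cfg.smoothing)

    if cfg.compute_significance:
        _significance_stage(gcs, ws, order, cfg, sig_seed)

    vc_result = None
    if cfg.compute_volume_conduction:
        vc_result = _volume_conduction_stage(rec, cfg, order, vc_seed)

    feats = classify.build_features(gcs)
    boot_cfg = replace(cfg.bootstrap, seed=boot_seed)
    report = classify.run_bootstrap(feats, boot_cfg)

    results = StudyResults(
        config=cfg, recording=raw, window_set=ws, order=order,
        gc_series=gcs, features=feats, report=report,
        volume_conduction=vc_result, attrition=ws.attrition(),
    )
    if cfg.out_dir is not None:
        results.save(cfg.out_dir)
    return results


def _resolve_order(cfg: PipelineConfig, ws: WindowSet) -> int:
    if cfg.ar_order != "bic":
        return int(cfg.ar_order)
    regions = ws.regions.regions
    a, b = ("LF", "LP") if "LF" in regions and "LP" in regions else \
        all_region_pairs(regions)[0]
    idx = np.linspace(0, len(ws.table) - 1,
                      min(cfg.bic_sample_windows, len(ws.table))).astype(int)
    sample = [(ws.data(i)[a], ws.data(i)[b]) for i in np.unique(idx)]
    return armodel.select_order_bic(sample, cfg.bic_max_order)


def _significance_stage(gcs: GCSeries, ws: WindowSet, order: int,
                        cfg: PipelineConfig, seed: int) -> None:
    """Max-surrogate significance flags on a window subsample per condition."""
    frame = gcs.frame
    frame["significant_gc_ab"] = pd.NA
    frame["significant_gc_ba"] = pd.NA
    for cond, sub in frame.groupby("condition"):
        windows = np.unique(sub["window"])
        pick = windows[np.linspace(0, len(windows) - 1,
                                   min(cfg.significance_windows, len(windows))
                                   ).astype(int)]
        for w in np.unique(pick):
            data = ws.data(int(w))
            rows = frame.index[(frame["window"] == w)]
            for ridx in rows:
                a, b = frame.loc[ridx, "pair"].split("-")
                stable = sum(ord(c) * 31 ** k for k, c in enumerate(a + b))
                scfg = replace(cfg.surrogate,
                               seed=int((seed + 7919 * int(w) + stable)
                                        % (2 ** 31)))
                thr_ab, thr_ba = surrogates.gc_significance_threshold(
                    data[a], data[b], order, scfg)
                frame.loc[ridx, "significant_gc_ab"] = \
                    bool(frame.loc[ridx, "gc_ab"] > thr_ab)
                frame.loc[ridx, "significant_gc_ba"] = \
                    bool(frame.loc[ridx, "gc_ba"] > thr_ba)


def _volume_conduction_stage(rec: Recording, cfg: PipelineConfig, order: int,
                             seed: int):
    """Source-shift surrogate + y=x goodness-of-fit on pooled window x pair GC."""
    fs = rec.fs
    loc = rec.markers.get("LOC", 0)
    start = loc + int(cfg.post_induction_skip * fs)
    stop = min(rec.n_samples, start + int(cfg.vc_duration_s * fs))
    if stop - start < int(8 * cfg.window_s * fs):
        start, stop = 0, rec.n_samples
    keep = [i for i, lbl in enumerate(rec.labels)
            if lbl not in rec.excluded_channels]
    segment = rec.signal[keep, start:stop]
    labels = tuple(rec.labels[i] for i in keep)

    scfg = replace(cfg.surrogate, seed=seed)
    surr = surrogates.source_shift_surrogate(segment, scfg)

    win = int(cfg.window_s * fs)
    step = int(cfg.step_s * fs)

    def gc_values(sig: np.ndarray) -> np.ndarray:
        from .gc import granger_pair

        sub = Recording(signal=sig, labels=labels, fs=fs)
        rs = ingest.average_regions(sub)
        starts = np.arange(0, sig.shape[1] - win + 1, step)
        idx = np.unique(np.linspace(0, len(starts) - 1,
                                    min(cfg.vc_windows, len(starts))
                                    ).astype(int))
        pairs = all_region_pairs(rs.regions)
        vals = []
        for i in idx:
            s = int(starts[i])
            data = {r: rs.data[r][s:s + win] for r in rs.regions}
            for a, b in pairs:
                est = granger_pair(data[a], data[b], order)
                if not est.undefined:
                    vals.extend([est.gc_12, est.gc_21])
        return np.asarray(vals)

    gc_orig = gc_values(segment)
    gc_surr = gc_values(surr)
    n = min(len(gc_orig), len(gc_surr))
    return surrogates.volume_conduction_check(gc_orig[:n], gc_surr[:n])


__all__ = [
    "PipelineConfig", "StudyResults", "GrangerStateStudy", "run_pipeline",
]
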