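"""Recording I/O, region averaging and state-labeled window extraction.

The analysis operates on five region-averaged series (LF, RF, LP, RP, Z)
rather than the 19 raw electrodes. Windows are 4 s long, sliding by 1 s,
labeled awake or anesthetized relative to the LOC (anesthetic induction) and
ROC (recovery of consciousness) markers. No frequency filtering is applied by
default at any point before Granger-causality estimation, because filtering
perturbs the timing relations the measure depends on; the 50-Hz notch is an
explicitly opt-in comparison path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import REGION_NAMES, REGIONS, normalize_label

AWAKE, ANESTH = "awake", "anesthetized"


@dataclass
class Recording:
    """Raw multichannel recording: channels x samples, 10/20 labels, sampling
    rate, named marker samples, and labels excluded from region averaging."""

    signal: np.ndarray
    labels: tuple[str, ...]
    fs: float
    markers: dict[str, int] = field(default_factory=dict)
    excluded_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = tuple(normalize_label(c) for c in self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        n = self.signal.shape[1]
        for name, s in self.markers.items():
            if not 0 <= s < n:
                raise ValueError(f"marker {name!r} at sample {s} outside recording")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class RegionSignals:
    """Region-averaged series with the electrode membership actually used.

    Regions with no usable electrode are absent from ``data`` (never silently
    zero); downstream pair enumeration skips them.
    """

    data: dict[str, np.ndarray]
    membership: dict[str, list[str]]
    fs: float
    markers: dict[str, int] = field(default_factory=dict)
    filtered: bool = False

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(r for r in REGION_NAMES if r in self.data)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.data.values())))


QC_FLAGS = ("stationary", "dw_ok", "consistent", "artifact_free")


@dataclass
class WindowSet:
    """State-labeled 4-s windows over region signals plus per-window QC flags.

    ``table`` has one row per window: condition (LOC/ROC), state, start
    (samples), start_s, and the four boolean QC columns. Diagnostics other
    than the artifact rule are filled in by :func:`anesgc.armodel.run_diagnostics`.
    A window enters feature extraction only when all four flags are true.
    """

    regions: RegionSignals
    table: pd.DataFrame
    win_samples: int
    step_samples: int

    def data(self, i: int) -> dict[str, np.ndarray]:
        s = int(self.table.iloc[i]["start"])
        return {r: self.regions.data[r][s:s + self.win_samples]
                for r in self.regions.regions}

    @property
    def admitted(self) -> np.ndarray:
        """Boolean mask of windows passing all four QC gates."""
        return self.table[list(QC_FLAGS)].fillna(False).all(axis=1).to_numpy()

    def attrition(self) -> dict[str, int]:
        """Per-gate exclusion bookkeeping.

        Gates are counted hierarchically (artifact, stationarity,
        Durbin-Watson, consistency): a window is charged to the first gate it
        fails, so admitted plus the per-gate counts sums to the total.
        """
        t = self.table
        out = {"total": len(t), "admitted": int(self.admitted.sum())}
        surviving = np.ones(len(t), dtype=bool)
        for flag in ("artifact_free", "stationary", "dw_ok", "consistent"):
            col = t[flag].fillna(False).to_numpy(dtype=bool)
            out[f"failed_{flag}"] = int((surviving & ~col).sum())
            surviving &= col
        return out

    def to_table(self) -> pd.DataFrame:
        return self.table.copy()


# ---------------------------------------------------------------------------
# reading

def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read an EDF file or a delimited channel-matrix text file (+ JSON
    sidecar with fs/markers). The signal is returned unfiltered."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _read_edf(path)
    if format in ("matrix", "matrix+json"):
        return _read_matrix(path)
    raise ValueError(f"unknown format {format!r}")


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6          # MNE returns volts for uV channels
    labels = tuple(normalize_label(c) for c in raw.ch_names)
    meta = _read_sidecar(path)
    fs = float(meta.get("fs", raw.info["sfreq"]))
    markers = {n: int(s) for n, s in meta.get("markers", [])}
    return Recording(signal=signal, labels=labels, fs=fs, markers=markers)


def _read_matrix(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
    delim = "\t" if "\t" in header else None
    raw_labels = header.split(delim)
    unknown = []
    labels = []
    for lbl in raw_labels:
        try:
            labels.append(normalize_label(lbl))
        except ValueError:
            unknown.append(lbl)
    if unknown:
        raise ValueError(f"unknown channel labels in header: {unknown}")
    data = np.loadtxt(path, skiprows=1, delimiter=delim)
    meta = _read_sidecar(path)
    if "fs" not in meta:
        raise ValueError(f"sampling rate not found: no sidecar {path}.json with 'fs'")
    markers = {n: int(s) for n, s in meta.get("markers", [])}
    return Recording(signal=data.T, labels=tuple(labels), fs=float(meta["fs"]),
                     markers=markers)


# ---------------------------------------------------------------------------
# channel exclusion and region averaging

def detect_bad_channels(rec: Recording, flat_tol: float = 0.5,
                        clip_fraction: float = 0.05) -> list[str]:
    """Signal-based proxy for impedance-driven electrode exclusion.

    Flags channels that are near-constant (variance < ``flat_tol``) or
    saturated (at least ``clip_fraction`` of samples pinned at the channel's
    extreme value). Detected labels are appended to ``excluded_channels``.
    """
    bad = []
    for i, lbl in enumerate(rec.labels):
        x = rec.signal[i]
        if np.var(x) < flat_tol:
            bad.append(lbl)
            continue
        lo, hi = x.min(), x.max()
        frac = max(np.mean(x == lo), np.mean(x == hi))
        if frac >= clip_fraction:
            bad.append(lbl)
    for lbl in bad:
        if lbl not in rec.excluded_channels:
            rec.excluded_channels.append(lbl)
    return bad


def average_regions(rec: Recording) -> RegionSignals:
    """Sample-wise arithmetic mean over each region's usable electrodes.

    A region whose electrodes are all missing or excluded is marked absent
    (omitted from the output) rather than zero-filled.
    """
    index = {lbl: i for i, lbl in enumerate(rec.labels)}
    excluded = set(rec.excluded_channels)
    data: dict[str, np.ndarray] = {}
    membership: dict[str, list[str]] = {}
    for region, members in REGIONS.items():
        usable = [m for m in members if m in index and m not in excluded]
        if not usable:
            continue
        data[region] = rec.signal[[index[m] for m in usable]].mean(axis=0)
        membership[region] = usable
    return RegionSignals(data=data, membership=membership, fs=rec.fs,
                         markers=dict(rec.markers))


def notch_50hz(rs: RegionSignals, q: float = 30.0) -> RegionSignals:
    """Opt-in second-order IIR notch at 50 Hz, applied causally per region.

    Returned signals carry ``filtered=True`` so reports can compare filtered
    against unfiltered GC.
    """
    if rs.fs <= 100:
        raise ValueError("50-Hz notch requires fs > 100 Hz")
    b, a = sps.iirnotch(50.0, q, fs=rs.fs)
    data = {r: sps.lfilter(b, a, x) for r, x in rs.data.items()}
    return RegionSignals(data=data, membership=dict(rs.membership), fs=rs.fs,
                         markers=dict(rs.markers), filtered=True)


# ---------------------------------------------------------------------------
# window extraction

def _window_starts(seg_start: int, seg_end: int, win: int, step: int) -> np.ndarray:
    """Half-open window starts: [start, start+win) fully inside the segment."""
    if seg_end - seg_start < win:
        return np.empty(0, dtype=int)
    return np.arange(seg_start, seg_end - win + 1, step)


def extract_state_segments(rs: RegionSignals, post_induction_skip: float = 300.0,
                           n_anesth_windows: int = 300,
                           window_s: float = 4.0, step_s: float = 1.0,
                           artifact_mad_k: float = 8.0) -> WindowSet:
    """Cut state-labeled sliding windows around the LOC and ROC markers.

    Awake windows come from before LOC (condition LOC) and after ROC
    (condition ROC). Anesthetized windows start ``post_induction_skip``
    seconds after LOC (condition LOC; the skip removes intubation artifacts
    and guarantees full unconsciousness) and end at ROC (condition ROC);
    each anesthetized set is capped at ``n_anesth_windows`` (the earliest
    eligible windows for LOC, the latest for ROC).

    Artifact QC is applied here: a window is flagged not artifact-free when
    any sample of any region deviates from the segment median by more than
    ``artifact_mad_k`` scaled MADs. The remaining QC flags are left unset.
    """
    if "LOC" not in rs.markers or "ROC" not in rs.markers:
        raise ValueError("markers LOC and ROC are required")
    fs = rs.fs
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    loc, roc = rs.markers["LOC"], rs.markers["ROC"]
    n = rs.n_samples
    skip = int(round(post_induction_skip * fs))

    segments = [
        ("LOC", AWAKE, _window_starts(0, loc, win, step)),
        ("LOC", ANESTH, _window_starts(loc + skip, roc, win, step)[:n_anesth_windows]),
        ("ROC", ANESTH, _window_starts(loc + skip, roc, win, step)[-n_anesth_windows:]),
        ("ROC", AWAKE, _window_starts(roc, n, win, step)),
    ]

    rows = []
    for cond, state, starts in segments:
        if starts.size == 0:
            continue
        seg = {r: rs.data[r][starts[0]: starts[-1] + win] for r in rs.regions}
        ok = _artifact_free(seg, starts - starts[0], win, artifact_mad_k)
        for s, good in zip(starts, ok):
            rows.append({
                "condition": cond, "state": state, "start": int(s),
                "start_s": s / fs,
                "stationary": pd.NA, "dw_ok": pd.NA, "consistent": pd.NA,
                "artifact_free": bool(good),
            })
    table = pd.DataFrame(rows, columns=[
        "condition", "state", "start", "start_s", *QC_FLAGS,
    ])
    for flag in ("stationary", "dw_ok", "consistent"):
        table[flag] = table[flag].astype("boolean")
    table["artifact_free"] = table["artifact_free"].astype("boolean")
    return WindowSet(regions=rs, table=table, win_samples=win, step_samples=step)


def _artifact_free(seg: dict[str, np.ndarray], rel_starts: np.ndarray,
                   win: int, k: float) -> np.ndarray:
    """Robust amplitude rule per window: all samples within k scaled MADs of
    the segment median, per region."""
    ok = np.ones(len(rel_starts), dtype=bool)
    for x in seg.values():
        med = np.median(x)
        mad = 1.4826 * np.median(np.abs(x - med))
        if mad == 0:
            continue
        outlier = np.abs(x - med) > k * mad
        if not outlier.any():
            continue
        for j, s in enumerate(rel_starts):
            if outlier[s:s + win].any():
                ok[j] = False
    return ok


__all__ = [
    "Recording", "RegionSignals", "WindowSet", "QC_FLAGS", "AWAKE", "ANESTH",
    "read_recording", "detect_bad_channels", "average_regions",
    "notch_50hz", "extract_state_segments",
]
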