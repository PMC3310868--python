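"""Synthetic multichannel EEG-like recordings with a state-switching VAR core.

The generator emulates the statistical structure the downstream analysis
assumes: five latent region sources follow stable AR dynamics; during the
"anesthetized" span the two posterior sources additionally receive a lag-1
drive from the two frontal sources' innovations, which switches off again at
recovery. Driving through the innovations (rather than the filtered source
values) keeps every pairwise frontal/posterior VAR well specified — the
omitted second driver contributes white, not autocorrelated, residual
variance — so the residual-whiteness admission gate behaves on synthetic
data the way it does on real recordings.
Every electrode of a region observes that region's source plus independent
sensor noise, so region averaging remains a meaningful noise-reduction step.
Optional nuisances — 50-Hz line noise, sparse high-amplitude artifact bursts,
flat-lined bad channels, and an instantaneous mixing matrix — are applied on
top of the clean channel signals.

This is not a biophysical EEG model (no 1/f background, no dipole forward
model); it reproduces only the second-order structure that pairwise
Granger-causality analysis relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from scipy.signal import lfilter as sps_lfilter

from ._var import companion_spectral_radius
from .montage import CHANNELS_1020, REGION_NAMES, REGIONS, normalize_label

_BURN = 512
_SIGNAL_SCALE = 10.0  # maps unit-variance sources onto a µV-like range

#: (modulus, frequency Hz) of the complex pole pairs defining each source's
#: own AR dynamics; chosen to give a stable, oscillatory, EEG-flavored
#: spectrum (alpha-, theta- and beta-band resonances).
_POLE_PAIRS = ((0.50, 10.0), (0.40, 4.0), (0.30, 20.0))


def _own_ar_coefficients(p: int, fs: float) -> np.ndarray:
    """AR(p) coefficients a_1..a_p from damped-oscillator pole pairs."""
    poly = np.array([1.0])
    remaining = p
    i = 0
    while remaining >= 2:
        r, f = _POLE_PAIRS[i % len(_POLE_PAIRS)]
        theta = 2.0 * np.pi * f / fs
        pair = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
        poly = np.convolve(poly, pair)
        remaining -= 2
        i += 1
    if remaining == 1:
        poly = np.convolve(poly, np.array([1.0, -0.4]))
    return -poly[1:]


def _ar_unit_variance_scale(coefs: np.ndarray) -> float:
    """Innovation scale giving the AR process unit stationary variance.

    Clustered low-frequency poles amplify the innovations substantially, so
    the stationary variance is computed exactly (discrete Lyapunov equation
    on the companion form) and inverted.
    """
    from scipy.linalg import solve_discrete_lyapunov

    p = len(coefs)
    comp = np.zeros((p, p))
    comp[0] = coefs
    if p > 1:
        comp[1:, :-1] = np.eye(p - 1)
    q = np.zeros((p, p))
    q[0, 0] = 1.0
    var = solve_discrete_lyapunov(comp, q)[0, 0]
    return 1.0 / np.sqrt(var)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic recording.

    durations : seconds of (pre-LOC awake, anesthetized, post-ROC awake)
    coupling_awake / coupling_anesth : lag-1 frontal->posterior VAR
        cross-coefficients in the two states (dimensionless)
    ar_order_true : lag order of the generating VAR
    noise_sd : innovation standard deviation of each latent source
    sensor_noise_sd : per-electrode independent white noise, in source units
    line_noise_amp : amplitude (µV-like units) of an added 50-Hz sinusoid
        with an independent random phase per channel
    artifact_rate : expected high-amplitude bursts per minute
    artifact_amplitude : burst height as a multiple of the median channel SD
    bad_channels : labels emitted as near-constant with a large DC offset
    mixing : optional instantaneous channels x channels mixing matrix
    """

    n_channels: int = 19
    fs: float = 256.0
    durations: tuple[float, float, float] = (600.0, 960.0, 600.0)
    coupling_awake: float = 0.0
    coupling_anesth: float = 0.4
    ar_order_true: int = 6
    noise_sd: float = 1.0
    sensor_noise_sd: float = 0.2
    line_noise_amp: float = 0.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 20.0
    bad_channels: tuple[str, ...] = ()
    mixing: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d < 0 for d in self.durations):
            raise ValueError("durations must be non-negative")
        if self.ar_order_true < 1:
            raise ValueError("ar_order_true must be >= 1")
        if self.noise_sd <= 0 or self.sensor_noise_sd < 0:
            raise ValueError("noise standard deviations must be positive")
        if self.line_noise_amp < 0:
            raise ValueError("line_noise_amp must be non-negative")
        if self.artifact_rate < 0 or self.artifact_amplitude < 0:
            raise ValueError("artifact rate/amplitude must be non-negative")
        if self.n_channels != len(CHANNELS_1020):
            raise ValueError(
                f"only the {len(CHANNELS_1020)}-channel 10/20 montage is supported"
            )
        object.__setattr__(
            self, "bad_channels",
            tuple(normalize_label(c) for c in self.bad_channels),
        )
        if self.mixing is not None:
            m = np.asarray(self.mixing, dtype=float)
            if m.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing must be n_channels x n_channels")
            object.__setattr__(self, "mixing", m)
        # construction-time stability check of both regimes
        for name, c in (("awake", self.coupling_awake),
                        ("anesthetized", self.coupling_anesth)):
            rho = companion_spectral_radius(self._var_coefs(c))
            if rho >= 1.0:
                raise ValueError(
                    f"generating VAR is unstable in the {name} state "
                    f"(companion spectral radius {rho:.4f} >= 1)"
                )

    def _var_coefs(self, coupling: float) -> np.ndarray:
        """(p+1, 5, 5) lag matrices of the equivalent latent source VAR.

        The posterior equations receive the frontal innovations at lag 1;
        written on the source values that is +c at lag 1 and -c*a_k at lag
        k+1 (the frontal innovation reconstructed from the frontal past).
        Used for the construction-time stability check.
        """
        p = self.ar_order_true
        own = _own_ar_coefficients(p, self.fs)
        coefs = np.zeros((p + 1, 5, 5))
        for r in range(5):
            for l in range(p):
                coefs[l, r, r] = own[l]
        # frontal (0,1) innovations into posterior (2,3) equations
        for post in (2, 3):
            for front in (0, 1):
                coefs[0, post, front] += coupling
                for k in range(p):
                    coefs[k + 1, post, front] -= coupling * own[k]
        return coefs


@dataclass
class SyntheticRecording:
    """A generated recording plus the ground truth that produced it."""

    signal: np.ndarray          # channels x samples, µV-like
    labels: tuple[str, ...]
    fs: float
    markers: list[tuple[str, int]]
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def marker_sample(self, name: str) -> int:
        for n, s in self.markers:
            if n == name:
                return s
        raise KeyError(name)


def generate_recording(config: SimConfig) -> SyntheticRecording:
    """Simulate a recording per ``config``; identical config+seed gives
    bit-identical output."""
    fs = config.fs
    n_pre, n_an, n_post = (int(round(d * fs)) for d in config.durations)
    n_total = n_pre + n_an + n_post

    ss = np.random.SeedSequence(config.seed)
    rng_src, rng_sensor, rng_line, rng_artifact = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    state = np.zeros(_BURN + n_total, dtype=np.int8)
    state[_BURN + n_pre: _BURN + n_pre + n_an] = 1

    own = _own_ar_coefficients(config.ar_order_true, config.fs)
    scale = _ar_unit_variance_scale(own)
    innov = rng_src.normal(0.0, config.noise_sd * scale,
                           size=(_BURN + n_total, 5))
    # lag-1 frontal-innovation drive into the posterior sources, with the
    # per-sample coupling coefficient switching at the markers
    c_t = np.where(state == 1, config.coupling_anesth, config.coupling_awake)
    u = innov.copy()
    frontal_drive = innov[:-1, 0] + innov[:-1, 1]       # LF + RF innovations
    for post in (2, 3):                                  # LP, RP
        u[1:, post] += c_t[1:] * frontal_drive
    ar_poly = np.concatenate([[1.0], -own])
    sources = sps_lfilter([1.0], ar_poly, u, axis=0)[_BURN:]  # n_total x 5

    region_index = {r: i for i, r in enumerate(REGION_NAMES)}
    chan_region = {
        ch: r for r, members in REGIONS.items() for ch in members
    }
    signal = np.empty((config.n_channels, n_total))
    for i, ch in enumerate(CHANNELS_1020):
        src = sources[:, region_index[chan_region[ch]]]
        noise = rng_sensor.normal(0.0, config.sensor_noise_sd, size=n_total)
        signal[i] = _SIGNAL_SCALE * (src + noise)

    if config.mixing is not None:
        signal = config.mixing @ signal

    if config.line_noise_amp > 0:
        t = np.arange(n_total) / fs
        phases = rng_line.uniform(0.0, 2.0 * np.pi, size=config.n_channels)
        signal += config.line_noise_amp * np.sin(
            2.0 * np.pi * 50.0 * t[None, :] + phases[:, None]
        )

    truth = {
        "state": state[_BURN:].copy(),
        "coupling_awake": config.coupling_awake,
        "coupling_anesth": config.coupling_anesth,
        "bad_channels": list(config.bad_channels),
        "artifacts": [],
    }
    rec = SyntheticRecording(
        signal=signal,
        labels=CHANNELS_1020,
        fs=fs,
        markers=[("LOC", n_pre), ("ROC", n_pre + n_an)],
        truth=truth,
    )

    if config.artifact_rate > 0:
        rec = _add_bursts(rec, config.artifact_rate, config.artifact_amplitude,
                          rng_artifact)

    for ch in config.bad_channels:
        i = CHANNELS_1020.index(ch)
        rec.signal[i] = 200.0 + 1e-3 * rng_sensor.normal(size=n_total)

    return rec


def inject_artifacts(recording: SyntheticRecording, rate: float,
                     amplitude: float, seed: int) -> SyntheticRecording:
    """Add Poisson-timed high-amplitude bursts (<= 0.5 s) across all channels.

    ``rate`` is the expected number of bursts per minute; ``amplitude`` scales
    the burst height in multiples of the median channel standard deviation.
    Burst intervals are appended to ``truth['artifacts']``. ``rate == 0``
    returns the recording unchanged.
    """
    if rate < 0:
        raise ValueError("artifact rate must be non-negative")
    if rate == 0:
        return recording
    out = SyntheticRecording(
        signal=recording.signal.copy(),
        labels=recording.labels,
        fs=recording.fs,
        markers=list(recording.markers),
        truth={**recording.truth, "artifacts": list(recording.truth.get("artifacts", []))},
    )
    return _add_bursts(out, rate, amplitude, np.random.default_rng(seed))


def _add_bursts(rec: SyntheticRecording, rate: float, amplitude: float,
                rng: np.random.Generator) -> SyntheticRecording:
    n = rec.n_samples
    fs = rec.fs
    n_bursts = rng.poisson(rate * n / fs / 60.0)
    scale = amplitude * float(np.median(np.std(rec.signal, axis=1)))
    starts = np.sort(rng.integers(0, max(1, n - 1), size=n_bursts))
    for s in starts:
        dur = int(rng.uniform(0.1, 0.5) * fs)
        e = min(n, int(s) + max(dur, 1))
        envelope = np.sin(np.pi * np.arange(e - s) / (e - s))
        rec.signal[:, s:e] += scale * envelope[None, :]
        rec.truth["artifacts"].append((int(s), int(e)))
    return rec


# ---------------------------------------------------------------------------
# writers

def write_matrix(rec: SyntheticRecording, path: str | Path) -> Path:
    """Write the recording as a delimited channel-matrix text file (one row
    per sample, tab-separated, header of channel labels) plus a JSON sidecar
    holding fs, markers and truth. Returns the sidecar path."""
    path = Path(path)
    header = "\t".join(rec.labels)
    np.savetxt(path, rec.signal.T, fmt="%.6f", delimiter="\t",
               header=header, comments="")
    return _write_sidecar(rec, path)


def write_edf(rec: SyntheticRecording, path: str | Path) -> Path:
    """Write a minimal 16-bit EDF file (1-s data records, physical unit uV)
    plus the JSON sidecar. Returns the sidecar path."""
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))                       # samples per record per signal
    n_ch = len(rec.labels)
    n_rec = rec.n_samples // spr
    data = rec.signal[:, : n_rec * spr]

    pmin = float(np.floor(data.min() - 1.0))
    pmax = float(np.ceil(data.max() + 1.0))
    dmin, dmax = -32768, 32767

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {s!r}")
        return b.ljust(width)

    hdr = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("synthetic recording", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (n_ch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(n_ch), 4),
    ])
    fields = [
        ("".join, [pad(lbl, 16) for lbl in rec.labels]),
        ("".join, [pad("synthetic", 80)] * n_ch),
        ("".join, [pad("uV", 8)] * n_ch),
        ("".join, [pad(f"{pmin:g}", 8)] * n_ch),
        ("".join, [pad(f"{pmax:g}", 8)] * n_ch),
        ("".join, [pad(str(dmin), 8)] * n_ch),
        ("".join, [pad(str(dmax), 8)] * n_ch),
        ("".join, [pad("", 80)] * n_ch),
        ("".join, [pad(str(spr), 8)] * n_ch),
        ("".join, [pad("", 32)] * n_ch),
    ]
    sig_hdr = b"".join(b"".join(parts) for _, parts in fields)

    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((data - pmin) * gain + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return _write_sidecar(rec, path)


def _write_sidecar(rec: SyntheticRecording, data_path: Path) -> Path:
    sidecar = data_path.with_suffix(data_path.suffix + ".json")
    truth = dict(rec.truth)
    if "state" in truth:
        st = np.asarray(truth["state"])
        change = np.flatnonzero(np.diff(st)) + 1
        truth["state_changes"] = [int(c) for c in change]
        truth["initial_state"] = int(st[0]) if st.size else 0
        del truth["state"]
    meta = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "markers": [[n, int(s)] for n, s in rec.markers],
        "truth": truth,
    }
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return sidecar


__all__ = [
    "SimConfig", "SyntheticRecording", "generate_recording",
    "inject_artifacts", "write_matrix", "write_edf",
]
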