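"""Raw ECG handling: containers, file I/O, bandpass filtering, RR artifact rules.

The processing chain mirrors common wearable-ECG practice: a linear-phase
FIR bandpass (3-45 Hz) suppresses baseline drift and powerline interference,
QRS detection (see :mod:`coldface.qrs`) yields R-peak times, and the derived
RR-interval series is cleaned by physiological rate bounds plus statistical
outlier rules before HRV features are computed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal


class EcgError(ValueError):
    pass


@dataclass
class EcgRecording:
    """Single-channel ECG: voltage samples (arbitrary units) at ``fs`` Hz.

    ``t0`` places the first sample on the session clock (seconds).
    """

    samples: np.ndarray
    fs: float = 256.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise EcgError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise EcgError("ECG must be a single channel (1-D array)")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class RPeakSeries:
    """Strictly increasing R-peak times (s, session clock)."""

    peak_times_s: np.ndarray
    source: str = "detected"  # {detected, corrected}

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.size > 1 and np.any(np.diff(self.peak_times_s) <= 0):
            raise EcgError("R-peak times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.peak_times_s.size


# Per-interval artifact flags.
FLAG_OK = "ok"
FLAG_RATE = "removed_rate"
FLAG_OUTLIER = "removed_outlier"
FLAG_DIFF = "removed_diff"
RR_FLAGS = (FLAG_OK, FLAG_RATE, FLAG_OUTLIER, FLAG_DIFF)


@dataclass
class RRSeries:
    """Beat times with the derived RR intervals and per-interval artifact flags.

    ``rr_ms[i]`` is the interval between ``beat_times_s[i]`` and
    ``beat_times_s[i+1]``.  A flag other than ``ok`` marks an interval whose
    value was replaced by linear interpolation; the flag records which rule
    fired.
    """

    beat_times_s: np.ndarray
    rr_ms: np.ndarray
    flags: np.ndarray = None

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.rr_ms.size != max(self.beat_times_s.size - 1, 0):
            raise EcgError("rr_ms must have one entry per beat pair")
        if np.any(self.rr_ms <= 0):
            raise EcgError("RR intervals must be positive")
        if self.flags is None:
            self.flags = np.full(self.rr_ms.size, FLAG_OK, dtype=object)
        else:
            self.flags = np.asarray(self.flags, dtype=object)
            if self.flags.size != self.rr_ms.size:
                raise EcgError("flags must match rr_ms length")

    @classmethod
    def from_peaks(cls, peaks: RPeakSeries) -> "RRSeries":
        t = peaks.peak_times_s
        return cls(beat_times_s=t, rr_ms=np.diff(t) * 1000.0)

    @property
    def n_beats(self) -> int:
        return self.beat_times_s.size

    @property
    def imputed_mask(self) -> np.ndarray:
        return self.flags != FLAG_OK

    def interval_times_s(self) -> np.ndarray:
        """Start time of each RR interval (time of the opening beat)."""
        return self.beat_times_s[:-1]

    def segment(self, start_s: float, end_s: float) -> "RRSeries":
        """Intervals whose opening beat lies in [start_s, end_s)."""
        mask = (self.beat_times_s[:-1] >= start_s) & (self.beat_times_s[:-1] < end_s)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return RRSeries(np.empty(0), np.empty(0), np.empty(0, dtype=object))
        beats = np.append(self.beat_times_s[idx], self.beat_times_s[idx[-1] + 1])
        return RRSeries(beats, self.rr_ms[idx], self.flags[idx])


@dataclass
class ArtifactConfig:
    """Thresholds for the RR-interval artifact rules.

    Intervals outside the physiological heart-rate band [hr_min, hr_max] bpm
    are removed first; then RR values deviating >= ``z_rr`` sigma from the
    mean, and successive RR differences deviating >= ``z_diff`` sigma, are
    removed.  Removed intervals are imputed by linear interpolation.
    """

    hr_min_bpm: float = 45.0
    hr_max_bpm: float = 200.0
    z_rr: float = 2.576
    z_diff: float = 1.96

    def __post_init__(self) -> None:
        if not 0 < self.hr_min_bpm < self.hr_max_bpm:
            raise EcgError("require 0 < hr_min_bpm < hr_max_bpm")
        if self.z_rr <= 0 or self.z_diff <= 0:
            raise EcgError("z thresholds must be positive")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ecg(path, fs: float = 256.0, t0: float = 0.0) -> EcgRecording:
    """Read an ECG recording from CSV (one voltage column) or flat binary.

    The binary dialect is little-endian float32 with a JSON sidecar
    ``<path>.json`` holding ``fs`` and ``t0`` (written by
    :func:`write_ecg`); explicit ``fs``/``t0`` arguments override the
    sidecar.  CSV files may carry a single ``voltage`` header line.
    """
    path = Path(path)
    if not path.exists():
        raise EcgError(f"no such ECG file: {path}")
    if path.suffix in (".bin", ".dat"):
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            fs = meta.get("fs", fs)
            t0 = meta.get("t0", t0)
        samples = np.fromfile(path, dtype="<f4").astype(float)
    else:
        import pandas as pd

        if path.stat().st_size == 0:
            raise EcgError(f"empty ECG file: {path}")
        try:
            df = pd.read_csv(path, header=None, dtype=float)
        except ValueError:  # header line present
            df = pd.read_csv(path, header=0, dtype=float)
        samples = df.iloc[:, 0].to_numpy(float)
    if samples.size == 0:
        raise EcgError(f"empty ECG file: {path}")
    return EcgRecording(samples=samples, fs=fs, t0=t0)


def write_ecg(rec: EcgRecording, path) -> None:
    """Write an ECG recording: ``.bin`` little-endian float32 + JSON sidecar,
    anything else as single-column CSV with a ``voltage`` header."""
    path = Path(path)
    if path.suffix in (".bin", ".dat"):
        rec.samples.astype("<f4").tofile(path)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"fs": rec.fs, "t0": rec.t0}))
    else:
        np.savetxt(path, rec.samples, fmt="%.6f", header="voltage", comments="")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def design_bandpass(fs: float, low_hz: float = 3.0, high_hz: float = 45.0,
                    numtaps: int | None = None) -> np.ndarray:
    """Linear-phase FIR bandpass taps (Hamming window design).

    The default order (two seconds of taps, forced odd) gives >= 20 dB
    attenuation at DC and at 50/60 Hz powerline frequencies for fs = 256 Hz
    while keeping the 3-45 Hz QRS band within about 1 dB of unity.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise EcgError(f"invalid band edges ({low_hz}, {high_hz}) for fs={fs}")
    if numtaps is None:
        numtaps = 2 * int(fs) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs)


def bandpass_filter(rec: EcgRecording, low_hz: float = 3.0, high_hz: float = 45.0,
                    numtaps: int | None = None) -> EcgRecording:
    """Zero-lag FIR bandpass: symmetric taps applied centred, so the group
    delay is compensated and R-peak times are not shifted; output length
    equals input length."""
    taps = design_bandpass(rec.fs, low_hz, high_hz, numtaps)
    # centred convolution == filtering with (numtaps-1)/2 delay removed
    filtered = signal.fftconvolve(rec.samples, taps, mode="same")
    return EcgRecording(samples=filtered, fs=rec.fs, t0=rec.t0)


# ---------------------------------------------------------------------------
# RR artifact rules
# ---------------------------------------------------------------------------

def _interpolate_removed(rr: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Linear interpolation of removed entries between surviving neighbours;
    nearest-value extension at the series edges."""
    out = rr.astype(float).copy()
    idx = np.arange(rr.size)
    if not ok.any():
        raise EcgError("all RR intervals removed; recording unprocessable")
    out[~ok] = np.interp(idx[~ok], idx[ok], rr[ok])
    return out


def rr_artifact_filter(rr: RRSeries, cfg: ArtifactConfig | None = None) -> RRSeries:
    """Flag artifactual RR intervals and impute them by linear interpolation.

    Rules, applied once each, in order: (1) heart rate outside
    [hr_min, hr_max] bpm; (2) RR deviating >= z_rr * sigma from the mean RR;
    (3) successive RR difference deviating >= z_diff * sigma of the
    differences (the later interval of the pair is flagged).  Sigma is
    re-estimated over the surviving intervals after each stage, so a gross
    artifact caught by an earlier rule cannot inflate the spread estimate
    used by a later one.  With sigma = 0 (constant series) the statistical
    rules flag nothing.  Intervals already flagged on input stay flagged,
    are excluded from the estimates and are never re-flagged; total beat
    count is unchanged.
    """
    cfg = cfg or ArtifactConfig()
    if rr.rr_ms.size == 0:
        raise EcgError("empty RR series")
    values = rr.rr_ms.copy()
    flags = rr.flags.copy()
    ok = flags == FLAG_OK

    hr = 60000.0 / values
    rate_bad = ok & ((hr <= cfg.hr_min_bpm) | (hr >= cfg.hr_max_bpm))
    flags[rate_bad] = FLAG_RATE
    ok &= ~rate_bad

    # (2) RR-level outliers against the post-rate-removal distribution
    if ok.sum() >= 2:
        mu, sd = values[ok].mean(), values[ok].std(ddof=0)
        if sd > 0:
            out_bad = ok & (np.abs(values - mu) >= cfg.z_rr * sd)
            flags[out_bad] = FLAG_OUTLIER
            ok &= ~out_bad

    # (3) successive-difference outliers between adjacent surviving intervals
    if ok.sum() >= 3:
        adj = ok[1:] & ok[:-1]
        if adj.any():
            d = values[1:] - values[:-1]
            sd_d = d[adj].std(ddof=0)
            if sd_d > 0:
                dev = np.abs(d[adj] - d[adj].mean())
                bad_pos = np.nonzero(adj)[0][dev >= cfg.z_diff * sd_d] + 1
                flags[bad_pos] = FLAG_DIFF
                ok[bad_pos] = False

    imputed = _interpolate_removed(values, ok)
    return RRSeries(beat_times_s=rr.beat_times_s, rr_ms=imputed, flags=flags)


def read_rr_csv(path) -> RRSeries:
    """Read an RR series CSV with columns beat_time_s, rr_ms, flag."""
    import pandas as pd

    df = pd.read_csv(path)
    beats = df["beat_time_s"].to_numpy(float)
    rr = df["rr_ms"].to_numpy(float)[:-1] if np.isnan(df["rr_ms"].iloc[-1]) \
        else df["rr_ms"].to_numpy(float)[: beats.size - 1]
    flags = df["flag"].astype(str).to_numpy(object)[: rr.size]
    return RRSeries(beat_times_s=beats, rr_ms=rr, flags=flags)


def write_rr_csv(rr: RRSeries, path) -> None:
    """Write an RR series to CSV (last beat carries empty rr/flag)."""
    import pandas as pd

    df = pd.DataFrame({
        "beat_time_s": rr.beat_times_s,
        "rr_ms": np.append(rr.rr_ms, np.nan),
        "flag": np.append(rr.flags, ""),
    })
    df.to_csv(path, index=False, float_format="%.6f")
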