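"""Hamilton-style QRS detection.

Implements the open-source Hamilton (EP Limited) detection rules on a
bandpass-filtered single-lead ECG: the detection function is the absolute
first difference smoothed by an 80 ms moving average; candidate peaks are
classified as QRS or noise by adaptive thresholds maintained from running
averages of the last eight QRS and noise peak heights, with a 200 ms
refractory period, a T-wave rejection rule and a search-back pass that
rescues beats missed during threshold adaptation.

All thresholds are relative to observed peak heights, so detection is
invariant to amplitude scaling of the input signal.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .ecg import EcgRecording, EcgError, RPeakSeries

REFRACTORY_S = 0.200       # minimum QRS-to-QRS spacing
TWAVE_WINDOW_S = 0.360     # candidates this close need the slope-height check
SEARCHBACK_FACTOR = 1.5    # search back when gap exceeds 1.5 x mean RR
TH_COEFF = 0.3125          # detection threshold position between noise and QRS means
SEARCHBACK_TH_COEFF = 0.5  # reduced threshold used during search-back
MA_WINDOW_S = 0.080        # smoothing window of the detection function


def _detection_function(x: np.ndarray, fs: float) -> np.ndarray:
    d = np.abs(np.diff(x, prepend=x[0]))
    w = max(int(round(MA_WINDOW_S * fs)), 1)
    return sps.fftconvolve(d, np.ones(w) / w, mode="same")


def _refine_peak(x: np.ndarray, idx: int, fs: float, half_window_s: float = 0.10) -> int:
    """Snap a detection-function peak to the extremum of |ECG| nearby."""
    hw = int(round(half_window_s * fs))
    lo, hi = max(idx - hw, 0), min(idx + hw + 1, x.size)
    return lo + int(np.argmax(np.abs(x[lo:hi])))


class _RunningMean:
    def __init__(self, init: float, size: int = 8):
        self.buf = [init]
        self.size = size

    def push(self, v: float) -> None:
        self.buf.append(v)
        if len(self.buf) > self.size:
            self.buf.pop(0)

    @property
    def mean(self) -> float:
        return float(np.mean(self.buf))


def detect_r_peaks(rec: EcgRecording) -> RPeakSeries:
    """Detect R peaks on a (filtered) ECG recording.

    Returns strictly increasing peak times on the session clock; no two
    peaks closer than the refractory period.  A flat or featureless signal
    yields an empty series.
    """
    if rec.duration_s < 2.0:
        raise EcgError("recording shorter than 2 s cannot be processed")
    x = rec.samples
    fs = rec.fs
    det = _detection_function(x, fs)
    if det.max() <= 0:
        return RPeakSeries(np.empty(0))

    min_dist = max(int(REFRACTORY_S * fs), 1)
    cand, props = sps.find_peaks(det, distance=min_dist,
                                 height=1e-3 * det.max())
    if cand.size == 0:
        return RPeakSeries(np.empty(0))
    heights = props["peak_heights"]

    # prime the adaptive averages from the first two seconds
    lead = det[: int(2 * fs)]
    qrs_avg = _RunningMean(float(lead.max()))
    noise_avg = _RunningMean(float(np.median(lead)))

    qrs_idx: list[int] = []
    qrs_heights: list[float] = []
    rr_avg = _RunningMean(0.8, size=8)  # seconds; seeded with a nominal RR
    have_rr = False

    def threshold() -> float:
        return noise_avg.mean + TH_COEFF * (qrs_avg.mean - noise_avg.mean)

    # candidates rejected as noise, kept for search-back
    noise_cand: list[tuple[int, float]] = []

    def accept(i: int, h: float) -> None:
        nonlocal have_rr
        if qrs_idx:
            rr = (i - qrs_idx[-1]) / fs
            if have_rr:
                rr_avg.push(rr)
            else:
                rr_avg.buf = [rr]
                have_rr = True
        qrs_idx.append(i)
        qrs_heights.append(h)
        qrs_avg.push(h)

    for i, h in zip(cand, heights):
        th = threshold()
        since_last = (i - qrs_idx[-1]) / fs if qrs_idx else np.inf
        is_qrs = h > th and since_last >= REFRACTORY_S
        # T-wave rule: a close-following candidate with much smaller height
        if is_qrs and since_last < TWAVE_WINDOW_S and h < 0.5 * qrs_heights[-1]:
            is_qrs = False
        if is_qrs:
            # search-back first if a long gap precedes this beat
            if qrs_idx and since_last > SEARCHBACK_FACTOR * rr_avg.mean:
                _search_back(noise_cand, qrs_idx[-1], i, th, accept, fs)
            accept(i, h)
            noise_cand.clear()
        else:
            noise_avg.push(h)
            noise_cand.append((i, h))

    # trailing search-back for a gap at the end of the record
    if qrs_idx and noise_cand:
        last_gap = (cand[-1] - qrs_idx[-1]) / fs
        if last_gap > SEARCHBACK_FACTOR * rr_avg.mean:
            _search_back(noise_cand, qrs_idx[-1], cand[-1] + min_dist,
                         threshold(), accept, fs)

    refined = sorted({_refine_peak(x, i, fs) for i in qrs_idx})
    # enforce refractory after refinement
    peaks: list[int] = []
    for i in refined:
        if peaks and (i - peaks[-1]) / fs < REFRACTORY_S:
            if np.abs(x[i]) > np.abs(x[peaks[-1]]):
                peaks[-1] = i
        else:
            peaks.append(i)
    times = rec.t0 + np.asarray(peaks, float) / fs
    return RPeakSeries(times, source="detected")


def _search_back(noise_cand, last_qrs: int, now: int, th: float, accept, fs: float):
    """Rescue the largest rejected candidate in an overlong RR gap."""
    lo = last_qrs + int(REFRACTORY_S * fs)
    hi = now - int(REFRACTORY_S * fs)
    window = [(i, h) for i, h in noise_cand if lo <= i <= hi]
    if not window:
        return
    i, h = max(window, key=lambda p: p[1])
    if h > SEARCHBACK_TH_COEFF * th:
        accept(i, h)
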