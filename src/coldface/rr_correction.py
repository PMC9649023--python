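"""R-peak correction following the Lipponen & Tarvainen decision rules.

Beats are classified from the series of successive RR differences (dRR)
normalised by a time-varying threshold (5.2 x the quartile deviation over a
91-beat window), together with deviations from an 11-beat running median RR
(mRR).  Patterns in the (dRR, neighbour-dRR) subspace identify ectopic
(short-long / long-short) beats; overlong or overshort intervals consistent
with half or double the local median identify missed and extra beats;
remaining large deviations are treated as misaligned detections.

Corrections operate on beat times: extra beats are deleted, missed beats are
inserted at the interval midpoint, ectopic/misaligned beats are moved to the
midpoint of their neighbours.  Each correction is logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import RPeakSeries

ALPHA = 5.2          # threshold scale on the quartile deviation
DRR_WINDOW = 91      # beats used for the time-varying threshold
MED_WINDOW = 11      # beats used for the running median RR
C1, C2 = 0.13, 0.17  # ectopic decision-line constants
MISALIGNED_MRR = 3.0 # |mRR|/th2 needed to call a lone deviation misaligned


@dataclass
class CorrectionLog:
    """Per-beat record of applied corrections: (beat_index, kind)."""

    entries: list[tuple[int, str]] = field(default_factory=list)

    def add(self, index: int, kind: str) -> None:
        self.entries.append((index, kind))

    def __len__(self) -> int:
        return len(self.entries)


def _rolling_qd(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling quartile deviation (half the IQR)."""
    s = pd.Series(x)
    q1 = s.rolling(window, center=True, min_periods=3).quantile(0.25)
    q3 = s.rolling(window, center=True, min_periods=3).quantile(0.75)
    return ((q3 - q1) / 2.0).to_numpy()


def _classify(beats: np.ndarray):
    """Return (index, kind) of the first suspicious interval, or None.

    Interval i spans beats[i] .. beats[i+1].
    """
    rr = np.diff(beats)
    n = rr.size
    if n < 4:
        return None
    drr = np.diff(rr, prepend=rr[0])
    th1 = ALPHA * _rolling_qd(drr, DRR_WINDOW)
    med = pd.Series(rr).rolling(MED_WINDOW, center=True, min_periods=1).median().to_numpy()
    mrr = rr - med
    mrr = np.where(mrr < 0, 2 * mrr, mrr)
    th2 = ALPHA * _rolling_qd(mrr, DRR_WINDOW)

    with np.errstate(divide="ignore", invalid="ignore"):
        drr_n = np.where(th1 > 0, drr / np.where(th1 > 0, th1, 1.0), 0.0)
        mrr_n = np.where(th2 > 0, mrr / np.where(th2 > 0, th2, 1.0), 0.0)

    for i in range(n):
        s11 = drr_n[i]
        if abs(s11) <= 1 and abs(mrr_n[i]) <= MISALIGNED_MRR:
            continue
        prev_d = drr_n[i - 1] if i >= 1 else 0.0
        next_d = drr_n[i + 1] if i + 1 < n else 0.0
        s12 = max(prev_d, next_d) if s11 > 0 else min(prev_d, next_d)
        # ectopic: negative-positive-negative (or inverse) dRR pattern
        if (s11 > 1 and s12 < -C1 * s11 - C2) or (s11 < -1 and s12 > -C1 * s11 + C2):
            return i, "ectopic"
        # missed beat: interval close to twice the local median
        if th2[i] > 0 and abs(rr[i] / 2.0 - med[i]) < th2[i] and rr[i] > med[i]:
            return i, "missed"
        # extra beat: two adjacent intervals sum to the local median
        if (i + 1 < n and th2[i] > 0
                and abs(rr[i] + rr[i + 1] - med[i]) < th2[i]):
            return i, "extra"
        if abs(mrr_n[i]) > MISALIGNED_MRR:
            return i, "misaligned"
    return None


def correct_r_peaks(peaks: RPeakSeries, rec=None, max_corrections: int | None = None
                    ) -> tuple[RPeakSeries, CorrectionLog]:
    """Correct ectopic / missed / extra / misaligned beats in a peak series.

    Returns the corrected series (``source='corrected'``) and a log of the
    applied corrections.  An artifact-free series is returned unchanged.
    The optional ``rec`` argument is accepted for interface symmetry; the
    correction operates purely on beat timing.
    """
    beats = peaks.peak_times_s.copy()
    log = CorrectionLog()
    if max_corrections is None:
        max_corrections = max(beats.size // 10, 10)

    for _ in range(max_corrections):
        hit = _classify(beats)
        if hit is None:
            break
        i, kind = hit
        if kind == "extra":
            # delete the beat separating intervals i and i+1
            beats = np.delete(beats, i + 1)
        elif kind == "missed":
            beats = np.insert(beats, i + 1, beats[i] + (beats[i + 1] - beats[i]) / 2.0)
        else:  # ectopic or misaligned: re-centre the offending beat
            if 1 <= i + 1 < beats.size - 1:
                beats[i + 1] = (beats[i] + beats[i + 2]) / 2.0
            else:
                beats = np.delete(beats, min(i + 1, beats.size - 1))
        log.add(i, kind)

    return RPeakSeries(beats, source="corrected"), log
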