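"""Time-domain heart-rate and HRV measures with baseline normalisation.

Three measures are computed per protocol subphase:

* ``hr_bpm``   — mean heart rate, 60000 / mean(RR in ms)
* ``rmssd_ms`` — root mean square of successive RR differences
* ``prr50_pct``— percentage of successive RR differences > 50 ms

Each participant's measures are normalised to their 15-min Global Baseline
(``BL_Glo``) and expressed as percent change, so ``delta`` values read as
"+25" = 25 % above resting level.  The temporal statistic ``t_glo``
quantifies, for a subphase, the percentage of time a 10-beat sliding-window
measure exceeded its Global Baseline value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg import RRSeries
from .protocol import SUBPHASE_NAMES, StudyProtocol

MEASURES = ("hr_bpm", "rmssd_ms", "prr50_pct")


@dataclass
class HrvMeasures:
    hr_bpm: float
    rmssd_ms: float
    prr50_pct: float

    def as_dict(self) -> dict[str, float]:
        return {"hr_bpm": self.hr_bpm, "rmssd_ms": self.rmssd_ms,
                "prr50_pct": self.prr50_pct}

    def __getitem__(self, key: str) -> float:
        return self.as_dict()[key]


@dataclass
class BaselineReference:
    """Per-participant Global Baseline measures (computed pre-stress)."""

    participant: str
    bl_glo: HrvMeasures


def compute_measures(rr_ms: np.ndarray | RRSeries) -> HrvMeasures:
    """Compute HR, RMSSD and pRR50 over one RR segment.

    Fewer than 2 intervals gives an all-NaN result with a warning; RMSSD
    and pRR50 additionally need >= 3 intervals (2 successive differences)
    to be meaningful and are NaN below that.
    """
    if isinstance(rr_ms, RRSeries):
        rr_ms = rr_ms.rr_ms
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        warnings.warn(f"segment has {rr.size} RR intervals; measures undefined",
                      stacklevel=2)
        return HrvMeasures(np.nan, np.nan, np.nan)
    hr = 60000.0 / rr.mean()
    d = np.diff(rr)
    if rr.size < 3:
        return HrvMeasures(hr, np.nan, np.nan)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    prr50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    return HrvMeasures(hr, rmssd, prr50)


def normalize_to_baseline(m: HrvMeasures, ref: BaselineReference) -> HrvMeasures:
    """Percent change of each measure relative to the Global Baseline.

    A zero baseline value (possible for pRR50 in very regular hearts) makes
    the corresponding normalised measure undefined (NaN, with a warning).
    """
    out = {}
    for key in MEASURES:
        base = ref.bl_glo[key]
        val = m[key]
        if base == 0 or np.isnan(base):
            warnings.warn(f"baseline {key} is zero/undefined; "
                          "normalised value set to NaN", stacklevel=2)
            out[key] = np.nan
        else:
            out[key] = 100.0 * (val - base) / base
    return HrvMeasures(**out)


def denormalize(norm: HrvMeasures, ref: BaselineReference) -> HrvMeasures:
    """Inverse of :func:`normalize_to_baseline` (raw values from % change)."""
    out = {k: ref.bl_glo[k] * (1.0 + norm[k] / 100.0) for k in MEASURES}
    return HrvMeasures(**out)


# ---------------------------------------------------------------------------
# sliding-window statistics
# ---------------------------------------------------------------------------

def sliding_window_measure(rr_ms: np.ndarray, measure: str, n: int = 10) -> np.ndarray:
    """Measure evaluated over every window of ``n`` consecutive RR intervals.

    Window w covers intervals [w, w+n); the window advances one beat at a
    time.  Returns one value per window (len(rr) - n + 1 windows).
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < n:
        return np.empty(0)
    sw = np.lib.stride_tricks.sliding_window_view(rr, n)
    if measure == "hr_bpm":
        return 60000.0 / sw.mean(axis=1)
    d = np.diff(sw, axis=1)
    if measure == "rmssd_ms":
        return np.sqrt(np.mean(d ** 2, axis=1))
    if measure == "prr50_pct":
        return 100.0 * np.mean(np.abs(d) > 50.0, axis=1)
    raise KeyError(f"unknown measure {measure!r}")


def t_glo_fraction(rr: RRSeries | np.ndarray, baseline_value: float,
                   measure: str, n: int = 10) -> float:
    """Percentage of subphase time a windowed measure exceeded baseline.

    Every 10-beat window is compared against the participant's Global
    Baseline value of the same measure (strictly above; ties count as
    not-above).  Because windows overlap, each RR interval is covered by up
    to ``n`` windows; the interval's above-baseline fraction is the mean of
    its covering windows' indicators, and the result is the RR-duration-
    weighted average of those fractions — i.e. percentage of *time*, not of
    windows.  Segments shorter than ``n`` intervals give NaN with a warning.
    """
    rr_ms = rr.rr_ms if isinstance(rr, RRSeries) else np.asarray(rr, float)
    if rr_ms.size < n:
        warnings.warn(f"segment has {rr_ms.size} < {n} intervals; "
                      "t_glo undefined", stacklevel=2)
        return np.nan
    if np.isnan(baseline_value):
        return np.nan
    wvals = sliding_window_measure(rr_ms, measure, n)
    above = (wvals > baseline_value).astype(float)
    # coverage count of interval i: windows w with w <= i <= w + n - 1
    n_win = above.size
    cover = np.zeros(rr_ms.size)
    hits = np.zeros(rr_ms.size)
    # vectorised accumulation via cumulative sums of the indicator
    csum = np.concatenate([[0.0], np.cumsum(above)])
    for i in range(rr_ms.size):
        lo = max(i - n + 1, 0)
        hi = min(i, n_win - 1)
        if hi < lo:
            continue
        cover[i] = hi - lo + 1
        hits[i] = csum[hi + 1] - csum[lo]
    covered = cover > 0
    frac = hits[covered] / cover[covered]
    weights = rr_ms[covered]
    return float(100.0 * np.average(frac, weights=weights))


def peak_bradycardia_pct(rr: RRSeries, protocol: StudyProtocol, phase: int,
                         n: int = 10) -> float:
    """Peak cold-face bradycardia in one MIST phase, percent.

    The minimum 10-beat sliding-window heart rate during the RP/CFI
    subphase, expressed as percent decrease relative to the mean heart
    rate of the immediately preceding BL subphase.  Positive values =
    bradycardia; negative = tachycardia during the intervention window.
    """
    bl = protocol.subphase(phase, "BL")
    cfi = protocol.subphase(phase, "RP_CFI")
    rr_bl = rr.segment(bl.start_s, bl.end_s)
    rr_cfi = rr.segment(cfi.start_s, cfi.end_s)
    if rr_bl.rr_ms.size < 2 or rr_cfi.rr_ms.size < n:
        warnings.warn("too few beats for peak bradycardia", stacklevel=2)
        return np.nan
    bl_hr = 60000.0 / rr_bl.rr_ms.mean()
    min_hr = sliding_window_measure(rr_cfi.rr_ms, "hr_bpm", n).min()
    return float(100.0 * (1.0 - min_hr / bl_hr))


# ---------------------------------------------------------------------------
# per-participant subphase tables
# ---------------------------------------------------------------------------

def global_baseline_reference(rr: RRSeries, protocol: StudyProtocol,
                              participant: str = "") -> BaselineReference:
    """Measures over the whole (untrimmed) Global Baseline segment."""
    seg = rr.segment(protocol.global_baseline.start_s, protocol.global_baseline.end_s)
    return BaselineReference(participant, compute_measures(seg))


def subphase_table(rr: RRSeries, protocol: StudyProtocol, ref: BaselineReference,
                   participant: str = "", condition: str = "",
                   window_beats: int = 10) -> pd.DataFrame:
    """Long-format table of raw, normalised and t_glo measures per subphase."""
    rows = []
    for phase in (1, 2, 3):
        for sub in SUBPHASE_NAMES:
            seg = protocol.subphase(phase, sub)
            rseg = rr.segment(seg.start_s, seg.end_s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_measures(rseg)
                norm = normalize_to_baseline(m, ref)
                for meas in MEASURES:
                    tg = t_glo_fraction(rseg, ref.bl_glo[meas], meas, window_beats)
                    rows.append({
                        "participant": participant, "condition": condition,
                        "phase": phase, "subphase": sub, "measure": meas,
                        "value": m[meas], "normalized_value": norm[meas],
                        "t_glo": tg,
                    })
    return pd.DataFrame(rows)
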