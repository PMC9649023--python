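"""Salivary cortisol curve metrics.

From the six analysis samples S1..S6 (nmol/L at minutes 0, 30, 40, 50, 60,
70 relative to MIST start) the module derives the standard summary measures:

* ``auc_g`` — trapezoidal area under the curve with respect to ground,
  total cortisol output over the observation window (nmol*min/L)
* ``auc_i`` — area with respect to increase, ``auc_g`` minus the baseline
  rectangle ``c1*(t6-t1)``; may be negative and indexes HPA-axis reactivity
* ``delta_c_max`` — maximum increase over the first sample, as percent of c1
* ``slope_s1_s4`` — cortisol slope between S1 and S4 (nmol/(L*min))

The pre-protocol screening sample S0 takes no part in these metrics; it is
only used to flag participants with an elevated baseline (cohort screen at
mean + 3 SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CortisolError(ValueError):
    pass


@dataclass
class CortisolProfile:
    """One participant's cortisol samples S1..S6 plus the S0 screen."""

    participant: str
    times_min: np.ndarray          # t1..t6, minutes relative to MIST start
    conc_nmol_l: np.ndarray        # c1..c6
    s0_nmol_l: float = np.nan
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.conc_nmol_l = np.asarray(self.conc_nmol_l, dtype=float)
        if self.times_min.size != 6 or self.conc_nmol_l.size != 6:
            raise CortisolError("profile requires exactly 6 analysis samples (S1..S6)")
        if np.any(np.diff(self.times_min) <= 0):
            raise CortisolError("sample times must be strictly increasing")
        if np.any(self.conc_nmol_l < 0):
            raise CortisolError("concentrations must be non-negative")


@dataclass
class CortisolMetrics:
    auc_g: float
    auc_i: float
    delta_c_max: float      # percent of c1 (see delta_c_max_abs for nmol/L)
    slope_s1_s4: float
    delta_c_max_abs: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {"auc_g": self.auc_g, "auc_i": self.auc_i,
                "delta_c_max": self.delta_c_max,
                "slope_s1_s4": self.slope_s1_s4,
                "delta_c_max_abs": self.delta_c_max_abs}


def auc_g(p: CortisolProfile) -> float:
    """Trapezoidal area under the cortisol curve over [t1, t6]."""
    return float(np.trapezoid(p.conc_nmol_l, p.times_min))


def auc_i(p: CortisolProfile) -> float:
    """Area with respect to increase: auc_g minus the c1 baseline rectangle."""
    span = p.times_min[-1] - p.times_min[0]
    return auc_g(p) - float(p.conc_nmol_l[0]) * span


def response_metrics(p: CortisolProfile) -> CortisolMetrics:
    """All curve metrics for one profile.

    ``delta_c_max`` is reported as percent increase over c1, matching the
    convention of reporting maximum cortisol increase in %; the absolute
    difference (nmol/L) is carried alongside.  A zero first sample leaves
    the percentage undefined (NaN with warning).
    """
    c = p.conc_nmol_l
    t = p.times_min
    abs_inc = float(c[1:].max() - c[0])
    if c[0] == 0:
        warnings.warn("c1 = 0: percent delta_c_max undefined", stacklevel=2)
        pct = np.nan
    else:
        pct = 100.0 * abs_inc / float(c[0])
    slope = float((c[3] - c[0]) / (t[3] - t[0]))
    return CortisolMetrics(auc_g=auc_g(p), auc_i=auc_i(p), delta_c_max=pct,
                           slope_s1_s4=slope, delta_c_max_abs=abs_inc)


def screen_baseline(s0_values: np.ndarray, z: float = 3.0) -> np.ndarray:
    """Cohort-level S0 screen: flag values above mean + z * SD.

    The mean and SD are computed once over the whole cohort (each
    participant contributes, including prospective outliers).  Requires at
    least 3 participants.  An all-equal cohort (SD = 0) flags nobody.
    """
    s0 = np.asarray(s0_values, dtype=float)
    if s0.size < 3:
        raise CortisolError("baseline screen requires >= 3 participants")
    sd = s0.std(ddof=0)
    if sd == 0:
        return np.zeros(s0.size, dtype=bool)
    return s0 > s0.mean() + z * sd


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_saliva_csv(path) -> list[CortisolProfile]:
    """Read profiles from a long-format saliva CSV.

    Columns: participant, condition, sample (S0..S6), time_min,
    cortisol_nmol_l.
    """
    df = pd.read_csv(path)
    profiles = []
    for (pid,), g in df.groupby(["participant"], sort=True):
        g = g.set_index("sample")
        s0 = float(g.loc["S0", "cortisol_nmol_l"]) if "S0" in g.index else np.nan
        rows = g.loc[[f"S{i}" for i in range(1, 7)]]
        profiles.append(CortisolProfile(
            participant=str(pid),
            times_min=rows["time_min"].to_numpy(float),
            conc_nmol_l=rows["cortisol_nmol_l"].to_numpy(float),
            s0_nmol_l=s0,
            condition=str(g["condition"].iloc[0]) if "condition" in g else "",
        ))
    return profiles


def metrics_table(profiles: list[CortisolProfile]) -> pd.DataFrame:
    """Per-participant metrics table for a cohort."""
    rows = []
    for p in profiles:
        m = response_metrics(p)
        rows.append({"participant": p.participant, "condition": p.condition,
                     "s0_nmol_l": p.s0_nmol_l, **m.as_dict()})
    return pd.DataFrame(rows)
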