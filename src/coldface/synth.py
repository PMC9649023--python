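"""Synthetic cohort generator: RR trajectories, ECG waveforms, cortisol curves.

The generator emulates the physiological structure the analysis pipeline
assumes, with programmed ground truth carried alongside every signal:

* **Stress tachycardia** — heart rate ramps up during each Arithmetic Task
  (AT) subphase, with escalating peak gains over the three MIST phases and
  exponential recovery during Feedback.
* **Cold Face Test bradycardia** — in the CFT condition, heart rate dips
  during the Cold Face Intervention (CFI): onset 5.6 s after stimulus
  start, linear ramp to peak bradycardia at 35.8 s with a depth of
  22.5 % +/- 9.0 % of the pre-stimulus level, held until stimulus end,
  then exponential recovery.
* **Baseline drift** — the Control condition's per-phase baseline creeps
  upward (incomplete recovery between phases); the CFT condition returns
  to its resting level.
* **Beat-to-beat variability** — white Gaussian RR jitter scaled so the
  expected RMSSD matches a configurable target.
* **Cortisol response** — a log-normal-shaped pulse on an individual
  baseline, peaking 10-20 min after stressor end, with condition-dependent
  amplitude (CFT blunted) and additive sampling noise.

A single global seed drives per-participant substreams, so each participant
is individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cortisol import CortisolProfile
from .ecg import EcgRecording, EcgError, RRSeries, write_ecg, write_rr_csv
from .protocol import StudyProtocol, SUBPHASE_NAMES, build_mist_protocol


class SimulationError(ValueError):
    pass


@dataclass
class CftParams:
    """Cold-face bradycardia kinetics (population means from CFT literature)."""

    onset_s: float = 5.6
    peak_s: float = 35.8
    depth_pct: float = 22.5
    depth_sd_pct: float = 9.0
    recovery_tau_s: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.depth_pct < 100:
            raise SimulationError("depth_pct must be in (0, 100)")
        if self.onset_s >= self.peak_s:
            raise SimulationError("onset must precede peak bradycardia")


@dataclass
class CortisolParams:
    c1_mean: float = 5.0            # nmol/L, afternoon salivary baseline
    c1_sd: float = 1.5
    onset_delay_min: float = 10.0   # secretion onset after MIST start
    peak_delay_min: float = 15.0    # peak after stressor end (10-20 min window)
    shape: float = 0.6              # log-normal width of the response pulse
    amplitude_pct: dict = field(default_factory=lambda: {"Control": 70.0, "CFT": 5.0})
    amplitude_sd_pct: float = 25.0
    noise_sd: float = 0.5           # assay + sampling noise, nmol/L

    def __post_init__(self) -> None:
        if not 10.0 <= self.peak_delay_min <= 20.0:
            raise SimulationError("peak_delay_min must lie in [10, 20] min")


@dataclass
class SimulationConfig:
    """Cohort-level generator settings; defaults mirror the study conditions
    (25 analysed participants: 13 Control, 12 CFT)."""

    seed: int = 0
    n_control: int = 13
    n_cft: int = 12
    baseline_hr_bpm: float = 70.0
    baseline_hr_sd: float = 8.0
    # peak AT tachycardia per MIST phase, % above the global baseline
    stress_gain_pct: tuple = (26.0, 33.0, 39.0)
    stress_gain_sd_pct: float = 5.0
    at_ramp_s: float = 60.0        # time to peak tachycardia within AT
    at_sustain_frac: float = 0.85  # fraction of peak held after the first minute
    fb_recovery_tau_s: float = 40.0
    # Control-condition baseline drift per phase (% above BL_Glo); CFT drifts 0
    bl_drift_pct: tuple = (0.0, 8.0, 15.0)
    bl_drift_sd_pct: float = 3.0
    cft: CftParams = field(default_factory=CftParams)
    rmssd_target_ms: float = 45.0  # 0 disables beat-to-beat noise
    cortisol: CortisolParams = field(default_factory=CortisolParams)
    # planted exclusion archetypes (appended to the nominal cohort)
    n_cft_nonresponders: int = 0
    n_s0_outliers: int = 0
    n_hr_outliers: int = 0
    s0_outlier_nmol_l: float = 21.0
    hr_outlier_gain_factor: float = 2.5
    nonresponder_tachycardia_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_cft < 2:
            raise SimulationError("need at least 2 participants per condition")
        if self.baseline_hr_bpm <= 0 or self.rmssd_target_ms < 0:
            raise SimulationError("invalid rate/variability settings")


@dataclass
class SubjectParams:
    """Per-participant programmed parameters (the simulation ground truth)."""

    participant: str
    condition: str
    baseline_hr_bpm: float
    stress_gain_pct: tuple
    bl_drift_pct: tuple
    cft_depth_pct: float        # negative = planted non-responder tachycardia
    role: str = "normal"        # normal | cft_nonresponder | s0_outlier | hr_outlier


# ---------------------------------------------------------------------------
# instantaneous heart-rate profile
# ---------------------------------------------------------------------------

def programmed_hr(t: float, sp: SubjectParams, cfg: SimulationConfig,
                  protocol: StudyProtocol) -> float:
    """Noise-free instantaneous heart rate (bpm) at session time ``t``."""
    base = sp.baseline_hr_bpm
    mult = 1.0
    dip = 0.0
    for p_idx, phase in enumerate(protocol.mist_phases):
        if not (phase.start_s <= t < phase.end_s):
            continue
        drift = 1.0 + sp.bl_drift_pct[p_idx] / 100.0
        bl, rp, at, fb = phase.subphases
        peak_mult = 1.0 + sp.stress_gain_pct[p_idx] / 100.0
        if t < rp.start_s:                       # BL
            mult = drift
        elif t < at.start_s:                     # RP / CFI
            mult = drift
            if sp.condition == "CFT":
                tr = t - rp.start_s
                c = cfg.cft
                depth = sp.cft_depth_pct / 100.0
                if tr < c.onset_s:
                    dip = 0.0
                elif tr < c.peak_s:
                    dip = depth * (tr - c.onset_s) / (c.peak_s - c.onset_s)
                else:
                    dip = depth
        elif t < fb.start_s:                     # AT
            tr = t - at.start_s
            if sp.condition == "CFT" and cfg.cft.recovery_tau_s > 0:
                dip = (sp.cft_depth_pct / 100.0) * np.exp(-tr / cfg.cft.recovery_tau_s)
            if tr < cfg.at_ramp_s:
                # ramp from the drifted level to the absolute peak multiplier
                mult = drift + (peak_mult - drift) * tr / cfg.at_ramp_s
            else:
                frac = (tr - cfg.at_ramp_s) / max(at.duration_s - cfg.at_ramp_s, 1.0)
                sustain = drift + (peak_mult - drift) * cfg.at_sustain_frac
                mult = peak_mult + (sustain - peak_mult) * frac
        else:                                    # FB: decay back to drifted level
            tr = t - fb.start_s
            sustain = drift + (peak_mult - drift) * cfg.at_sustain_frac
            mult = drift + (sustain - drift) * np.exp(-tr / cfg.fb_recovery_tau_s)
        return base * mult * (1.0 - dip)
    return base  # global baseline / outside MIST


def simulate_rr_trajectory(cfg: SimulationConfig, condition: str,
                           protocol: StudyProtocol,
                           rng: np.random.Generator | None = None,
                           subject: SubjectParams | None = None
                           ) -> tuple[RRSeries, dict]:
    """Draw one participant's beat series over [0, MIST end].

    Beats are placed by stepping through the programmed instantaneous HR
    profile; white Gaussian jitter with sigma = rmssd_target / sqrt(2) on
    the RR intervals yields the configured RMSSD in expectation.  Returns
    the RR series and a ground-truth dict sufficient to score every
    pipeline output (programmed subphase means, CFI minima, BL means).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if subject is None:
        subject = _draw_subject(cfg, condition, "P00", rng, role="normal")
    sigma_ms = cfg.rmssd_target_ms / np.sqrt(2.0)

    beats = [0.0]
    t = 0.0
    end = protocol.mist_end_s
    while t < end:
        hr = programmed_hr(t, subject, cfg, protocol)
        rr_ms = 60000.0 / hr
        if sigma_ms > 0:
            rr_ms += rng.normal(0.0, sigma_ms)
        rr_ms = max(rr_ms, 300.0)
        t += rr_ms / 1000.0
        beats.append(t)
    beats = np.asarray(beats)
    rr = RRSeries(beat_times_s=beats, rr_ms=np.diff(beats) * 1000.0)
    truth = _truth_for(subject, cfg, protocol)
    return rr, truth


def _truth_for(sp: SubjectParams, cfg: SimulationConfig,
               protocol: StudyProtocol) -> dict:
    """Programmed (noise-free) reference values on a 0.1 s grid."""
    def grid_mean(seg):
        ts = np.arange(seg.start_s, seg.end_s, 0.1)
        return float(np.mean([programmed_hr(t, sp, cfg, protocol) for t in ts]))

    def grid_min(seg):
        ts = np.arange(seg.start_s, seg.end_s, 0.1)
        return float(np.min([programmed_hr(t, sp, cfg, protocol) for t in ts]))

    subphase_mean = {}
    cfi_min, bl_mean = {}, {}
    for p in (1, 2, 3):
        for name in SUBPHASE_NAMES:
            seg = protocol.subphase(p, name)
            subphase_mean[f"MIST{p}_{name}"] = grid_mean(seg)
        cfi_min[f"MIST{p}"] = grid_min(protocol.subphase(p, "RP_CFI"))
        bl_mean[f"MIST{p}"] = grid_mean(protocol.subphase(p, "BL"))
    return {
        "participant": sp.participant, "condition": sp.condition,
        "role": sp.role,
        "baseline_hr_bpm": sp.baseline_hr_bpm,
        "cft_depth_pct": sp.cft_depth_pct,
        "stress_gain_pct": list(sp.stress_gain_pct),
        "bl_drift_pct": list(sp.bl_drift_pct),
        "subphase_mean_hr": subphase_mean,
        "cfi_min_hr": cfi_min,
        "bl_mean_hr": bl_mean,
    }


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

#: P-QRS-T template as (amplitude, centre offset s, Gaussian width s)
ECG_TEMPLATE = (
    (0.12, -0.18, 0.035),   # P
    (-0.12, -0.026, 0.009), # Q
    (1.00, 0.0, 0.010),     # R
    (-0.18, 0.026, 0.009),  # S
    (0.35, 0.28, 0.060),    # T
)


def synthesize_ecg(rr: RRSeries, fs: float = 256.0, noise_sd: float = 0.0,
                   wander_amp: float = 0.0,
                   rng: np.random.Generator | None = None,
                   amplitude: float = 1.0) -> EcgRecording:
    """Template-based ECG waveform with R peaks at the RR series' beat times.

    Parameterised Gaussian P-QRS-T complexes are placed at each beat;
    optional additive Gaussian noise and 0.25 Hz baseline wander can be
    superimposed.  Ground-truth R times are exactly ``rr.beat_times_s``.
    """
    if fs < 100:
        raise EcgError(f"fs = {fs} Hz too low for QRS morphology (need >= 100)")
    if rr.n_beats == 0:
        raise EcgError("empty RR series")
    t_start = rr.beat_times_s[0] - 0.5
    t_end = rr.beat_times_s[-1] + 0.5
    n = int(np.ceil((t_end - t_start) * fs)) + 1
    x = np.zeros(n)
    times = t_start + np.arange(n) / fs
    lo_off, hi_off = -0.32, 0.48
    for bt in rr.beat_times_s:
        i0 = max(int((bt + lo_off - t_start) * fs), 0)
        i1 = min(int((bt + hi_off - t_start) * fs) + 1, n)
        tr = times[i0:i1] - bt
        seg = np.zeros(i1 - i0)
        for amp, mu, sd in ECG_TEMPLATE:
            seg += amp * np.exp(-0.5 * ((tr - mu) / sd) ** 2)
        x[i0:i1] += seg
    if noise_sd > 0 or wander_amp > 0:
        rng = rng or np.random.default_rng(0)
        if noise_sd > 0:
            x += rng.normal(0.0, noise_sd, n)
        if wander_amp > 0:
            x += wander_amp * np.sin(2 * np.pi * 0.25 * times + rng.uniform(0, 2 * np.pi))
    return EcgRecording(samples=amplitude * x, fs=fs, t0=t_start)


# ---------------------------------------------------------------------------
# cortisol
# ---------------------------------------------------------------------------

def _cortisol_pulse(t_min: np.ndarray, onset_min: float, peak_min: float,
                    shape: float) -> np.ndarray:
    """Log-normal response pulse, 0 before onset, max 1 at ``peak_min``."""
    t = np.asarray(t_min, dtype=float)
    out = np.zeros_like(t)
    tau = t - onset_min
    pk = peak_min - onset_min
    pos = tau > 0
    out[pos] = np.exp(-0.5 * (np.log(tau[pos] / pk) / shape) ** 2)
    return out


def simulate_cortisol_profile(cfg: SimulationConfig, condition: str,
                              protocol: StudyProtocol,
                              rng: np.random.Generator | None = None,
                              participant: str = "P00",
                              s0_override: float | None = None
                              ) -> tuple[CortisolProfile, dict]:
    """One participant's cortisol samples S0..S6 plus the noiseless truth.

    The response peaks ``peak_delay_min`` after the end of the MIST (within
    the S3-S4 sampling window) with amplitude scaled per condition; the
    CFT condition's blunted amplitude emulates vagal HPA-axis inhibition.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    cp = cfg.cortisol
    c_base = max(rng.normal(cp.c1_mean, cp.c1_sd), 1.0)
    amp_pct = rng.normal(cp.amplitude_pct[condition], cp.amplitude_sd_pct)
    amp_pct = max(amp_pct, -20.0)  # allow mild negative responders
    amp = c_base * amp_pct / 100.0
    mist_dur_min = (protocol.mist_end_s - protocol.mist_start_s) / 60.0
    peak_min = mist_dur_min + cp.peak_delay_min

    times = np.asarray(protocol.saliva_times_min, float)  # S0..S6
    clean = c_base + amp * _cortisol_pulse(times, cp.onset_delay_min,
                                           peak_min, cp.shape)
    noisy = clean + (rng.normal(0.0, cp.noise_sd, times.size) if cp.noise_sd > 0 else 0.0)
    noisy = np.maximum(noisy, 0.05)
    s0 = float(noisy[0]) if s0_override is None else float(s0_override)
    profile = CortisolProfile(participant=participant, times_min=times[1:],
                              conc_nmol_l=noisy[1:], s0_nmol_l=s0,
                              condition=condition)
    truth = {"c_base": float(c_base), "amplitude_nmol_l": float(amp),
             "amplitude_pct": float(amp_pct), "peak_min": float(peak_min),
             "clean_conc": clean[1:].tolist(), "clean_s0": float(clean[0])}
    return profile, truth


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _draw_subject(cfg: SimulationConfig, condition: str, pid: str,
                  rng: np.random.Generator, role: str) -> SubjectParams:
    base = max(rng.normal(cfg.baseline_hr_bpm, cfg.baseline_hr_sd), 40.0)
    gains = tuple(
        max(g + (rng.normal(0.0, cfg.stress_gain_sd_pct)
                 if cfg.stress_gain_sd_pct > 0 and g > 0 else 0.0), min(g, 2.0))
        for g in cfg.stress_gain_pct)
    if role == "hr_outlier":
        gains = tuple(g * cfg.hr_outlier_gain_factor for g in gains)
    if condition == "Control":
        drift = tuple(
            max(d + (rng.normal(0.0, cfg.bl_drift_sd_pct)
                     if d > 0 and cfg.bl_drift_sd_pct > 0 else 0.0), 0.0)
            for d in cfg.bl_drift_pct)
        depth = 0.0
    else:
        drift = (0.0, 0.0, 0.0)
        if role == "cft_nonresponder":
            depth = -cfg.nonresponder_tachycardia_pct
        else:
            depth = float(np.clip(
                rng.normal(cfg.cft.depth_pct, cfg.cft.depth_sd_pct)
                if cfg.cft.depth_sd_pct > 0 else cfg.cft.depth_pct, 2.0, 60.0))
    return SubjectParams(participant=pid, condition=condition,
                         baseline_hr_bpm=base, stress_gain_pct=gains,
                         bl_drift_pct=drift, cft_depth_pct=depth, role=role)


@dataclass
class Participant:
    params: SubjectParams
    rr: RRSeries
    truth: dict
    cortisol: CortisolProfile
    cortisol_truth: dict


@dataclass
class CohortBundle:
    config: SimulationConfig
    protocol: StudyProtocol
    participants: list


def simulate_cohort(cfg: SimulationConfig, protocol: StudyProtocol | None = None,
                    out_dir=None, with_ecg: bool = False) -> CohortBundle:
    """Generate a full cohort with per-participant reproducible substreams.

    The roster is n_control Control then n_cft CFT participants, plus any
    planted exclusion archetypes (CFT non-responders, S0 cortisol
    outliers, HR hyper-responders) appended to their condition.  With
    ``out_dir`` the bundle is written in the directory layout the pipeline
    consumes (per participant: rr.csv [+ ecg.csv], events.csv, saliva.csv,
    truth.json; cohort-level: protocol.json, config.yaml).
    """
    protocol = protocol or build_mist_protocol()
    roster: list[tuple[str, str]] = []  # (condition, role)
    roster += [("Control", "normal")] * cfg.n_control
    roster += [("CFT", "normal")] * cfg.n_cft
    roster += [("CFT", "cft_nonresponder")] * cfg.n_cft_nonresponders
    roster += [("Control", "s0_outlier")] * cfg.n_s0_outliers
    roster += [("Control", "hr_outlier")] * cfg.n_hr_outliers

    participants = []
    for i, (condition, role) in enumerate(roster):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng([int(cfg.seed), i])
        sp = _draw_subject(cfg, condition, pid, rng, role)
        rr, truth = simulate_rr_trajectory(cfg, condition, protocol, rng, sp)
        s0_override = cfg.s0_outlier_nmol_l if role == "s0_outlier" else None
        prof, ctruth = simulate_cortisol_profile(
            cfg, condition, protocol, rng, pid, s0_override=s0_override)
        participants.append(Participant(sp, rr, truth, prof, ctruth))

    bundle = CohortBundle(config=cfg, protocol=protocol, participants=participants)
    if out_dir is not None:
        write_bundle(bundle, out_dir, with_ecg=with_ecg)
    return bundle


def write_bundle(bundle: CohortBundle, out_dir, with_ecg: bool = False,
                 fs: float = 256.0) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.protocol.save(out / "protocol.json")
    cfg_dict = asdict(bundle.config)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict))
    events = _events_rows(bundle.protocol)
    for p in bundle.participants:
        pdir = out / p.params.participant
        pdir.mkdir(exist_ok=True)
        write_rr_csv(p.rr, pdir / "rr.csv")
        if with_ecg:
            rec = synthesize_ecg(p.rr, fs=fs)
            write_ecg(rec, pdir / "ecg.csv")
            (pdir / "ecg.json").write_text(json.dumps({"fs": fs, "t0": rec.t0}))
        with open(pdir / "events.csv", "w") as fh:
            fh.write("event_name,start_s,end_s\n")
            for name, s, e in events:
                fh.write(f"{name},{s},{e}\n")
        _write_saliva(p, pdir / "saliva.csv", bundle.protocol)
        (pdir / "truth.json").write_text(json.dumps(
            {"rr": p.truth, "cortisol": p.cortisol_truth}, indent=1))


def _events_rows(protocol: StudyProtocol):
    rows = [("BL_Glo", protocol.global_baseline.start_s, protocol.global_baseline.end_s)]
    for phase in protocol.mist_phases:
        for seg in phase.subphases:
            rows.append((f"MIST{phase.index}_{seg.name}", seg.start_s, seg.end_s))
    return rows


def _write_saliva(p: Participant, path, protocol: StudyProtocol) -> None:
    times = np.asarray(protocol.saliva_times_min, float)
    with open(path, "w") as fh:
        fh.write("participant,condition,sample,time_min,cortisol_nmol_l\n")
        fh.write(f"{p.params.participant},{p.params.condition},S0,"
                 f"{times[0]},{p.cortisol.s0_nmol_l:.4f}\n")
        for i, (t, c) in enumerate(zip(p.cortisol.times_min, p.cortisol.conc_nmol_l), 1):
            fh.write(f"{p.params.participant},{p.params.condition},S{i},{t},{c:.4f}\n")
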