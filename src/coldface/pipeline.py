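"""Cohort orchestration: ingest -> ECG pipeline -> features -> exclusions -> stats.

``run_pipeline`` consumes a cohort directory (one subdirectory per
participant holding ``ecg.csv`` or ``rr.csv``, ``events.csv`` and
``saliva.csv``, with a cohort-level ``protocol.json``), processes each
participant fail-soft, applies the study's exclusion rules, runs the
condition-comparison statistics on the retained cohort and writes tidy
CSV/JSON outputs plus a run manifest.  Identical inputs and configuration
produce identical outputs.
"""

from __future__ import annotations

import json
import traceback
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cortisol import metrics_table, read_saliva_csv, screen_baseline
from .ecg import (ArtifactConfig, RRSeries, bandpass_filter, read_ecg,
                  read_rr_csv, rr_artifact_filter)
from .hrv import global_baseline_reference, subphase_table
from .protocol import StudyProtocol, build_mist_protocol
from .qrs import detect_r_peaks
from .rr_correction import correct_r_peaks
from .stats import (StatsConfig, gate_and_compare_conditions,
                    gate_and_compare_paired, mixed_anova, results_table,
                    rm_anova_gg)


@dataclass
class ExclusionConfig:
    """Thresholds of the three cohort exclusion rules.

    (a) CFT non-response: mean normalised HR change during CFI at or above
        ``cfi_threshold_pct`` in *both* MIST1 and MIST2 (no bradycardia when
        little stress was induced);
    (b) screening cortisol S0 above cohort mean + ``s0_z`` SD;
    (c) participant mean normalised HR response over the AT subphases more
        than ``hr_z`` SD from the cohort mean.
    """

    cfi_threshold_pct: float = 0.0
    s0_z: float = 3.0
    hr_z: float = 3.0


@dataclass
class PipelineConfig:
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    window_beats: int = 10
    seed: int = 0


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    participants: dict = field(default_factory=dict)  # pid -> status
    exclusions: list = field(default_factory=list)    # {participant, reason}
    outputs: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"version": self.version, "config": self.config,
                "participants": self.participants,
                "exclusions": self.exclusions, "outputs": self.outputs}


# ---------------------------------------------------------------------------
# per-participant processing
# ---------------------------------------------------------------------------

def process_participant(pdir: Path, protocol: StudyProtocol,
                        cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One participant: signal -> clean RR -> subphase measures + cortisol.

    Prefers raw ECG (``ecg.csv``/``ecg.bin``) and falls back to a
    precomputed RR series (``rr.csv``).
    """
    pdir = Path(pdir)
    pid = pdir.name
    ecg_path = next((p for p in (pdir / "ecg.csv", pdir / "ecg.bin")
                     if p.exists()), None)
    if ecg_path is not None:
        meta = {}
        sidecar = pdir / "ecg.json"
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        rec = read_ecg(ecg_path, fs=meta.get("fs", 256.0), t0=meta.get("t0", 0.0))
        rr = ecg_to_rr(rec, cfg.artifact)
    elif (pdir / "rr.csv").exists():
        rr = rr_artifact_filter(read_rr_csv(pdir / "rr.csv"), cfg.artifact)
    else:
        raise FileNotFoundError(f"{pdir}: neither ecg.csv/ecg.bin nor rr.csv found")

    profiles = read_saliva_csv(pdir / "saliva.csv")
    condition = profiles[0].condition if profiles else ""

    ref = global_baseline_reference(rr, protocol, pid)
    measures = subphase_table(rr, protocol, ref, participant=pid,
                              condition=condition, window_beats=cfg.window_beats)
    cort = metrics_table(profiles)
    cort["participant"] = pid
    return measures, cort


def ecg_to_rr(rec, artifact_cfg: ArtifactConfig | None = None,
              clean: bool = True) -> RRSeries:
    """Full ECG chain: bandpass -> QRS detection -> beat correction -> RR rules.

    ``clean=False`` stops after the beat-level correction, returning the RR
    series without the statistical artifact rules applied.  Extremum-type
    summaries (e.g. peak cold-face bradycardia) are best measured on that
    series: the cohort-level outlier rules are designed to excise ectopic
    artifacts and will censor genuinely extreme but real bradycardia,
    replacing it with interpolated values.
    """
    filtered = bandpass_filter(rec)
    peaks = detect_r_peaks(filtered)
    corrected, _ = correct_r_peaks(peaks, filtered)
    rr = RRSeries.from_peaks(corrected)
    if not clean:
        return rr
    return rr_artifact_filter(rr, artifact_cfg or ArtifactConfig())


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(measures: pd.DataFrame, cortisol: pd.DataFrame,
                     cfg: ExclusionConfig | None = None
                     ) -> tuple[list[str], list[dict]]:
    """Apply the three cohort exclusion rules; one recorded reason each.

    Rules are evaluated in order (CFT non-response, S0 outlier, HR
    response outlier); a participant matched by an earlier rule is not
    re-flagged by a later one.  Returns (retained ids, exclusion records).
    """
    cfg = cfg or ExclusionConfig()
    pids = sorted(measures["participant"].unique())
    excluded: dict[str, str] = {}

    hr = measures[measures["measure"] == "hr_bpm"]
    # (a) CFT non-responders
    cft_ids = hr.loc[hr["condition"] == "CFT", "participant"].unique()
    cfi = hr[hr["subphase"] == "RP_CFI"].pivot_table(
        index="participant", columns="phase", values="normalized_value")
    for pid in cft_ids:
        if pid in cfi.index and \
                cfi.loc[pid, 1] >= cfg.cfi_threshold_pct and \
                cfi.loc[pid, 2] >= cfg.cfi_threshold_pct:
            excluded.setdefault(pid, "cft_nonresponse")

    # (b) S0 cortisol screen (cohort-level, computed once over everyone)
    s0 = cortisol.drop_duplicates("participant").set_index("participant")["s0_nmol_l"]
    s0 = s0.reindex(pids).dropna()
    if s0.size >= 3:
        flags = screen_baseline(s0.to_numpy(), z=cfg.s0_z)
        for pid in s0.index[flags]:
            excluded.setdefault(pid, "s0_outlier")

    # (c) HR response outliers: mean normalised HR over AT subphases
    at = hr[hr["subphase"] == "AT"].groupby("participant")["normalized_value"].mean()
    at = at.reindex(pids).dropna()
    if at.size >= 3 and at.std(ddof=0) > 0:
        z = (at - at.mean()).abs() / at.std(ddof=0)
        for pid in at.index[z > cfg.hr_z]:
            excluded.setdefault(pid, "hr_outlier")

    retained = [p for p in pids if p not in excluded]
    records = [{"participant": p, "reason": r} for p, r in sorted(excluded.items())]
    return retained, records


# ---------------------------------------------------------------------------
# study statistics
# ---------------------------------------------------------------------------

def run_study_stats(measures: pd.DataFrame, cortisol: pd.DataFrame,
                    saliva_long: pd.DataFrame | None = None,
                    cfg: StatsConfig | None = None) -> dict[str, pd.DataFrame]:
    """The study's comparison battery on a processed cohort.

    Produces tidy tables mirroring the analysis structure: paired
    stress-response tests (BL vs AT), cold-face response tests (BL vs CFI),
    repeated-measures phase-course ANOVAs, mixed condition x phase ANOVAs
    for the BL and RP/CFI subphases, and the cortisol condition
    comparisons (plus a condition x time mixed ANOVA when per-sample
    concentrations are supplied).
    """
    cfg = cfg or StatsConfig()
    out: dict[str, pd.DataFrame] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["at_response"] = _paired_subphase(measures, "BL", "AT", cfg)
        out["cfi_response"] = _paired_subphase(
            measures[measures["condition"] == "CFT"], "BL", "RP_CFI", cfg)
        out["phase_course"] = _phase_course(measures, cfg)
        out["condition_by_phase_BL"] = _mixed_by_subphase(measures, "BL", cfg)
        out["condition_by_phase_RP_CFI"] = _mixed_by_subphase(measures, "RP_CFI", cfg)
        out["cortisol_condition"] = _cortisol_condition(cortisol, cfg)
        if saliva_long is not None:
            out["cortisol_condition_by_time"] = _cortisol_time(saliva_long, cfg)
    return out


def _paired_subphase(measures: pd.DataFrame, sub_a: str, sub_b: str,
                     cfg: StatsConfig) -> pd.DataFrame:
    rows = []
    for (cond, meas, phase), g in measures.groupby(["condition", "measure", "phase"]):
        piv = g.pivot_table(index="participant", columns="subphase",
                            values="normalized_value")
        if sub_a not in piv or sub_b not in piv:
            continue
        piv = piv[[sub_a, sub_b]].dropna()
        if len(piv) < 3:
            continue
        r = gate_and_compare_paired(piv[sub_b].to_numpy(), piv[sub_a].to_numpy(), cfg)
        rows.append({"condition": cond, "measure": meas, "phase": phase,
                     "n": len(piv), **r.as_dict()})
    return pd.DataFrame(rows)


def _phase_course(measures: pd.DataFrame, cfg: StatsConfig) -> pd.DataFrame:
    rows = []
    for (cond, meas, sub), g in measures.groupby(["condition", "measure", "subphase"]):
        if sub == "RP_CFI":
            continue
        df = g.rename(columns={"normalized_value": "dv"}).dropna(subset=["dv"])
        if df["participant"].nunique() < 3:
            continue
        r = rm_anova_gg(df, dv="dv", within="phase", subject="participant", cfg=cfg)
        rows.append({"condition": cond, "measure": meas, "subphase": sub,
                     "n": df["participant"].nunique(), **r.as_dict()})
    return pd.DataFrame(rows)


def _mixed_by_subphase(measures: pd.DataFrame, sub: str,
                       cfg: StatsConfig) -> pd.DataFrame:
    rows = []
    g0 = measures[measures["subphase"] == sub]
    for meas, g in g0.groupby("measure"):
        for dv_col, label in (("normalized_value", meas), ("t_glo", f"t_glo({meas})")):
            df = g.rename(columns={dv_col: "dv"}).dropna(subset=["dv"])
            if df.empty or df["condition"].nunique() < 2:
                continue
            try:
                res = mixed_anova(df, dv="dv", within="phase",
                                  between="condition", subject="participant",
                                  cfg=cfg)
            except ValueError:
                continue
            for term, r in res.items():
                rows.append({"measure": label, "subphase": sub,
                             "term": term, **r.as_dict()})
    return pd.DataFrame(rows)


def _cortisol_condition(cortisol: pd.DataFrame, cfg: StatsConfig) -> pd.DataFrame:
    rows = []
    for metric in ("auc_g", "auc_i", "delta_c_max", "slope_s1_s4"):
        sub = cortisol.dropna(subset=[metric])
        ctrl = sub.loc[sub["condition"] == "Control", metric].to_numpy()
        cft = sub.loc[sub["condition"] == "CFT", metric].to_numpy()
        if min(ctrl.size, cft.size) < 3:
            continue
        r = gate_and_compare_conditions(cft, ctrl, cfg)
        rows.append({"metric": metric, "n_control": ctrl.size,
                     "n_cft": cft.size, **r.as_dict()})
    return pd.DataFrame(rows)


def _cortisol_time(saliva_long: pd.DataFrame, cfg: StatsConfig) -> pd.DataFrame:
    df = saliva_long[saliva_long["sample"] != "S0"].rename(
        columns={"cortisol_nmol_l": "dv", "sample": "time"})
    res = mixed_anova(df, dv="dv", within="time", between="condition",
                      subject="participant", cfg=cfg)
    return results_table(res).assign(analysis="cortisol_condition_by_time")


# ---------------------------------------------------------------------------
# cohort runner
# ---------------------------------------------------------------------------

def run_pipeline(input_dir, output_dir, cfg: PipelineConfig | None = None
                 ) -> RunManifest:
    """Process a cohort directory end to end and write all outputs.

    Malformed participants are skipped and logged in the manifest (the
    cohort aborts only if fewer than 2 participants per condition
    survive).  Outputs: ``measures.csv``, ``cortisol_metrics.csv``,
    ``stats/*.csv``, ``manifest.json``.
    """
    cfg = cfg or PipelineConfig()
    in_dir, out_dir = Path(input_dir), Path(output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proto_path = in_dir / "protocol.json"
    protocol = StudyProtocol.load(proto_path) if proto_path.exists() \
        else build_mist_protocol()
    manifest = RunManifest(config=_config_dict(cfg))

    all_measures, all_cort, all_saliva = [], [], []
    pdirs = sorted(p for p in in_dir.iterdir() if p.is_dir())
    for pdir in pdirs:
        pid = pdir.name
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m, c = process_participant(pdir, protocol, cfg)
            all_measures.append(m)
            all_cort.append(c)
            sal = pd.read_csv(pdir / "saliva.csv")
            all_saliva.append(sal)
            manifest.participants[pid] = "processed"
        except Exception as exc:  # fail-soft per participant
            manifest.participants[pid] = f"failed: {exc}"
    if not all_measures:
        raise RuntimeError("no participant could be processed")

    measures = pd.concat(all_measures, ignore_index=True)
    cortisol = pd.concat(all_cort, ignore_index=True)
    saliva = pd.concat(all_saliva, ignore_index=True)

    retained, exclusions = apply_exclusions(measures, cortisol, cfg.exclusion)
    manifest.exclusions = exclusions
    n_cond = measures[measures["participant"].isin(retained)] \
        .drop_duplicates("participant")["condition"].value_counts()
    if (n_cond < 2).any() or len(n_cond) < 2:
        raise RuntimeError("fewer than 2 retained participants per condition")

    kept_m = measures[measures["participant"].isin(retained)]
    kept_c = cortisol[cortisol["participant"].isin(retained)]
    kept_s = saliva[saliva["participant"].isin(retained)]
    tables = run_study_stats(kept_m, kept_c, kept_s, cfg.stats)

    _write_csv(measures, out_dir / "measures.csv", manifest)
    _write_csv(cortisol, out_dir / "cortisol_metrics.csv", manifest)
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    stats_json = {}
    for name, tab in tables.items():
        _write_csv(tab, stats_dir / f"{name}.csv", manifest)
        stats_json[name] = json.loads(tab.to_json(orient="records"))
    (stats_dir / "stats.json").write_text(json.dumps(stats_json, indent=1))
    manifest.outputs.append(str(stats_dir / "stats.json"))
    (out_dir / "manifest.json").write_text(json.dumps(manifest.as_dict(), indent=1))
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df = df.copy()
    for col in df.columns:  # tuples (dfs, CIs) -> stable strings
        if df[col].map(lambda v: isinstance(v, tuple)).any():
            df[col] = df[col].map(
                lambda v: "|".join(f"{x:.6g}" for x in v) if isinstance(v, tuple) else v)
    df.to_csv(path, index=False, float_format="%.6g")
    manifest.outputs.append(str(path))


def _config_dict(cfg: PipelineConfig) -> dict:
    return asdict(cfg)
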