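"""Raw ECG to clean RR series: filter, detect, correct, de-artifact.

Synthesises a two-minute ECG with known R-peak times, runs the full
detection chain and reports how faithfully the beats were recovered.
"""

import numpy as np

from coldface import (SimulationConfig, bandpass_filter, build_mist_protocol,
                      correct_r_peaks, detect_r_peaks, rr_artifact_filter,
                      RRSeries, simulate_rr_trajectory, synthesize_ecg)

protocol = build_mist_protocol()
cfg = SimulationConfig(seed=7)
rr_true, _ = simulate_rr_trajectory(cfg, "Control", protocol)
segment = rr_true.segment(0.0, 120.0)

ecg = synthesize_ecg(segment, fs=256.0)
filtered = bandpass_filter(ecg)                # 3-45 Hz zero-lag FIR
peaks = detect_r_peaks(filtered)               # Hamilton detection rules
corrected, log = correct_r_peaks(peaks)        # beat-level correction
cleaned = rr_artifact_filter(RRSeries.from_peaks(corrected))

true_hr = 60000.0 / segment.rr_ms.mean()
det_hr = 60000.0 / cleaned.rr_ms.mean()
print(f"true beats {segment.n_beats}, detected {peaks.n}, "
      f"beat corrections {len(log)}")
print(f"mean HR: programmed {true_hr:.2f} bpm, recovered {det_hr:.2f} bpm")
print(f"intervals flagged by artifact rules: "
      f"{int((cleaned.flags != 'ok').sum())} of {cleaned.rr_ms.size}")
# The recovered mean heart rate should sit within ~1 bpm of the programmed
# value; flagged intervals were replaced by linear interpolation.
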