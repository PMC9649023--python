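import numpy as np
import pytest

from coldface import (SimulationConfig, detect_r_peaks, bandpass_filter,
                      simulate_cohort, simulate_cortisol_profile,
                      simulate_rr_trajectory, synthesize_ecg, programmed_hr)
from coldface.ecg import EcgError
from coldface.synth import SimulationError, _draw_subject, CftParams


def quiet_config(**kw):
    cfg = SimulationConfig(seed=7, rmssd_target_ms=0.0, baseline_hr_sd=0.0,
                           stress_gain_sd_pct=0.0, bl_drift_sd_pct=0.0, **kw)
    cfg.cft.depth_sd_pct = 0.0
    return cfg


class TestRRTrajectory:
    def test_zero_modulation_gives_constant_rr(self, protocol):
        cfg = quiet_config(stress_gain_pct=(0.0, 0.0, 0.0),
                           bl_drift_pct=(0.0, 0.0, 0.0))
        rr, _ = simulate_rr_trajectory(cfg, "Control", protocol)
        assert np.allclose(rr.rr_ms, 60000.0 / cfg.baseline_hr_bpm)

    def test_cfi_minimum_matches_programmed_depth(self, protocol):
        cfg = quiet_config()
        rr, truth = simulate_rr_trajectory(cfg, "CFT", protocol)
        expected_min = cfg.baseline_hr_bpm * (1 - cfg.cft.depth_pct / 100.0)
        for p in (1, 2, 3):
            assert truth["cfi_min_hr"][f"MIST{p}"] == pytest.approx(expected_min, abs=0.1)
        # trough occurs near peak_s after stimulus onset
        cfi = protocol.subphase(1, "RP_CFI")
        hrs = [programmed_hr(t, _subject(cfg), cfg, protocol)
               for t in np.arange(cfi.start_s, cfi.end_s, 0.1)]
        t_min = cfi.start_s + 0.1 * int(np.argmin(hrs))
        assert cfi.start_s + cfg.cft.peak_s - 1 <= t_min

    def test_fixed_seed_reproducible(self, protocol):
        cfg = SimulationConfig(seed=3)
        rr1, _ = simulate_rr_trajectory(cfg, "CFT", protocol,
                                        np.random.default_rng(9))
        rr2, _ = simulate_rr_trajectory(cfg, "CFT", protocol,
                                        np.random.default_rng(9))
        assert np.array_equal(rr1.rr_ms, rr2.rr_ms)

    def test_rmssd_target_reached_in_expectation(self, protocol):
        from coldface import compute_measures
        cfg = quiet_config()
        cfg.rmssd_target_ms = 45.0
        rr, _ = simulate_rr_trajectory(cfg, "Control", protocol,
                                       np.random.default_rng(4))
        seg = rr.segment(0.0, protocol.global_baseline.end_s)
        assert compute_measures(seg).rmssd_ms == pytest.approx(45.0, rel=0.10)

    def test_invalid_depth_rejected(self):
        with pytest.raises(SimulationError):
            CftParams(depth_pct=120.0)


def _subject(cfg):
    return _draw_subject(cfg, "CFT", "P0", np.random.default_rng(0), "normal")


class TestEcgSynthesis:
    def test_noise_free_detection_recovers_99pct(self, protocol):
        cfg = quiet_config()
        rr, _ = simulate_rr_trajectory(cfg, "Control", protocol)
        sub = rr.segment(0.0, 120.0)
        rec = bandpass_filter(synthesize_ecg(sub))
        det = detect_r_peaks(rec)
        assert det.n >= 0.99 * sub.n_beats

    def test_amplitude_scaled_output_same_beats(self, protocol):
        cfg = quiet_config()
        rr, _ = simulate_rr_trajectory(cfg, "Control", protocol)
        sub = rr.segment(0.0, 60.0)
        a = detect_r_peaks(bandpass_filter(synthesize_ecg(sub, amplitude=1.0)))
        b = detect_r_peaks(bandpass_filter(synthesize_ecg(sub, amplitude=0.1)))
        assert np.array_equal(a.peak_times_s, b.peak_times_s)

    def test_empty_rr_rejected(self):
        from coldface import RRSeries
        with pytest.raises(EcgError):
            synthesize_ecg(RRSeries(np.empty(0), np.empty(0)))

    def test_low_fs_rejected(self, protocol):
        cfg = quiet_config()
        rr, _ = simulate_rr_trajectory(cfg, "Control", protocol)
        with pytest.raises(EcgError):
            synthesize_ecg(rr.segment(0.0, 10.0), fs=50.0)


class TestCortisol:
    def test_zero_amplitude_zero_noise_flat(self, protocol):
        cfg = quiet_config()
        cfg.cortisol.amplitude_pct = {"Control": 0.0, "CFT": 0.0}
        cfg.cortisol.amplitude_sd_pct = 0.0
        cfg.cortisol.noise_sd = 0.0
        prof, _ = simulate_cortisol_profile(cfg, "Control", protocol)
        assert np.allclose(prof.conc_nmol_l, prof.conc_nmol_l[0])
        from coldface import response_metrics
        assert response_metrics(prof).delta_c_max == 0.0

    def test_noiseless_control_peaks_at_s3_or_s4(self, protocol):
        cfg = quiet_config()
        cfg.cortisol.amplitude_sd_pct = 0.0
        cfg.cortisol.noise_sd = 0.0
        for seed in range(5):
            prof, _ = simulate_cortisol_profile(
                cfg, "Control", protocol, np.random.default_rng(seed))
            peak_sample = int(np.argmax(prof.conc_nmol_l)) + 1  # S1..S6
            assert peak_sample in (3, 4)

    def test_seed_reproducible(self, protocol):
        cfg = SimulationConfig(seed=0)
        a, _ = simulate_cortisol_profile(cfg, "CFT", protocol,
                                         np.random.default_rng(5))
        b, _ = simulate_cortisol_profile(cfg, "CFT", protocol,
                                         np.random.default_rng(5))
        assert np.array_equal(a.conc_nmol_l, b.conc_nmol_l)

    def test_peak_delay_bounds_enforced(self):
        from coldface.synth import CortisolParams
        with pytest.raises(SimulationError):
            CortisolParams(peak_delay_min=25.0)


class TestCohort:
    def test_single_participant_per_condition_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(n_control=1, n_cft=5)

    def test_roster_and_roles(self, protocol):
        cfg = SimulationConfig(seed=1, n_control=2, n_cft=2,
                               n_cft_nonresponders=1)
        bundle = simulate_cohort(cfg, protocol)
        roles = [p.params.role for p in bundle.participants]
        conds = [p.params.condition for p in bundle.participants]
        assert len(bundle.participants) == 5
        assert roles.count("cft_nonresponder") == 1
        assert conds.count("Control") == 2 and conds.count("CFT") == 3

    def test_cohort_mean_depth_near_configured(self, protocol):
        cfg = SimulationConfig(seed=11, n_control=2, n_cft=24)
        bundle = simulate_cohort(cfg, protocol)
        depths = np.array([p.params.cft_depth_pct for p in bundle.participants
                           if p.params.condition == "CFT"])
        se = cfg.cft.depth_sd_pct / np.sqrt(depths.size)
        assert abs(depths.mean() - cfg.cft.depth_pct) <= 2.5 * se

    def test_bundle_layout_feeds_pipeline(self, protocol, tmp_path):
        cfg = SimulationConfig(seed=2, n_control=2, n_cft=2)
        simulate_cohort(cfg, protocol, out_dir=tmp_path)
        assert (tmp_path / "protocol.json").exists()
        for pid in ("P01", "P02", "P03", "P04"):
            for fname in ("rr.csv", "events.csv", "saliva.csv", "truth.json"):
                assert (tmp_path / pid / fname).exists()
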