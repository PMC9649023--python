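import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coldface import (BaselineReference, HrvMeasures, compute_measures,
                      denormalize, normalize_to_baseline, sliding_window_measure,
                      t_glo_fraction)
from conftest import rr_from_intervals


def loop_measures(rr_ms):
    """Straight-from-definition oracle, scalar loops only."""
    rr = list(map(float, rr_ms))
    hr = 60000.0 / (sum(rr) / len(rr))
    diffs = [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]
    rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
    prr50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    return hr, rmssd, prr50


class TestComputeMeasures:
    def test_constant_800ms(self):
        m = compute_measures(np.full(100, 800.0))
        assert m.hr_bpm == pytest.approx(75.0)
        assert m.rmssd_ms == 0.0 and m.prr50_pct == 0.0

    def test_alternating_800_860_gives_prr50_100(self):
        m = compute_measures(np.array([800.0, 860.0] * 20))
        assert m.prr50_pct == 100.0

    def test_rmssd_hand_arithmetic(self):
        m = compute_measures(np.array([800.0, 810.0, 790.0]))
        assert m.rmssd_ms == pytest.approx(np.sqrt((10 ** 2 + 20 ** 2) / 2))

    def test_too_few_intervals_warns_nan(self):
        with pytest.warns(UserWarning):
            m = compute_measures(np.array([800.0]))
        assert np.isnan(m.hr_bpm)

    def test_agrees_with_loop_oracle(self, rng):
        for _ in range(50):
            rr = rng.uniform(400, 1400, rng.integers(5, 200))
            m = compute_measures(rr)
            hr, rmssd, prr50 = loop_measures(rr)
            assert m.hr_bpm == pytest.approx(hr, rel=1e-9)
            assert m.rmssd_ms == pytest.approx(rmssd, rel=1e-9)
            assert m.prr50_pct == pytest.approx(prr50, abs=1e-9)


class TestNormalization:
    def _ref(self, hr=60.0, rmssd=40.0, prr50=20.0):
        return BaselineReference("p", HrvMeasures(hr, rmssd, prr50))

    def test_hr_75_vs_60_is_plus_25pct(self):
        norm = normalize_to_baseline(HrvMeasures(75.0, 40.0, 20.0), self._ref())
        assert norm.hr_bpm == pytest.approx(25.0)

    def test_value_equal_to_baseline_is_zero(self):
        norm = normalize_to_baseline(HrvMeasures(60.0, 40.0, 20.0), self._ref())
        assert norm.hr_bpm == 0.0

    def test_zero_baseline_prr50_warns_nan(self):
        with pytest.warns(UserWarning):
            norm = normalize_to_baseline(HrvMeasures(60.0, 40.0, 5.0),
                                         self._ref(prr50=0.0))
        assert np.isnan(norm.prr50_pct)

    @given(st.floats(40, 140), st.floats(1, 200), st.floats(0.5, 100))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_recovers_raw(self, hr, rmssd, prr50):
        ref = self._ref()
        raw = HrvMeasures(hr, rmssd, prr50)
        back = denormalize(normalize_to_baseline(raw, ref), ref)
        assert back.hr_bpm == pytest.approx(hr, rel=1e-12)
        assert back.rmssd_ms == pytest.approx(rmssd, rel=1e-12)
        assert back.prr50_pct == pytest.approx(prr50, rel=1e-12)


def brute_force_t_glo(rr_ms, baseline, measure, n=10):
    """Window-by-window loop oracle with per-interval duration weighting."""
    rr = np.asarray(rr_ms, float)
    n_win = rr.size - n + 1
    above = []
    for w in range(n_win):
        win = rr[w:w + n]
        if measure == "hr_bpm":
            v = 60000.0 / win.mean()
        elif measure == "rmssd_ms":
            v = np.sqrt(np.mean(np.diff(win) ** 2))
        else:
            v = 100.0 * np.mean(np.abs(np.diff(win)) > 50.0)
        above.append(v > baseline)
    num = den = 0.0
    for i in range(rr.size):
        wins = [w for w in range(n_win) if w <= i <= w + n - 1]
        if not wins:
            continue
        frac = sum(above[w] for w in wins) / len(wins)
        num += frac * rr[i]
        den += rr[i]
    return 100.0 * num / den


class TestTGlo:
    def test_all_below_gives_zero(self):
        rr = np.full(60, 1000.0)  # HR 60, baseline 75 -> never above
        assert t_glo_fraction(rr, 75.0, "hr_bpm") == 0.0

    def test_all_above_gives_100(self):
        rr = np.full(60, 700.0)  # HR ~85.7 above baseline 75
        assert t_glo_fraction(rr, 75.0, "hr_bpm") == 100.0

    def test_half_above_is_about_50(self):
        # equal *durations* above and below; tolerance = one window's weight
        rr = np.concatenate([np.full(45, 700.0), np.full(35, 900.0)])
        got = t_glo_fraction(rr, 60000.0 / 800.0, "hr_bpm")
        assert got == pytest.approx(50.0, abs=10 * 900 / (45 * 700 + 35 * 900) * 100)

    def test_matches_brute_force_oracle(self, rng):
        for measure in ("hr_bpm", "rmssd_ms", "prr50_pct"):
            for _ in range(10):
                rr = rng.uniform(600, 1100, rng.integers(15, 80))
                base = {"hr_bpm": 72.0, "rmssd_ms": 120.0, "prr50_pct": 50.0}[measure]
                assert t_glo_fraction(rr, base, measure) == pytest.approx(
                    brute_force_t_glo(rr, base, measure), abs=1e-9)

    def test_tie_counts_as_not_above(self):
        rr = np.full(30, 800.0)
        assert t_glo_fraction(rr, 75.0, "hr_bpm") == 0.0  # windowed HR == 75

    def test_short_segment_warns_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(t_glo_fraction(np.full(5, 800.0), 75.0, "hr_bpm"))

    def test_uniform_slowing_cannot_increase_t_glo_hr(self, rng):
        for _ in range(20):
            rr = rng.uniform(600, 1000, 50)
            base = 70.0
            before = t_glo_fraction(rr, base, "hr_bpm")
            after = t_glo_fraction(rr * 1.1, base, "hr_bpm")
            assert after <= before + 1e-12


def test_sliding_window_matches_segmentwise_compute(rng):
    rr = rng.uniform(500, 1200, 60)
    got = sliding_window_measure(rr, "rmssd_ms", 10)
    exp = [compute_measures(rr[i:i + 10]).rmssd_ms for i in range(51)]
    assert np.allclose(got, exp)
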