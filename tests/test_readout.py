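"""Spectral readout: band powers, beta/gamma ratio, evoked input."""

import numpy as np
import pytest

from bgqsp.readout import (
    BETA_BAND,
    GAMMA_BAND,
    LFPTrace,
    band_power,
    bg_ratio,
    evoked_input,
)

DT = 0.5  # ms -> 2 kHz sampling


def sine(freq, duration_ms=2500.0, amp=1.0, dt=DT, phase=0.0):
    t = np.arange(0.0, duration_ms, dt) / 1000.0
    return LFPTrace(amp * np.sin(2 * np.pi * freq * t + phase), dt)


class TestBandPower:
    def test_pure_beta_tone(self):
        tr = sine(20.0)
        total = band_power(tr, 0.5, tr.fs / 2)
        assert band_power(tr, *BETA_BAND) / total > 0.99
        assert band_power(tr, *GAMMA_BAND) / total < 1e-6

    def test_pure_gamma_tone(self):
        tr = sine(80.0)
        total = band_power(tr, 0.5, tr.fs / 2)
        assert band_power(tr, *GAMMA_BAND) / total > 0.99

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(sine(20.0), 60.0, 2000.0)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(sine(20.0), 50.0, 12.0)

    def test_white_noise_band_ratio_matches_bandwidths(self):
        """Flat PSD: beta/gamma power ratio -> 38/40 (bandwidth ratio)."""
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tr = LFPTrace(rng.standard_normal(8000), DT)
            r = bg_ratio(tr)
            ratios.append(r.ratio)
        assert np.mean(ratios) == pytest.approx(38.0 / 40.0, rel=0.10)

    def test_parseval_partition(self):
        """Disjoint bands covering [0, Nyquist] sum to the trace variance."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(5000) + 0.5 * np.sin(
            2 * np.pi * 25.0 * np.arange(5000) * DT / 1000.0)
        tr = LFPTrace(x, DT)
        edges = [0.0, 12.0, 50.0, 60.0, 100.0, tr.fs / 2]
        total = sum(band_power(tr, lo, hi, method="periodogram")
                    for lo, hi in zip(edges[:-1], edges[1:]))
        # the half-weighted Nyquist bin is excluded by the < hi mask; include it
        var = np.var(x - x.mean())
        assert total == pytest.approx(var, rel=0.01)

    def test_welch_vs_periodogram_consistency(self):
        rng = np.random.default_rng(11)
        t = np.arange(0, 2500.0, DT) / 1000.0
        x = (np.sin(2 * np.pi * 22 * t) + 0.6 * np.sin(2 * np.pi * 72 * t)
             + 0.3 * rng.standard_normal(len(t)))
        tr = LFPTrace(x, DT)
        for band in (BETA_BAND, GAMMA_BAND):
            w = band_power(tr, *band, method="welch")
            p = band_power(tr, *band, method="periodogram")
            assert w == pytest.approx(p, rel=0.15)


class TestBgRatio:
    def test_equal_tones_give_unit_ratio(self):
        t = np.arange(0.0, 2500.0, DT) / 1000.0
        x = np.sin(2 * np.pi * 20 * t) + np.sin(2 * np.pi * 80 * t)
        r = bg_ratio(LFPTrace(x, DT))
        assert r.ratio == pytest.approx(1.0, rel=0.05)

    def test_gamma_dominated_trace(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 2500.0, DT) / 1000.0
        x = np.sin(2 * np.pi * 80 * t) + 0.01 * rng.standard_normal(len(t))
        assert bg_ratio(LFPTrace(x, DT)).ratio < 0.1

    def test_amplitude_scale_invariance_exact(self):
        """Scaling by a power of two is exact in floating point, so the ratio
        must be bit-identical."""
        rng = np.random.default_rng(3)
        tr = LFPTrace(rng.standard_normal(5000), DT)
        assert bg_ratio(LFPTrace(tr.values * 4.0, DT)).ratio == \
            bg_ratio(tr).ratio

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(5000)
        base = bg_ratio(LFPTrace(x, DT)).ratio
        shifted = bg_ratio(LFPTrace(x + 123.0, DT)).ratio
        assert shifted == pytest.approx(base, rel=1e-6)

    def test_zero_gamma_power_rejected(self):
        flat = LFPTrace(np.zeros(4000), DT)
        with pytest.raises(ValueError, match="gamma"):
            bg_ratio(flat)

    def test_low_gamma_band_optional(self):
        r = bg_ratio(sine(35.0), include_low_gamma=True)
        assert r.low_gamma is not None and r.low_gamma > 0


class TestEvokedInput:
    def test_zero_bursts_no_events(self):
        assert len(evoked_input(0, 5, seed=1)) == 0

    def test_event_count_is_bursts_times_spikes(self):
        ev = evoked_input(4, 6, seed=1)
        assert len(ev) == 24

    def test_deterministic_per_seed(self):
        a = evoked_input(3, 5, seed=42)
        b = evoked_input(3, 5, seed=42)
        c = evoked_input(3, 5, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_times_sorted_nonnegative(self):
        ev = evoked_input(5, 4, seed=9)
        assert np.all(np.diff(ev) >= 0) and np.all(ev >= 0)
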