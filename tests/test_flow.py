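import numpy as np
import pytest

from wavestate import (gen_vsd_recording, bandpass_vsd, pairwise_lags,
                       flow_from_lags, detect_flow_events, FlowConfig,
                       LagField, VSDRecording, hex_array, segment_rms,
                       classify_states)
from wavestate.flow import _pair_features
from wavestate.geometry import ArrayGeometry


def _lagfield(pairs, lags, corr=1.0):
    n = len(pairs)
    return LagField(pairs=pairs, lags=np.asarray(lags, float),
                    corrs=np.full(n, corr), valid=np.ones(n, bool),
                    clipped=np.zeros(n, bool))


class TestBandpass:
    def _sine_rec(self, f, rate=1600.0, dur=4.0, geometry=None):
        g = geometry or hex_array()
        t = np.arange(int(dur * rate)) / rate
        data = np.tile(np.sin(2 * np.pi * f * t)[:, None], (1, g.n_channels))
        return VSDRecording(data=data, rate=rate, geometry=g)

    def test_passband_preserves_amplitude(self):
        # long record, interior stretch: clear of the 0.5 Hz high-pass
        # settling transients
        out = bandpass_vsd(self._sine_rec(4.0, dur=20.0))
        mid = out.data[int(8 * 1600):int(12 * 1600), 0]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_attenuates(self):
        out = bandpass_vsd(self._sine_rec(100.0))
        assert np.abs(out.data[2000:4000, 0]).max() < 10 ** (-20 / 20)

    def test_dc_removed(self):
        g = hex_array()
        rec = VSDRecording(data=np.full((4000, g.n_channels), 7.0),
                           rate=1600.0, geometry=g)
        out = bandpass_vsd(rec)
        assert np.abs(out.data).mean() < 1e-6 * 7.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_vsd(self._sine_rec(4.0, rate=60.0), band=(0.5, 35.0))


class TestPairwiseLags:
    def test_delayed_copy_recovers_lag(self, geometry, flow_cfg, rng):
        rate = 1600.0
        w = int(flow_cfg.corr_window * rate)
        base = rng.standard_normal(w + 100)
        data = np.zeros((w, geometry.n_channels))
        data[:, 0] = base[50:50 + w]
        data[:, 1] = base[42:42 + w]          # channel 1 lags by 8 frames
        lf = pairwise_lags(data, geometry, flow_cfg, rate, pairs=[(0, 1)])
        assert lf.corrs[0] > 0.999
        assert lf.lags[0] == pytest.approx(8 / rate, abs=0.25 / rate)

    def test_oversized_delay_clips_and_flags(self, geometry, flow_cfg):
        # a smooth trace (correlation length > the true 60-frame delay)
        # drives the peak to the search boundary
        rate = 1600.0
        w = int(flow_cfg.corr_window * rate)
        t = np.arange(w + 200) / rate
        base = np.sin(2 * np.pi * 8.0 * t)    # period 200 frames
        data = np.zeros((w, geometry.n_channels))
        data[:, 0] = base[100:100 + w]
        data[:, 1] = base[40:40 + w]          # 60-frame delay > 40-frame max
        lf = pairwise_lags(data, geometry, flow_cfg, rate, pairs=[(0, 1)])
        assert lf.clipped[0]
        assert abs(lf.lags[0]) == pytest.approx(flow_cfg.max_shift)

    def test_plane_wave_lags_match_analytic(self, geometry, flow_cfg,
                                            ring_pairs):
        rate, v, theta = 1600.0, 120.0, 0.6
        rec, _ = gen_vsd_recording("sync", 4.0, noise_sd=0.0,
                                   waves=[(2.0, v, theta)], seed=0)
        filt = bandpass_vsd(rec)
        w = int(flow_cfg.corr_window * rate)
        start = int(1.95 * rate)
        lf = pairwise_lags(filt.data[start:start + w], geometry, flow_cfg,
                           rate)
        d, _, _ = _pair_features(ring_pairs, geometry)
        expected = d @ np.array([np.cos(theta), np.sin(theta)]) / v
        np.testing.assert_allclose(lf.lags, expected, atol=0.5 / rate)

    def test_zero_variance_trace_skipped(self, geometry, flow_cfg, rng):
        rate = 1600.0
        w = int(flow_cfg.corr_window * rate)
        data = rng.standard_normal((w, geometry.n_channels))
        data[:, 1] = 0.0
        lf = pairwise_lags(data, geometry, flow_cfg, rate, pairs=[(0, 1)])
        assert not lf.valid[0]


class TestFlowFromLags:
    def test_ideal_plane_wave(self, geometry, flow_cfg, ring_pairs):
        d, _, _ = _pair_features(ring_pairs, geometry)
        lags = d @ np.array([1.0, 0.0]) / 100.0
        ev = flow_from_lags(_lagfield(ring_pairs, lags), geometry, flow_cfg)
        assert ev.pattern == "translation"
        assert ev.reliability > 0.99
        assert ev.speed == pytest.approx(100.0, rel=0.02)
        assert min(ev.direction, 2 * np.pi - ev.direction) < np.radians(2)

    def test_radial_lags_classified_source(self, geometry, flow_cfg,
                                           ring_pairs):
        _, rad, _ = _pair_features(ring_pairs, geometry)
        ev = flow_from_lags(_lagfield(ring_pairs, 0.004 * rad), geometry,
                            flow_cfg)
        assert ev.pattern == "source"
        assert np.isnan(ev.speed)

    def test_rotational_lags_classified_spiral(self, geometry, flow_cfg,
                                               ring_pairs):
        _, _, azi = _pair_features(ring_pairs, geometry)
        ev = flow_from_lags(_lagfield(ring_pairs, 0.002 * azi), geometry,
                            flow_cfg)
        assert ev.pattern == "spiral"

    def test_random_lags_rarely_reliable(self, geometry, flow_cfg,
                                         ring_pairs, rng):
        below = 0
        n = 1000
        for _ in range(n):
            ev = flow_from_lags(
                _lagfield(ring_pairs, rng.normal(0, 0.005, 12)), geometry,
                flow_cfg)
            if ev.reliability < 0.85:
                below += 1
        assert below / n >= 0.95

    def test_too_few_valid_pairs_gives_none(self, geometry, flow_cfg,
                                            ring_pairs):
        lf = _lagfield(ring_pairs, np.zeros(12))
        lf.valid[:] = False
        lf.valid[:3] = True
        assert flow_from_lags(lf, geometry, flow_cfg) is None


class TestDetectFlowEvents:
    def test_three_injected_waves_three_events(self):
        waves = [(3.0, 90.0, 0.5), (10.0, 110.0, 2.0), (17.0, 100.0, 4.0)]
        rec, _ = gen_vsd_recording("sync", 20.0, noise_sd=0.005, seed=0,
                                   waves=waves)
        ev = detect_flow_events(rec)
        assert len(ev) == 3
        for (t0, v, th), e in zip(waves, ev):
            assert abs(e.t - t0) <= 0.25       # within half a window + front
            assert e.speed == pytest.approx(v, rel=0.05)

    def test_pure_noise_event_rate_low(self):
        total = 0
        for s in range(2):
            rec, _ = gen_vsd_recording("sync", 60.0, seed=50 + s, waves=[])
            total += len(detect_flow_events(rec))
        assert total / 120.0 < 0.05

    def test_reliability_one_keeps_nothing(self):
        rec, _ = gen_vsd_recording("sync", 10.0, seed=1)
        cfg = FlowConfig(reliability_min=1.0)
        assert detect_flow_events(rec, cfg) == []

    def test_threshold_monotonicity(self):
        rec, _ = gen_vsd_recording("desync", 20.0, seed=3)
        counts = [len(detect_flow_events(rec, FlowConfig(reliability_min=r)))
                  for r in (0.85, 0.9, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_events_inherit_state_labels(self):
        rec, _ = gen_vsd_recording("sync", 10.0, seed=2)
        rms = segment_rms(rec.data[:, 0], rec.rate)
        seg = classify_states(rms, criterion=-1.0)   # everything 'sync'
        ev = detect_flow_events(rec, states=seg)
        assert ev and all(e.state == "sync" for e in ev)

    def test_direction_equivariance_and_speed_scale(self):
        def recover(alpha, speed, rotate=False):
            g = hex_array()
            if rotate:
                R = np.array([[np.cos(alpha), -np.sin(alpha)],
                              [np.sin(alpha), np.cos(alpha)]])
                g = ArrayGeometry(g.positions @ R.T, g.spacing,
                                  g.ring_channels)
            rec, _ = gen_vsd_recording("sync", 4.0, noise_sd=0.0,
                                       geometry=g, waves=[(2.0, speed,
                                                           alpha)])
            e = [x for x in detect_flow_events(rec)
                 if x.pattern == "translation"][0]
            return e.speed, e.direction

        s0, d0 = recover(0.0, 100.0)
        s1, d1 = recover(0.7, 100.0, rotate=True)
        err = abs((d1 - (d0 + 0.7) + np.pi) % (2 * np.pi) - np.pi)
        assert err < np.radians(2)
        assert s1 == pytest.approx(s0, rel=0.02)
        s2, _ = recover(0.0, 200.0)
        assert s2 / s0 == pytest.approx(2.0, rel=0.02)

    def test_noiseless_recovery_of_every_wave(self):
        waves = [(2.0, 80.0, 1.0), (6.0, 150.0, 3.5), (10.0, 60.0, 5.5)]
        rec, tr = gen_vsd_recording("sync", 13.0, noise_sd=0.0, seed=0,
                                    waves=waves)
        ev = [e for e in detect_flow_events(rec) if e.pattern == "translation"]
        assert len(ev) == 3
        for (t0, v, th), e in zip(waves, ev):
            assert e.speed == pytest.approx(v, rel=0.02)
            err = abs((e.direction - th + np.pi) % (2 * np.pi) - np.pi)
            assert err < np.radians(5)


class TestFlowConfig:
    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            FlowConfig(corr_window=0.04, max_shift=0.025)

    def test_invalid_reliability_rejected(self):
        with pytest.raises(ValueError):
            FlowConfig(reliability_min=1.5)
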