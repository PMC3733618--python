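import numpy as np
import pytest

from wavestate import (csd_transform, detect_up_transitions, phase_triggers,
                       triggered_csd_average, avrec_fraction,
                       gen_laminar_session, CSDProfile)


class TestCSDTransform:
    def test_linear_profile_gives_zero_interior(self):
        z = np.arange(16)[:, None]
        v = 0.3 * z * np.ones((16, 50))
        prof = csd_transform(v, pitch=0.05, rate=1000.0)
        assert np.abs(prof.csd[1:-1]).max() < 1e-9

    def test_quadratic_profile_constant_csd(self):
        z = np.arange(10, dtype=float)[:, None]
        v = (z ** 2) * np.ones((10, 20))
        prof = csd_transform(v, pitch=1.0, rate=1.0, conductivity=1.0)
        np.testing.assert_allclose(prof.csd[1:-1], -2.0, atol=1e-9)

    def test_inverts_forward_model_exactly(self):
        rec = gen_laminar_session(10.0, seed=1, noise_sd=0.0)
        prof = csd_transform(rec.lfp, rec.pitch, rec.rate)
        scale = np.abs(rec.true_csd).max()
        err = np.abs(prof.csd[1:-1] - rec.true_csd[1:-1]).max()
        assert err < 1e-6 * scale

    def test_linearity(self, rng):
        v1 = rng.standard_normal((12, 30))
        v2 = rng.standard_normal((12, 30))
        a, b = 2.0, -0.7
        c12 = csd_transform(a * v1 + b * v2, 0.05, 1000.0).csd
        c1 = csd_transform(v1, 0.05, 1000.0).csd
        c2 = csd_transform(v2, 0.05, 1000.0).csd
        np.testing.assert_allclose(c12, a * c1 + b * c2, atol=1e-9)

    def test_too_few_channels(self):
        with pytest.raises(ValueError):
            csd_transform(np.ones((2, 10)), 0.05, 1000.0)

    def test_nonuniform_pitch_rejected(self):
        with pytest.raises(ValueError):
            csd_transform(np.ones((5, 10)), 0.05, 1000.0,
                          depths=[0.0, 0.05, 0.1, 0.2, 0.25])

    def test_smoothing_preserves_total_current(self, rng):
        v = rng.standard_normal((20, 40))
        rough = csd_transform(v, 0.05, 1000.0).csd
        smooth = csd_transform(v, 0.05, 1000.0, smooth=True).csd
        # 3-point Hamming smoothing is near mass-preserving on the interior
        np.testing.assert_allclose(smooth[2:-2].sum(axis=0),
                                   rough[2:-2].sum(axis=0), rtol=0.2,
                                   atol=0.5 * np.abs(rough).max())


class TestMUATriggers:
    def test_rate_step_triggers_once_at_onset(self):
        base = np.arange(0.0, 60.0, 0.2)        # 5 Hz regular
        step = np.arange(10.0, 10.6, 0.02)      # 50 Hz for 600 ms
        trig = detect_up_transitions([np.sort(np.r_[base, step])],
                                     duration=60.0)
        assert len(trig) == 1
        assert trig.times[0] == pytest.approx(10.0, abs=0.015)

    def test_short_elevation_rejected_by_persistence(self):
        base = np.arange(0.0, 60.0, 0.2)
        step = np.arange(10.0, 10.3, 0.02)      # only 300 ms
        trig = detect_up_transitions([np.sort(np.r_[base, step])],
                                     duration=60.0)
        assert len(trig) == 0

    def test_homogeneous_poisson_rarely_triggers(self):
        rng = np.random.default_rng(1)
        zero = 0
        runs = 40
        for _ in range(runs):
            spk = np.sort(rng.uniform(0, 60, rng.poisson(20 * 60)))
            if len(detect_up_transitions([spk], duration=60.0)) == 0:
                zero += 1
        assert zero / runs >= 0.95

    def test_detects_generated_up_states(self):
        rec = gen_laminar_session(30.0, seed=4, mode="sync")
        trig = detect_up_transitions(rec.mua_times, duration=rec.duration)
        # most up states trigger, each trigger sits near an onset
        assert len(trig) >= 0.8 * len(rec.up_times)
        assert len(trig) <= 1.1 * len(rec.up_times)
        d = np.abs(trig.times[:, None] - rec.up_times[None, :]).min(axis=1)
        assert np.median(d) < 0.05

    def test_empty_spikes_error(self):
        with pytest.raises(ValueError):
            detect_up_transitions([np.empty(0)], duration=10.0)


class TestPhaseTriggers:
    def test_four_hz_cosine_triggers_at_maxima(self):
        rate = 1000.0
        t = np.arange(int(10 * rate)) / rate
        trig = phase_triggers(np.cos(2 * np.pi * 4 * t), rate)
        # maxima sit at multiples of 250 ms
        off = np.abs(trig.times * 4 - np.round(trig.times * 4)) / 4
        assert off.max() < 1.0 / rate
        iti = np.diff(trig.times)
        assert np.all(np.abs(iti - 0.25) < 1.0 / rate)

    def test_desync_session_inter_trigger_interval(self):
        rec = gen_laminar_session(30.0, seed=2, mode="desync")
        ch = int(np.argmax(rec.lfp.std(axis=1)))
        trig = phase_triggers(rec.lfp[ch], rec.rate)
        assert 1 / 6 <= np.diff(trig.times).mean() <= 1 / 3

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            phase_triggers(np.zeros(5000), 10.0, band=(3.0, 6.0))


class TestTriggeredAverage:
    def _profile(self, csd, rate=1000.0):
        from wavestate.csd import TriggerSet
        t = np.arange(csd.shape[1]) / rate
        return CSDProfile(csd=csd, pitch=0.05, rate=rate, t=t)

    def test_single_trigger_returns_windowed_slice(self, rng):
        from wavestate.csd import TriggerSet
        csd = rng.standard_normal((8, 4000))
        prof = self._profile(csd)
        avg = triggered_csd_average(prof, TriggerSet([2.0], "mua_up"),
                                    window=1.0)
        np.testing.assert_allclose(avg.csd, csd[:, 1500:2501])
        assert avg.trigger_count == 1

    def test_averaging_reduces_noise_sqrt_n(self, rng):
        from wavestate.csd import TriggerSet
        rate = 1000.0
        event = np.zeros((4, 1001))
        n = 100
        csd = np.zeros((4, int(rate) * (n + 2)))
        times = 1.0 + np.arange(n) * 1.0
        noise_sd = 0.5
        csd += noise_sd * rng.standard_normal(csd.shape)
        prof = self._profile(csd, rate)
        avg = triggered_csd_average(prof, TriggerSet(times, "mua_up"), 1.0)
        assert avg.csd.std() == pytest.approx(noise_sd / np.sqrt(n), rel=0.25)

    def test_edge_triggers_dropped(self, rng):
        from wavestate.csd import TriggerSet
        prof = self._profile(rng.standard_normal((4, 3000)))
        avg = triggered_csd_average(
            prof, TriggerSet([0.1, 1.5, 2.9], "mua_up"), 1.0)
        assert avg.trigger_count == 1
        with pytest.raises(ValueError):
            triggered_csd_average(prof, TriggerSet([0.1], "mua_up"), 1.0)

    def test_sync_average_shows_supragranular_dipole(self):
        rec = gen_laminar_session(30.0, seed=6, mode="sync")
        prof = csd_transform(rec.lfp, rec.pitch, rec.rate)
        trig = detect_up_transitions(rec.mua_times, duration=rec.duration)
        avg = triggered_csd_average(prof, trig, 1.0)
        c = int(np.argmin(np.abs(avg.t)))
        depth_mass = np.abs(avg.csd[:, c - 100:c + 100]).sum(axis=1)
        # the strongest sink/source depths lie in the SG band (0..9)
        assert depth_mass.argmax() < 10


class TestAvrec:
    def _avg(self, csd):
        t = (np.arange(csd.shape[1]) - csd.shape[1] // 2) / 1000.0
        return CSDProfile(csd=csd, pitch=0.05, rate=1000.0, t=t)

    def test_all_mass_in_sg_gives_one(self):
        csd = np.zeros((32, 401))
        csd[2:8] = 1.0
        assert avrec_fraction(self._avg(csd)).sg_fraction == 1.0

    def test_equal_band_mass_gives_third(self):
        csd = np.zeros((32, 401))
        csd[4, :] = 3.0      # SG
        csd[12, :] = -3.0    # G
        csd[20, :] = 3.0     # IG
        assert avrec_fraction(self._avg(csd)).sg_fraction == pytest.approx(
            1 / 3, abs=1e-9)

    def test_sign_flip_and_gain_invariance(self, rng):
        csd = rng.standard_normal((32, 401))
        f0 = avrec_fraction(self._avg(csd)).sg_fraction
        assert avrec_fraction(self._avg(-csd)).sg_fraction == pytest.approx(f0)
        assert avrec_fraction(self._avg(5.0 * csd)).sg_fraction == \
            pytest.approx(f0)

    def test_missing_layer_bands_error(self, rng):
        prof = self._avg(rng.standard_normal((32, 401)))
        prof.layer_bands = {}
        with pytest.raises(ValueError):
            avrec_fraction(prof)

    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.684, 0.9])
    def test_parameter_recovery_across_fractions(self, frac):
        rec = gen_laminar_session(30.0, sg_fraction=frac, seed=3, mode="sync")
        prof = csd_transform(rec.lfp, rec.pitch, rec.rate)
        trig = detect_up_transitions(rec.mua_times, duration=rec.duration)
        avg = triggered_csd_average(prof, trig, 1.0)
        assert avrec_fraction(avg).sg_fraction == pytest.approx(frac,
                                                                abs=0.05)
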