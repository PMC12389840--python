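"""Synthetic radar-cube and tone generators."""

import numpy as np
import pytest

from radarhr import (RadarConfig, ToneSpec, VitalParams, add_awgn,
                     gen_displacement, gen_dual_tone, gen_radar_cube,
                     range_fft)


class TestDisplacement:
    def test_zero_amplitudes_give_zero_series(self, radar_config):
        p = VitalParams(respiration_amplitude=0.0, heart_amplitude=0.0)
        x = gen_displacement(p, radar_config, 100)
        assert np.all(x == 0.0)

    def test_heart_only_is_pure_sinusoid(self, radar_config):
        h, fh = 3e-4, 1.25
        p = VitalParams(respiration_amplitude=0.0, heart_amplitude=h,
                        heart_rate=fh)
        x = gen_displacement(p, radar_config, 1600)
        assert np.ptp(x) == pytest.approx(2 * h, rel=1e-3)
        spec = np.abs(np.fft.rfft(x))
        freqs = np.fft.rfftfreq(x.size, radar_config.frame_period)
        assert freqs[np.argmax(spec)] == pytest.approx(fh, abs=0.02)

    def test_default_periodogram_peaks_at_both_rates(self, radar_config):
        # independent DFT peak search around each physiological band
        p = VitalParams(respiration_harmonic_weights=(1.0,))
        x = gen_displacement(p, radar_config, 1200)
        spec = np.abs(np.fft.rfft(x * np.hanning(x.size)))
        freqs = np.fft.rfftfreq(x.size, radar_config.frame_period)
        resp_band = (freqs > 0.1) & (freqs < 0.5)
        heart_band = (freqs > 0.8) & (freqs < 2.0)
        f_resp = freqs[resp_band][np.argmax(spec[resp_band])]
        f_heart = freqs[heart_band][np.argmax(spec[heart_band])]
        assert f_resp == pytest.approx(0.25, abs=0.02)
        assert f_heart == pytest.approx(1.3, abs=0.02)

    def test_nonphysical_rate_rejected(self):
        with pytest.raises(ValueError):
            VitalParams(respiration_rate=-0.1)


class TestRadarCube:
    def test_static_target_has_constant_phase(self, radar_config, clean_params):
        import dataclasses
        p = dataclasses.replace(clean_params, respiration_amplitude=0.0,
                                heart_amplitude=0.0)
        cube = gen_radar_cube(radar_config, p, 64)
        rm = range_fft(cube)
        b = int(np.argmax(np.abs(rm.values[0, 0])))
        phase = np.angle(rm.values[:, 0, b])
        assert np.var(phase) < 1e-20

    def test_heart_only_phase_excursion(self, radar_config, clean_params):
        import dataclasses
        h = 2e-4
        p = dataclasses.replace(clean_params, respiration_amplitude=0.0,
                                heart_amplitude=h)
        cube = gen_radar_cube(radar_config, p, 400)
        rm = range_fft(cube)
        b = int(np.argmax(np.abs(rm.values[0, 0])))
        phase = np.unwrap(np.angle(rm.values[:, 0, b]))
        expected_pp = 8 * np.pi * h / radar_config.wavelength
        assert np.ptp(phase) == pytest.approx(expected_pp, rel=1e-3)

    def test_noiseless_phase_matches_displacement_law(self, radar_config,
                                                      clean_params):
        cube = gen_radar_cube(radar_config, clean_params, 256)
        rm = range_fft(cube)
        b = int(np.argmax(np.abs(rm.values[0, 0])))
        recovered = np.unwrap(np.angle(rm.values[:, 0, b]))
        x = gen_displacement(clean_params, radar_config, 256)
        truth = 4 * np.pi * (clean_params.nominal_range + x) / radar_config.wavelength
        resid = recovered - truth
        assert np.max(np.abs(resid - resid.mean())) < 1e-6

    def test_out_of_range_target_rejected(self, radar_config):
        with pytest.raises(ValueError):
            gen_radar_cube(radar_config,
                           VitalParams(nominal_range=10.0), 8)

    def test_bit_reproducible_per_seed(self, radar_config):
        a = gen_radar_cube(radar_config, VitalParams(seed=11), 16)
        b = gen_radar_cube(radar_config, VitalParams(seed=11), 16)
        c = gen_radar_cube(radar_config, VitalParams(seed=12), 16)
        assert np.array_equal(a.adc, b.adc)
        assert not np.array_equal(a.adc, c.adc)

    def test_hdf5_round_trip(self, radar_config, tmp_path):
        cube = gen_radar_cube(radar_config, VitalParams(seed=5), 8)
        path = tmp_path / "cube.h5"
        cube.save(path)
        back = cube.load(path)
        assert np.array_equal(back.adc, cube.adc)
        assert back.config == radar_config


class TestDualTone:
    def test_noiseless_value_at_origin(self):
        spec = ToneSpec(amplitudes=(0.2, 0.15), frequencies=(1.3, 2.7),
                        snr_db=np.inf)
        x = gen_dual_tone(spec)
        assert x[0] == pytest.approx(0.35)

    def test_noiseless_power_matches_tone_power(self):
        spec = ToneSpec(frequencies=(1.05, 1.20), snr_db=np.inf)
        x = gen_dual_tone(spec)
        expected = (0.2 ** 2 + 0.15 ** 2) / 2
        assert np.mean(x ** 2) == pytest.approx(expected, rel=0.05)

    def test_series_length_matches_sample_count(self):
        assert gen_dual_tone(ToneSpec()).size == 200

    def test_realized_snr_converges(self):
        spec = ToneSpec(n_samples=10_000, frequencies=(1.05, 1.20),
                        snr_db=10.0, seed=2)
        x = gen_dual_tone(spec)
        clean = gen_dual_tone(spec.replace(snr_db=np.inf))
        noise_var = np.var(x - clean)
        realized = 10 * np.log10(np.mean(clean ** 2) / noise_var)
        assert realized == pytest.approx(10.0, abs=0.2)

    def test_negative_infinite_snr_rejected(self):
        with pytest.raises(ValueError):
            gen_dual_tone(ToneSpec(snr_db=-np.inf))


class TestAddAwgn:
    def test_infinite_snr_is_identity(self):
        x = np.sin(np.linspace(0, 10, 100))
        assert np.array_equal(add_awgn(x, np.inf, 0), x)

    def test_noise_power_ratio(self):
        x = np.sin(2 * np.pi * 0.05 * np.arange(20_000))
        y = add_awgn(x, 6.0, seed=1)
        ratio = np.mean((y - x) ** 2) / np.mean(x ** 2)
        assert ratio == pytest.approx(10 ** (-0.6), rel=0.05)

    def test_zero_series_rejected(self):
        with pytest.raises(ValueError):
            add_awgn(np.zeros(10), 10.0, 0)
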