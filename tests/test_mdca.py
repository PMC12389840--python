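"""Multi-dimensional coherent accumulation."""

import numpy as np
import pytest

from radarhr import (pearson, phase_energy, run_mdca, sdca,
                     select_adjacent_bin, select_reference, spectral_snr)
from radarhr.rangeproc import PhaseMatrix


def pm_from(values, fs=20.0, power=None):
    return PhaseMatrix(values=np.asarray(values, dtype=float),
                       frame_rate=fs, power=power)


def planted_matrix(n_frames=128, n_ch=4, n_bins=16, seed=0):
    rng = np.random.default_rng(seed)
    return pm_from(rng.normal(size=(n_frames, n_ch, n_bins)))


class TestPhaseEnergy:
    def test_zero_phase_is_zero(self):
        pm = pm_from(np.zeros((16, 2, 4)))
        assert phase_energy(pm, 0, 0, slice(0, 16)) == 0.0

    def test_constant_phase_zero_after_mean_removal(self):
        pm = pm_from(np.full((16, 2, 4), 2.3))
        assert phase_energy(pm, 1, 2, slice(0, 16)) == 0.0

    def test_matches_direct_sum_of_squares(self):
        pm = planted_matrix(seed=5)
        win = slice(10, 90)
        x = pm.values[win, 2, 7]
        expected = np.sum((x - x.mean()) ** 2)
        assert phase_energy(pm, 2, 7, win) == pytest.approx(expected)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            phase_energy(planted_matrix(), 0, 0, slice(5, 5))


class TestSelectReference:
    def test_planted_argmax_found(self):
        pm = planted_matrix(seed=1)
        pm.values[:, 2, 7] += 40 * np.sin(np.linspace(0, 20, 128))
        assert select_reference(pm, slice(0, 128)) == (2, 7)

    def test_all_equal_energies_tie_to_first(self):
        base = np.sin(np.linspace(0, 20, 64))
        vals = np.tile(base[:, None, None], (1, 3, 5))
        assert select_reference(pm_from(vals), slice(0, 64)) == (0, 0)

    def test_matches_exhaustive_search(self):
        pm = planted_matrix(seed=9)
        win = slice(0, 128)
        best, arg = -1.0, None
        for ch in range(4):
            for b in range(16):
                e = phase_energy(pm, ch, b, win)
                if e > best:
                    best, arg = e, (ch, b)
        assert select_reference(pm, win) == arg


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(size=30)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        x = np.random.default_rng(1).normal(size=30)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestSdca:
    def test_identical_channels_sum_with_unit_correlation(self):
        base = np.sin(np.linspace(0, 12, 128))
        vals = np.tile(base[:, None, None], (1, 4, 3))
        s, k0, l, rho, doubled = sdca(pm_from(vals), 1, slice(0, 128), 0.8)
        assert rho == pytest.approx(1.0)
        assert not doubled
        assert np.allclose(s, 2 * base)

    def test_uncorrelated_channels_double_the_reference(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(128, 4, 1))
        vals[:, 0, 0] = 10 * np.sin(np.linspace(0, 12, 128))
        s, k0, l, rho, doubled = sdca(pm_from(vals), 0, slice(0, 128), 0.8)
        assert doubled
        assert k0 == 0
        assert np.allclose(s, 2 * vals[:, 0, 0])

    def test_picks_highest_correlation_among_candidates(self):
        rng = np.random.default_rng(3)
        ref = np.sin(np.linspace(0, 12, 256))
        noise = rng.normal(size=(256, 3))
        mix = [0.95, 0.6, 0.3]
        vals = np.empty((256, 4, 1))
        vals[:, 0, 0] = 10 * ref
        for i, m in enumerate(mix):
            z = m * ref + np.sqrt(1 - m ** 2) * noise[:, i]
            vals[:, i + 1, 0] = z
        s, k0, l, rho, doubled = sdca(pm_from(vals), 0, slice(0, 256), 0.8)
        # exhaustive oracle over candidate channels
        rhos = [pearson(vals[:, 0, 0], vals[:, c, 0]) for c in range(1, 4)]
        assert l == int(np.argmax(rhos)) + 1
        assert rho == pytest.approx(max(rhos))


class TestAdjacentBin:
    def test_higher_energy_neighbour_wins(self):
        vals = np.zeros((64, 2, 5))
        vals[:, :, 1] = np.sin(np.linspace(0, 9, 64))[:, None] * 3
        vals[:, :, 3] = np.sin(np.linspace(0, 9, 64))[:, None]
        assert select_adjacent_bin(pm_from(vals), 2, slice(0, 64)) == 1

    def test_edge_bin_uses_single_neighbour(self):
        pm = planted_matrix(seed=4)
        assert select_adjacent_bin(pm, 0, slice(0, 128)) == 1

    def test_matches_direct_comparison(self):
        pm = planted_matrix(seed=6)
        win = slice(0, 128)
        i0 = 7
        e = [sum(phase_energy(pm, c, b, win) for c in range(4))
             for b in (i0 - 1, i0 + 1)]
        expected = i0 - 1 if e[0] >= e[1] else i0 + 1
        assert select_adjacent_bin(pm, i0, win) == expected


class TestRunMdca:
    def test_replication_invariant(self):
        """A signal copied to every channel and bin accumulates exactly 4x
        (2 channels at each of 2 bins)."""
        base = np.sin(np.linspace(0, 30, 256)) * 3
        vals = np.tile(base[:, None, None], (1, 4, 8))
        vs = run_mdca(pm_from(vals), group_frames=128, impulse_filter=False)
        expected = np.concatenate([np.diff(4 * base[:128]),
                                   np.diff(4 * base[128:])])
        assert np.allclose(vs.values, expected)

    def test_zero_matrix_gives_zero_signal(self):
        vs = run_mdca(pm_from(np.zeros((128, 4, 8))))
        assert np.all(vs.values == 0.0)

    def test_linear_in_input_without_branches(self):
        pm = planted_matrix(seed=8)
        a = run_mdca(pm, gamma=1e-9, impulse_filter=False)
        scaled = pm_from(3.0 * pm.values)
        b = run_mdca(scaled, gamma=1e-9, impulse_filter=False)
        assert np.allclose(b.values, 3.0 * a.values)

    def test_group_length_bookkeeping(self):
        pm = planted_matrix(n_frames=300, seed=10)
        with pytest.warns(UserWarning):
            vs = run_mdca(pm, group_frames=128)
        assert vs.values.size == 2 * 127
        assert len(vs.selections) == 2

    def test_fewer_frames_than_group_rejected(self):
        with pytest.raises(ValueError):
            run_mdca(planted_matrix(n_frames=64), group_frames=128)

    def test_selection_log_round_trips_to_csv(self, tmp_path):
        import pandas as pd
        vs = run_mdca(planted_matrix(seed=12))
        path = tmp_path / "sel.csv"
        vs.selections_to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["group", "k0", "i0", "l", "rho", "i1",
                                    "doubled"]
        assert len(df) == len(vs.selections)


class TestSpectralSnr:
    def test_pure_on_bin_tone_saturates_with_warning(self):
        t = np.arange(512) / 20.0
        x = np.sin(2 * np.pi * 1.25 * t)       # exactly bin 32 of 512
        with pytest.warns(UserWarning):
            snr = spectral_snr(x, 20.0)
        assert snr >= 250.0

    def test_matches_direct_formula_evaluation(self):
        rng = np.random.default_rng(0)
        t = np.arange(512) / 20.0
        x = np.sin(2 * np.pi * 1.3 * t) + 0.5 * rng.normal(size=512)
        n = x.size
        X = np.fft.fft(x)
        df = 20.0 / n
        k1, k2 = int(0.8 / df), int(2.0 / df)
        p = np.abs(X[k1:k2 + 1]) ** 2
        kpeak = k1 + int(np.argmax(p))
        num = np.sum(np.abs(X[max(k1, kpeak - 2):min(k2, kpeak + 2) + 1]) ** 2)
        expected = 10 * np.log10(num / (np.sum(p) - num))
        assert spectral_snr(x, 20.0) == pytest.approx(expected)

    def test_peak_restricted_to_band(self):
        t = np.arange(512) / 20.0
        rng = np.random.default_rng(1)
        # strong tone outside the band, weak one inside
        x = 10 * np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 1.1 * t) \
            + 0.3 * rng.normal(size=512)
        snr = spectral_snr(x, 20.0)
        n = x.size
        X = np.abs(np.fft.fft(x)) ** 2
        df = 20.0 / n
        k1, k2 = int(0.8 / df), int(2.0 / df)
        kpeak = k1 + int(np.argmax(X[k1:k2 + 1]))
        assert abs(kpeak * df - 1.1) < 0.1    # band clamp held
        assert np.isfinite(snr)

    def test_band_above_nyquist_raises(self):
        # at fs = 1.5 Hz the 0.8-2 Hz band lies beyond Nyquist entirely
        with pytest.raises(ValueError):
            spectral_snr(np.ones(8), 1.5)
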