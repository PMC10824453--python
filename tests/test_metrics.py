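"""Spectral and connectivity measures against independent oracles."""

import numpy as np
import pytest

from tdcsim.metrics import (
    PeakFrequency,
    aec,
    aec_matrix,
    bandpass_analytic,
    epoch_measures,
    global_fc,
    peak_frequency,
    pli,
    pli_matrix,
    posterior_region_indices,
    psd,
    relative_band_power,
)

FS = 1000.0


def sine(freq, n=4096, fs=FS, phase=0.0):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs + phase)


class TestPSD:
    def test_sinusoid_peak_location(self):
        f, p = psd(sine(10.0), FS)
        assert abs(f[np.argmax(p)] - 10.0) <= f[1] - f[0]

    def test_resolution_bound(self):
        f, _ = psd(sine(10.0), FS)
        assert f[1] - f[0] <= 0.5

    def test_white_noise_flat(self, rng):
        x = rng.normal(size=40960)
        f, p = psd(x, FS)
        band = p[(f > 50) & (f < 450)]
        assert band.max() / band.min() < 5.0  # no dominant structure

    def test_parseval_within_one_percent(self, rng):
        x = rng.normal(size=8192)
        x -= x.mean()
        f, p = psd(x, FS)
        assert np.trapezoid(p, f) == pytest.approx(x.var(), rel=0.01)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="short"):
            psd(np.zeros(100), FS)


class TestRelativeBandPower:
    def test_pure_tone_inside_band(self):
        f, p = psd(sine(9.0), FS)
        assert relative_band_power(f, p, (8, 10)) > 0.95

    def test_pure_tone_outside_band(self):
        f, p = psd(sine(20.0), FS)
        assert relative_band_power(f, p, (8, 10)) < 0.05

    def test_equal_power_mixture_splits_half(self):
        x = sine(6.0) + sine(9.0)
        f, p = psd(x, FS)
        assert relative_band_power(f, p, (8, 10), (4, 30)) == pytest.approx(0.5, abs=0.03)

    def test_band_validation(self):
        f, p = psd(sine(9.0), FS)
        with pytest.raises(ValueError):
            relative_band_power(f, p, (10, 8))
        with pytest.raises(ValueError):
            relative_band_power(f, p, (2, 10), (4, 30))


class TestPeakFrequency:
    def test_shared_oscillation(self):
        f, p = psd(np.vstack([sine(10.0), sine(10.0, phase=1.0)]), FS)
        assert peak_frequency(f, p).hz == pytest.approx(10.0, abs=0.5)

    def test_slowed_signal(self):
        f, p = psd(sine(8.0) + 0.2 * sine(11.0), FS)
        assert peak_frequency(f, p).hz == pytest.approx(8.0, abs=0.5)

    def test_tie_breaks_to_lower_frequency(self):
        f = np.arange(0, 20.0, 0.5)
        p = np.zeros_like(f)
        p[(f == 8.0) | (f == 10.0)] = 1.0
        assert peak_frequency(f, p).hz == 8.0

    def test_flat_spectrum_flags_midpoint(self):
        f = np.arange(0, 20.0, 0.5)
        with pytest.warns(UserWarning, match="flat"):
            out = peak_frequency(f, np.ones_like(f), search=(4, 13))
        assert out == PeakFrequency(hz=8.5, flat=True)


def brute_pli(x, y):
    """Sample-by-sample reference: sign of the wrapped phase difference."""
    from scipy.signal import hilbert

    phx = np.angle(hilbert(x))
    phy = np.angle(hilbert(y))
    signs = [np.sign(np.sin(a - b)) for a, b in zip(phx, phy)]
    return abs(sum(signs) / len(signs))


def brute_aec(x, y):
    from scipy.signal import hilbert

    ex, ey = np.abs(hilbert(x)), np.abs(hilbert(y))
    mx, my = ex.mean(), ey.mean()
    num = float(np.sum((ex - mx) * (ey - my)))
    den = float(np.sqrt(np.sum((ex - mx) ** 2) * np.sum((ey - my) ** 2)))
    return num / den


class TestPLI:
    def test_quarter_cycle_lag_gives_one(self):
        x, y = sine(10.0), sine(10.0, phase=np.pi / 2)
        assert pli(x, y) == pytest.approx(1.0, abs=1e-6)

    def test_zero_lag_gives_zero(self):
        x = sine(10.0)
        assert pli(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_random_phases_near_zero(self, rng):
        n = 10_000
        x = np.cos(rng.uniform(0, 2 * np.pi, n))
        y = np.cos(rng.uniform(0, 2 * np.pi, n))
        assert pli(x, y) < 3 / np.sqrt(n) * 3

    def test_amplitude_invariance_and_symmetry(self, rng):
        x = sine(9.0, 2000) + 0.1 * rng.normal(size=2000)
        y = sine(9.0, 2000, phase=0.7) + 0.1 * rng.normal(size=2000)
        assert pli(3.7 * x, y) == pytest.approx(pli(x, y), abs=1e-12)
        assert pli(x, y) == pytest.approx(pli(y, x), abs=1e-12)

    def test_matches_brute_force_on_short_signals(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert pli(x, y) == pytest.approx(brute_pli(x, y), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pli(np.array([]), np.array([]))


class TestAEC:
    def test_identical_signals(self, rng):
        x = sine(10.0) * (1 + 0.3 * np.sin(2 * np.pi * 0.7 * np.arange(4096) / FS))
        assert aec(x, x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(aec(x, y)) < 0.1

    def test_shared_slow_gain_drives_correlation_up(self, rng):
        n = 8192
        gain = 1 + 0.9 * np.sin(2 * np.pi * 0.5 * np.arange(n) / FS)
        x = gain * sine(10.0, n) + 0.01 * rng.normal(size=n)
        y = gain * sine(10.0, n, phase=2.0) + 0.01 * rng.normal(size=n)
        assert aec(x, y) > 0.95

    def test_envelope_preserving_phase_shift_invariance(self):
        x = sine(10.0)
        y = sine(10.0, phase=np.pi / 3)
        # both envelopes are constant up to edge effects -> undefined,
        # so modulate both identically and shift the carrier phase
        mod = 1 + 0.5 * np.sin(2 * np.pi * 1.0 * np.arange(4096) / FS)
        assert aec(mod * x, mod * y) == pytest.approx(1.0, abs=0.02)

    def test_constant_envelope_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            out = aec(np.zeros(100), np.zeros(100))
        assert np.isnan(out)

    def test_matches_brute_force_on_short_signals(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert aec(x, y) == pytest.approx(brute_aec(x, y), abs=1e-12)


class TestPairwiseMatrices:
    def test_vectorized_match_pairwise_calls(self, rng):
        sig = rng.normal(size=(4, 50))
        from scipy.signal import hilbert

        analytic = hilbert(sig, axis=-1)
        P = pli_matrix(analytic)
        A = aec_matrix(analytic)
        for i in range(4):
            for j in range(i + 1, 4):
                assert P[i, j] == pytest.approx(brute_pli(sig[i], sig[j]), abs=1e-12)
                assert A[i, j] == pytest.approx(brute_aec(sig[i], sig[j]), abs=1e-12)
        assert np.allclose(P, P.T) and np.allclose(A, A.T)


class TestGlobalFC:
    def test_all_ones_off_diagonal(self):
        m = np.ones((4, 4)) - np.eye(4)
        assert global_fc(m) == 1.0

    def test_two_by_two(self):
        assert global_fc(np.array([[0.0, 0.4], [0.4, 0.0]])) == 0.4

    def test_matches_double_loop(self, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        vals = [m[i, j] for i in range(6) for j in range(i + 1, 6)]
        assert global_fc(m) == pytest.approx(np.mean(vals), abs=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            global_fc(np.zeros((1, 1)))


class TestEpochMeasures:
    def test_synthetic_alpha_network(self, rng):
        n, samples = 5, 4096
        carrier = sine(9.0, samples)
        signals = np.column_stack(
            [carrier + 0.3 * rng.normal(size=samples) for _ in range(n)]
        )
        out = epoch_measures(signals, FS)
        assert out["lower_alpha"] > 0.5
        assert 8.0 <= out["peak_frequency"] <= 10.0
        assert 0.0 <= out["pli"] <= 1.0
        assert -1.0 <= out["aec"] <= 1.0
        assert out["total_power"] == pytest.approx(
            (signals - signals.mean(0)).var(axis=0).mean()
        )

    def test_band_filter_produces_analytic_signal(self):
        x = sine(9.0, 4096)[None, :]
        analytic = bandpass_analytic(x, FS)
        assert np.iscomplexobj(analytic)
        # envelope of a pure in-band tone is near-constant away from edges
        env = np.abs(analytic[0, 500:-500])
        assert env.std() / env.mean() < 0.05


class TestPosteriorRegions:
    def test_aal_labels_select_posterior_cortex(self):
        from tdcsim import aal78_labels

        idx = posterior_region_indices(aal78_labels())
        labels = [aal78_labels()[i] for i in idx]
        assert "Precuneus_L" in labels and "Occipital_Sup_R" in labels
        assert all("Frontal" not in lab for lab in labels)

    def test_unmatched_labels_fall_back_to_all(self):
        assert posterior_region_indices(["a", "b"]) == [0, 1]
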