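"""Spectral transforms and dDTF: closed forms, invariants, directed recovery."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import mannwhitneyu

import eegflow as ef
from eegflow.ddtf import BandSpec, SpectralSet


def model_from(coeffs, sigma=None):
    coeffs = tuple(np.asarray(A, float) for A in coeffs)
    m = coeffs[0].shape[0]
    sigma = np.eye(m) if sigma is None else sigma
    resid = np.random.default_rng(0).standard_normal((100, m))
    return ef.MVARModel(len(coeffs), coeffs, np.zeros(m), sigma, resid, 100)


class TestTransferFunction:
    def test_zero_coefficients_give_identity_magnitude(self):
        model = model_from([np.zeros((3, 3))])
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        np.testing.assert_allclose(np.abs(spec.H_f),
                                   np.broadcast_to(np.eye(3), spec.H_f.shape),
                                   atol=1e-12)

    def test_scalar_ar1_closed_form(self):
        a = 0.6
        model = model_from([np.array([[a]])])
        freqs = np.array([0.0, 10.0, 30.0])
        spec = ef.transfer_function(model, freqs, fs=128.0)
        expected = 1.0 / np.abs(1 - a * np.exp(-2j * np.pi * freqs / 128.0))
        np.testing.assert_allclose(np.abs(spec.H_f[:, 0, 0]), expected, rtol=1e-12)
        assert np.abs(spec.H_f[0, 0, 0]) == pytest.approx(1 / (1 - a))

    def test_2x2_var1_matches_elementwise_inverse(self):
        A1 = np.array([[0.5, 0.2], [-0.3, 0.4]])
        model = model_from([A1])
        freqs = np.arange(1.0, 51.0)
        spec = ef.transfer_function(model, freqs, fs=128.0)
        for fi, f in enumerate(freqs):
            z = np.exp(-2j * np.pi * f / 128.0)
            Af = np.eye(2) - A1 * z
            a, b = Af[0]
            c, d = Af[1]
            inv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
            np.testing.assert_allclose(spec.H_f[fi], inv, atol=1e-10)

    def test_h_times_a_is_identity(self):
        model = model_from([np.array([[0.4, 0.1], [0.2, 0.3]]),
                            np.array([[-0.2, 0.0], [0.1, -0.1]])])
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        prod = spec.H_f @ spec.A_f
        np.testing.assert_allclose(prod, np.broadcast_to(np.eye(2), prod.shape),
                                   atol=1e-8)

    def test_frequencies_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ef.transfer_function(model_from([np.zeros((2, 2))]),
                                 np.array([70.0]), fs=128.0)


class TestSpectralDensity:
    def test_identity_case(self):
        model = model_from([np.zeros((2, 2))])
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        ef.spectral_density(spec, np.eye(2))
        np.testing.assert_allclose(spec.S_f, np.broadcast_to(np.eye(2), spec.S_f.shape),
                                   atol=1e-12)

    def test_hermitian_at_every_frequency(self):
        model = model_from([np.array([[0.5, 0.2], [-0.1, 0.4]])],
                           sigma=np.array([[1.0, 0.3], [0.3, 2.0]]))
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        ef.spectral_density(spec, model.noise_covariance)
        herm = np.conj(np.swapaxes(spec.S_f, 1, 2))
        assert np.abs(spec.S_f - herm).max() < 1e-10

    def test_non_psd_sigma_rejected(self):
        model = model_from([np.zeros((2, 2))])
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        with pytest.raises(ValueError):
            ef.spectral_density(spec, np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_matches_welch_estimate(self):
        """Nonparametric oracle: model spectrum vs Welch PSD on a long
        simulation, compared at the five band centres."""
        A1 = np.array([[0.6, 0.3], [0.0, 0.5]])
        truth = ef.VARTruth(1, (A1,), np.eye(2), np.zeros(2))
        fs = 128.0
        rec = ef.simulate_recording(truth, duration_s=100_000 / fs, fs=fs, seed=1,
                                    scale_uv=1.0, channel_names=("a", "b"))
        model = ef.fit_mvar(rec.data, 1)
        centres = np.array([3.0, 6.0, 10.5, 22.0, 41.0])
        spec = ef.transfer_function(model_from([A1]), centres, fs=fs)
        ef.spectral_density(spec, np.eye(2))
        # short segments: many averages keep the per-bin estimator noise well
        # below the 15% comparison band (the spectrum is smooth at 0.125 Hz)
        f_w, p_w = sps.welch(rec.data, fs=fs, nperseg=1024, axis=0)
        for ci, f0 in enumerate(centres):
            wi = int(np.argmin(np.abs(f_w - f0)))
            for ch in range(2):
                model_psd = 2 * spec.S_f[ci, ch, ch].real / fs  # one-sided density
                welch_psd = p_w[wi - 2:wi + 3, ch].mean()  # +/-0.25 Hz around centre
                assert abs(welch_psd - model_psd) / model_psd < 0.15


class TestDdtfMatrix:
    def test_identity_spectra_give_zero_offdiagonal(self):
        freqs = np.arange(1.0, 51.0)
        F = len(freqs)
        eye = np.broadcast_to(np.eye(2), (F, 2, 2)).astype(complex)
        spec = SpectralSet(freqs, eye.copy(), eye.copy(), eye.copy())
        d = ef.ddtf_matrix(spec)
        off = d[:, ~np.eye(2, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_ffdtf_normalization_sums_to_one_per_target(self):
        model = model_from([np.array([[0.5, 0.2], [-0.3, 0.4]])])
        spec = ef.transfer_function(model, np.arange(1.0, 51.0), fs=128.0)
        ef.spectral_density(spec, np.eye(2))
        H2 = np.abs(spec.H_f) ** 2
        ff = H2 / H2.sum(axis=(0, 2))[None, :, None]
        np.testing.assert_allclose(ff.sum(axis=(0, 2)), 1.0, atol=1e-8)

    def test_values_bounded_in_unit_interval(self, small_table):
        assert np.nanmin(small_table.X) >= 0.0
        assert np.nanmax(small_table.X) <= 1.0

    def test_unidirectional_coupling_recovered(self, var1_truth):
        """Flow 1 -> 2 only: summed-band dDTF(2<-1) > dDTF(1<-2) in >= 95/100 fits."""
        hits = 0
        for seed in range(100):
            rec = ef.simulate_recording(var1_truth, duration_s=6.0, fs=128.0,
                                        seed=seed, channel_names=("a", "b"))
            model = ef.fit_mvar(rec.data, 1)
            spec = ef.transfer_function(model, ef.DEFAULT_FREQS, fs=128.0)
            ef.spectral_density(spec, model.noise_covariance)
            band = ef.band_average(ef.ddtf_matrix(spec))
            forward = band[:, 1, 0].sum()   # source 0 -> target 1
            backward = band[:, 0, 1].sum()
            hits += forward > backward
        assert hits >= 95

    def test_null_specificity_uncoupled_vs_coupled(self, var1_truth):
        """Off-diagonal dDTF on uncoupled pairs is stochastically smaller than
        on the truly coupled pair (one-sided rank test over 100 windows)."""
        null_truth = ef.VARTruth(1, (0.5 * np.eye(2),), np.eye(2), np.zeros(2))
        coupled, uncoupled = [], []
        for seed in range(100):
            for truth, sink in ((var1_truth, coupled), (null_truth, uncoupled)):
                rec = ef.simulate_recording(truth, duration_s=6.0, fs=128.0,
                                            seed=seed, channel_names=("a", "b"))
                model = ef.fit_mvar(rec.data, 1)
                spec = ef.transfer_function(model, ef.DEFAULT_FREQS, fs=128.0)
                ef.spectral_density(spec, model.noise_covariance)
                band = ef.band_average(ef.ddtf_matrix(spec))
                sink.append(band[:, 1, 0].mean())
        _, p = mannwhitneyu(uncoupled, coupled, alternative="less")
        assert p < 0.01


class TestBandAverage:
    def test_constant_value_preserved(self):
        freqs = np.arange(1.0, 51.0)
        d = np.full((len(freqs), 2, 2), 0.37)
        out = ef.band_average(d, freqs)
        np.testing.assert_allclose(out, 0.37)

    def test_delta_band_members_on_1hz_grid(self):
        freqs = np.arange(1.0, 51.0)
        members = BandSpec().members(freqs)
        np.testing.assert_array_equal(freqs[members["delta"]], [2.0, 3.0])

    def test_bands_partition_2_to_50_hz(self):
        freqs = np.arange(1.0, 51.0)
        members = BandSpec().members(freqs)
        covered = np.concatenate([freqs[idx] for idx in members.values()])
        assert len(covered) == len(set(covered))
        np.testing.assert_array_equal(np.sort(covered), np.arange(2.0, 51.0))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no grid"):
            BandSpec().members(np.array([1.0]))


class TestConnectivityForRecording:
    def test_stew_geometry_tensor_shape(self):
        truth = ef.make_var_coefficients(ef.default_coupling_spec(), order=2)
        rec = ef.simulate_recording(truth[ef.HIGH], duration_s=150.0, fs=128.0, seed=0)
        t = ef.connectivity_for_recording(rec, ef.ConnectivityConfig(order=2))
        assert t.values.shape == (37, 5, 14, 14)
        assert t.valid.all()
        valid_vals = t.values[t.valid]
        assert valid_vals.min() >= 0.0 and valid_vals.max() <= 1.0

    def test_deterministic(self):
        truth = ef.make_var_coefficients(ef.default_coupling_spec(), order=2)
        rec = ef.simulate_recording(truth[ef.LOW], duration_s=20.0, fs=128.0, seed=5)
        a = ef.connectivity_for_recording(rec, ef.ConnectivityConfig(order=2))
        b = ef.connectivity_for_recording(rec, ef.ConnectivityConfig(order=2))
        np.testing.assert_array_equal(a.values, b.values)

    def test_partial_coherence_mode_also_bounded(self):
        truth = ef.make_var_coefficients(ef.default_coupling_spec(), order=2)
        rec = ef.simulate_recording(truth[ef.LOW], duration_s=20.0, fs=128.0, seed=5)
        t = ef.connectivity_for_recording(
            rec, ef.ConnectivityConfig(order=2, coherence_basis="partial"))
        vals = t.values[t.valid]
        assert vals.min() >= 0.0 and vals.max() <= 1.0 + 1e-9
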