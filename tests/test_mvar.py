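"""Windowing arithmetic, least-squares estimation, order selection, diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegflow as ef
from eegflow.synthetic import Recording


def make_rec(T, m=2, fs=1.0, seed=0):
    data = np.random.default_rng(seed).standard_normal((T, m))
    return Recording(data, fs=fs, channel_names=tuple(f"c{i}" for i in range(m)))


class TestSegmentWindows:
    def test_stew_geometry_gives_37_windows(self):
        rec = make_rec(19_200, fs=128.0)
        ws = ef.segment_windows(rec, 6.0, 4.0)
        assert len(ws) == 37

    def test_window_equal_to_duration_gives_one(self):
        rec = make_rec(1280, fs=128.0)
        ws = ef.segment_windows(rec, 10.0, 4.0)
        assert len(ws) == 1 and ws.starts[0] == 0

    def test_20s_example_starts(self):
        rec = make_rec(2560, fs=128.0)
        ws = ef.segment_windows(rec, 6.0, 4.0)
        assert len(ws) == 4
        np.testing.assert_array_equal(ws.starts, [0, 512, 1024, 1536])

    def test_window_longer_than_recording_rejected(self):
        with pytest.raises(ValueError):
            ef.segment_windows(make_rec(100, fs=1.0), 200.0, 10.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(T=st.integers(10, 3000), w=st.integers(1, 400), s=st.integers(1, 300))
    def test_count_matches_enumeration_of_valid_starts(self, T, w, s):
        if w > T:
            return
        brute = sum(1 for start in range(0, T, s) if start + w <= T)
        assert ef.window_count(T, w, s) == brute


class TestFitMvar:
    def test_residuals_satisfy_normal_equations(self):
        rec = make_rec(500, m=3, seed=1)
        model = ef.fit_mvar(rec.data, 2)
        x = rec.data - rec.data.mean(axis=0)
        Z = np.hstack([x[1:-1], x[:-2]])
        g = Z.T @ model.residuals
        assert np.abs(g).max() / np.abs(Z).max() < 1e-8

    def test_var1_coefficient_recovery_over_seeds(self):
        """Entries of A1 = 0.5 I recovered within +/-0.05 at T = 10,000."""
        truth = ef.VARTruth(1, (0.5 * np.eye(2),), np.eye(2), np.zeros(2))
        ok = 0
        for seed in range(20):
            rec = ef.simulate_recording(truth, duration_s=10_000, fs=1.0, seed=seed,
                                        scale_uv=1.0, channel_names=("a", "b"))
            model = ef.fit_mvar(rec.data, 1)
            ok += np.abs(model.coefficients[0] - truth.coefficients[0]).max() < 0.05
        assert ok >= 19

    def test_white_noise_coefficients_near_zero(self):
        truth = ef.VARTruth(1, (np.zeros((2, 2)),), np.eye(2), np.zeros(2))
        ok = 0
        for seed in range(20):
            rec = ef.simulate_recording(truth, duration_s=10_000, fs=1.0, seed=seed,
                                        scale_uv=1.0, channel_names=("a", "b"))
            model = ef.fit_mvar(rec.data, 2)
            ok += max(np.abs(A).max() for A in model.coefficients) < 0.05
        assert ok >= 19

    def test_duplicated_channel_reported_singular(self):
        x = np.random.default_rng(0).standard_normal((300, 2))
        dup = np.column_stack([x, x[:, 0]])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            ef.fit_mvar(dup, 2)

    def test_average_referenced_data_fits_via_common_mode_tolerance(self):
        """Average re-referencing leaves an exact common-mode null space that
        the fit must tolerate (minimum-norm) rather than reject."""
        rec = make_rec(800, m=4, seed=2)
        avg = rec.data - rec.data.mean(axis=1, keepdims=True)
        model = ef.fit_mvar(avg, 2)
        assert model.companion_radius() < 1.0

    def test_matches_statsmodels_var(self):
        """Independent oracle: statsmodels VAR OLS on demeaned data."""
        from statsmodels.tsa.vector_ar.var_model import VAR

        rng = np.random.default_rng(7)
        a1 = np.array([[0.5, 0.1], [-0.2, 0.3]])
        truth = ef.VARTruth(1, (a1,), np.eye(2), np.zeros(2))
        rec = ef.simulate_recording(truth, duration_s=2000, fs=1.0, seed=7,
                                    scale_uv=1.0, channel_names=("a", "b"))
        mine = ef.fit_mvar(rec.data, 2)
        sm = VAR(rec.data - rec.data.mean(axis=0)).fit(2, trend="n")
        for k in range(2):
            np.testing.assert_allclose(mine.coefficients[k], sm.coefs[k], atol=1e-8)


class TestOrderSelection:
    def test_single_candidate(self):
        rec = make_rec(300, seed=3)
        order, curve = ef.select_order_aic(rec.data, 1)
        assert order == 1 and set(curve) == {1}

    def test_recovers_true_order_of_strong_var2(self):
        a1 = np.array([[0.4, 0.2], [0.0, 0.3]])
        a2 = np.array([[-0.5, 0.0], [0.25, -0.45]])
        truth = ef.VARTruth(2, (a1, a2), np.eye(2), np.zeros(2))
        assert truth.is_stable()
        hits = 0
        for seed in range(50):
            rec = ef.simulate_recording(truth, duration_s=768, fs=1.0, seed=seed,
                                        scale_uv=1.0, channel_names=("a", "b"))
            order, _ = ef.select_order_aic(rec.data, 5)
            hits += order == 2
        assert hits >= 35  # >= 70% of replicates

    def test_white_noise_prefers_smallest_order(self):
        truth = ef.VARTruth(1, (np.zeros((2, 2)),), np.eye(2), np.zeros(2))
        hits = 0
        for seed in range(50):
            rec = ef.simulate_recording(truth, duration_s=768, fs=1.0, seed=seed,
                                        scale_uv=1.0, channel_names=("a", "b"))
            order, _ = ef.select_order_aic(rec.data, 4)
            hits += order == 1
        assert hits > 25

    def test_aic_curve_finite_on_full_rank_window(self):
        rec = make_rec(400, m=3, seed=4)
        _, curve = ef.select_order_aic(rec.data, 6)
        assert all(np.isfinite(v) for v in curve.values())


class TestDiagnostics:
    def test_whiteness_on_self_simulated_data(self):
        a1 = np.array([[0.5, 0.2], [-0.1, 0.4]])
        truth = ef.VARTruth(1, (a1,), np.eye(2), np.zeros(2))
        ok = 0
        for seed in range(50):
            rec = ef.simulate_recording(truth, duration_s=1000, fs=1.0, seed=seed,
                                        scale_uv=1.0, channel_names=("a", "b"))
            model = ef.fit_mvar(rec.data, 1)
            diag = ef.validate_model(model, rec.data, seed=seed)
            ok += diag.whiteness_pvalue > 0.05
        assert ok >= 45  # >= 90% of replicates

    def test_companion_radius_of_diagonal_var1(self):
        model = ef.MVARModel(1, (0.5 * np.eye(3),), np.zeros(3), np.eye(3),
                             np.random.default_rng(0).standard_normal((100, 3)), 100)
        diag = ef.validate_model(model, np.random.default_rng(1).standard_normal((101, 3)))
        assert diag.companion_radius == pytest.approx(0.5)
        assert diag.stable

    def test_explosive_model_flagged_unstable(self):
        model = ef.MVARModel(1, (1.1 * np.eye(2),), np.zeros(2), np.eye(2),
                             np.random.default_rng(0).standard_normal((100, 2)), 100)
        diag = ef.validate_model(model, np.random.default_rng(1).standard_normal((101, 2)))
        assert diag.companion_radius == pytest.approx(1.1)
        assert not diag.stable

    def test_consistency_high_for_well_specified_model(self):
        a1 = np.array([[0.6, 0.2], [0.0, 0.5]])
        truth = ef.VARTruth(1, (a1,), np.eye(2), np.zeros(2))
        rec = ef.simulate_recording(truth, duration_s=4000, fs=1.0, seed=0,
                                    scale_uv=1.0, channel_names=("a", "b"))
        model = ef.fit_mvar(rec.data, 1)
        diag = ef.validate_model(model, rec.data, seed=0)
        assert diag.consistency_percent > 60.0


class TestEstimatorConsistency:
    def test_rmse_decreases_with_sample_size(self):
        a1 = np.array([[0.5, 0.3], [0.1, 0.4]])
        truth = ef.VARTruth(1, (a1,), np.eye(2), np.zeros(2))
        rmse = []
        for T in (1000, 4000, 16000):
            errs = []
            for seed in range(5):
                rec = ef.simulate_recording(truth, duration_s=T, fs=1.0, seed=seed,
                                            scale_uv=1.0, channel_names=("a", "b"))
                model = ef.fit_mvar(rec.data, 1)
                errs.append(np.linalg.norm(model.coefficients[0] - a1))
            rmse.append(np.mean(errs))
        assert rmse[0] > rmse[1] > rmse[2]
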