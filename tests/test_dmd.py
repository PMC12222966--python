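"""Exact DMD, Hankel embedding, HoDMD: linear oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycodmd import (
    DMDModel,
    OscillatorParams,
    SnapshotPair,
    build_hankel,
    cell_mode_amplitude_features,
    fit_exact_dmd,
    fit_hodmd,
    predict,
    reconstruct,
    simulate_cell,
    solve_amplitudes,
    to_continuous_rates,
)
from glycodmd.errors import (
    DegenerateDataError,
    EmbeddingError,
    RankTruncationWarning,
)
from glycodmd.metrics import trace_fit_metrics


def exponential_mixture(rates, amps, n=80):
    """Rows of sums of real exponentials (known generator)."""
    k = np.arange(n)
    comps = np.array([a * r ** k for r, a in zip(rates, amps)])
    return comps


class TestHankel:
    def test_zero_embedding_returns_input(self):
        X = np.arange(12.0).reshape(3, 4)
        emb = build_hankel(X, d=0)
        assert np.array_equal(emb.H, X)

    def test_hand_constructed_stack(self):
        X = np.array([[0., 1., 2., 3., 4.],
                      [10., 11., 12., 13., 14.]])
        emb = build_hankel(X, d=1, l=1)
        expected = np.array([[0., 1., 2., 3.],
                             [10., 11., 12., 13.],
                             [1., 2., 3., 4.],
                             [11., 12., 13., 14.]])
        assert np.array_equal(emb.H, expected)

    @pytest.mark.parametrize("l", [1, 5])
    def test_step_lengths_give_expected_columns(self, l):
        X = np.random.default_rng(0).normal(size=(3, 40))
        emb = build_hankel(X, d=4, l=l)
        assert emb.H.shape == (15, 40 - 4 * l)

    def test_too_deep_embedding_reports_maximum(self):
        X = np.zeros((2, 10))
        with pytest.raises(EmbeddingError, match="d = 4"):
            build_hankel(X, d=9, l=2)


class TestExactDMD:
    def test_scalar_decay_recovers_rate(self):
        X = exponential_mixture([0.5], [1.0])
        model = fit_exact_dmd(X[:, :20], r=1)
        assert model.eigenvalues[0] == pytest.approx(0.5, abs=1e-10)

    def test_planar_rotation_eigenvalues(self, rotation_data):
        X, theta = rotation_data
        model = fit_exact_dmd(X, r=2)
        lam = np.sort_complex(model.eigenvalues)
        expected = np.sort_complex(np.array([np.exp(1j * theta),
                                             np.exp(-1j * theta)]))
        assert np.allclose(lam, expected, atol=1e-8)

    def test_mixed_linear_generator(self):
        # block diagonal: decay 0.9, rotation 0.2 rad scaled by 0.97
        A = np.zeros((3, 3))
        A[0, 0] = 0.9
        A[1:, 1:] = 0.97 * np.array([[np.cos(0.2), -np.sin(0.2)],
                                     [np.sin(0.2), np.cos(0.2)]])
        X = np.empty((3, 50))
        X[:, 0] = [1.0, 0.5, -0.2]
        for k in range(49):
            X[:, k + 1] = A @ X[:, k]
        model = fit_exact_dmd(X, r=3)
        assert np.allclose(np.sort_complex(model.eigenvalues),
                           np.sort_complex(np.linalg.eigvals(A)), atol=1e-8)

    def test_requested_rank_sets_eigenvalue_count(self, rotation_data):
        X, _ = rotation_data
        noisy = np.vstack([X] * 4) + 1e-3 * np.random.default_rng(1).normal(
            size=(8, X.shape[1]))
        model = fit_exact_dmd(noisy, r=5)
        assert len(model.eigenvalues) == 5
        assert model.modes.shape[1] == 5

    def test_rank_beyond_numerical_rank_warns_and_truncates(self):
        base = exponential_mixture([0.5], [1.0])[0]
        X = np.vstack([base, 2 * base, -3 * base])  # numerical rank 1
        with pytest.warns(RankTruncationWarning):
            model = fit_exact_dmd(X[:, :40], r=2)
        assert model.rank == 1

    def test_all_zero_input_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_exact_dmd(np.zeros((3, 10)), r=1)

    def test_conjugate_closure_for_real_input(self, standard_population):
        X = standard_population["f6p"].data[:20]
        model = fit_exact_dmd(build_hankel(X, d=20), r=10)
        lam = model.eigenvalues
        for z in lam:
            if abs(z.imag) > 1e-10:
                assert np.min(np.abs(lam - z.conjugate())) < 1e-8


class TestContinuousRates:
    def test_unit_eigenvalue_maps_to_zero_rate(self):
        assert to_continuous_rates([1.0], dt=2.0)[0] == 0

    def test_pure_phase(self):
        omega = to_continuous_rates([np.exp(0.2j)], dt=1.0)[0]
        assert omega == pytest.approx(0.2j, abs=1e-12)

    @given(st.floats(0.05, 2.0), st.floats(-3.0, 3.0), st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip(self, mag, angle, dt):
        lam = mag * np.exp(1j * angle)
        omega = to_continuous_rates([lam], dt)[0]
        assert abs(np.exp(omega * dt) - lam) < 1e-12 * max(1.0, mag)

    def test_zero_eigenvalue_sentinel(self):
        omega = to_continuous_rates([0.0], dt=1.0)[0]
        assert omega.real == -np.inf


class TestAmplitudes:
    def test_recovers_known_mixture_amplitudes(self):
        X = exponential_mixture([0.9, 0.6], [1.0, 1.0])
        data = np.vstack([3.0 * X[0] + 1.0 * X[1],
                          3.0 * X[0] - 1.0 * X[1]])
        model = fit_exact_dmd(data, r=2)
        recon = reconstruct(model, np.arange(data.shape[1]))
        assert np.allclose(recon, data, atol=1e-8)
        # amplitude of each exponential in the first row is (3, 1)
        contrib = np.abs(model.modes[0] * model.amplitudes)
        assert np.allclose(np.sort(contrib), [1.0, 3.0], atol=1e-8)

    def test_first_mode_snapshot_gives_unit_vector(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        b, resid = solve_amplitudes(model, model.modes[:, 0])
        assert np.allclose(b, [1.0, 0.0], atol=1e-10)
        assert resid < 1e-10

    def test_amplitudes_scale_linearly(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        b1, _ = solve_amplitudes(model, X[:, 0])
        b2, _ = solve_amplitudes(model, 2.5 * X[:, 0])
        assert np.allclose(b2, 2.5 * b1, atol=1e-10)


class TestReconstructPredict:
    def test_exact_linear_data_reconstructed(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        recon = reconstruct(model)
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_matches_brute_force_modal_sum(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        ks = np.arange(10)
        recon = reconstruct(model, ks)
        brute = np.stack([
            (model.modes[:model.m_rows] @
             (model.amplitudes * model.eigenvalues ** k)).real
            for k in ks], axis=1)
        assert np.allclose(recon, brute, atol=1e-12)

    def test_negative_steps_rejected(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        with pytest.raises(ValueError):
            reconstruct(model, np.array([-1, 0]))

    def test_forecast_of_decaying_exponential_is_exact(self):
        X = exponential_mixture([0.8], [2.0], n=30)
        model = fit_exact_dmd(X, r=1)
        result = predict(model, horizon=40)
        k = np.arange(30, 70)
        assert np.allclose(result.forecast[0], 2.0 * 0.8 ** k, atol=1e-8)
        assert result.split_index == 30

    def test_forecast_equals_extended_reconstruction(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        result = predict(model, horizon=15)
        full = reconstruct(model, np.arange(model.n_times + 15))
        assert np.allclose(result.fitted, full[:, :model.n_times])
        assert np.allclose(result.forecast, full[:, model.n_times:])

    def test_damped_forecast_beats_sustained(self):
        # damped (n = 2) transients extrapolate better than limit cycles
        r2 = {}
        for key, (v, n) in {"damped": (14.5, 2.0),
                            "sustained": (10.0, 3.0)}.items():
            p = OscillatorParams(v=v, n_hill=n, noise_sigma=0.0)
            x = simulate_cell(p).f6p
            x = x - x.mean()
            split = 400
            model = fit_exact_dmd(
                build_hankel(x[:split][None, :], d=150, dt=p.dt_out), r=12)
            recon = reconstruct(model, np.arange(x.size))[0]
            r2[key] = trace_fit_metrics(x[split:], recon[split:]).r2
        assert r2["sustained"] < r2["damped"]


class TestHoDMD:
    def test_order_one_equals_exact_dmd(self, rotation_data):
        X, _ = rotation_data
        exact = fit_exact_dmd(X, r=2)
        hodmd = fit_hodmd(X, d=1, r=2)
        assert np.allclose(np.sort_complex(hodmd.eigenvalues),
                           np.sort_complex(exact.eigenvalues), atol=1e-10)

    def test_deep_embedding_improves_oscillation_fit(self):
        p = OscillatorParams(v=14.5, seed=21)
        x = simulate_cell(p).f6p
        x = (x - x.mean())[None, :]

        def r2_at(d):
            model = fit_hodmd(x, d=d, r=10, dt=p.dt_out)
            cols = x.shape[1] - (d - 1)
            recon = reconstruct(model, np.arange(cols))
            return trace_fit_metrics(x[:, :cols], recon).r2

        assert r2_at(300) > r2_at(10)

    def test_reconstructs_synthetic_video(self):
        from glycodmd import TraceMatrix, frame_snapshot_matrix, synth_video
        base = OscillatorParams(noise_sigma=0.0, t_end=4.0)
        cells = np.stack([simulate_cell(base.with_(v=v)).f6p
                          for v in (13.5, 14.5, 16.0)])
        traces = TraceMatrix(cells, dt=base.dt_out)
        video = synth_video(traces, height=16, width=16, cell_radius=3,
                            background=2.0)
        M = frame_snapshot_matrix(video)
        model = fit_hodmd(M, d=30, r=12, dt=video.dt)
        recon = reconstruct(model, np.arange(M.shape[1]))
        r2 = trace_fit_metrics(M.ravel(), recon.ravel()).r2
        assert r2 > 0.9


class TestAmplitudeFeatures:
    def test_phase_gauge_invariance(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        before = cell_mode_amplitude_features(model)
        model.modes[:, 0] *= np.exp(0.7j)
        model.amplitudes[0] *= np.exp(-0.7j)
        after = cell_mode_amplitude_features(model)
        assert np.allclose(before, after, atol=1e-12)

    def test_identical_cells_identical_features(self):
        p = OscillatorParams(v=14.5, seed=5)
        x = simulate_cell(p).f6p
        data = np.vstack([x, x, x * 0 + x])  # duplicated rows
        model = fit_exact_dmd(build_hankel(data, d=30, dt=p.dt_out), r=6)
        feats = cell_mode_amplitude_features(model)
        assert np.allclose(feats[0], feats[1], atol=1e-9)

    def test_matches_elementwise_modulus(self, rotation_data):
        X, _ = rotation_data
        model = fit_exact_dmd(X, r=2)
        feats = cell_mode_amplitude_features(model)
        for i in range(feats.shape[0]):
            for j in range(feats.shape[1]):
                z = model.modes[i, j] * model.amplitudes[j]
                assert feats[i, j] == pytest.approx(
                    np.sqrt(z.real ** 2 + z.imag ** 2), abs=1e-12)
        assert (feats >= 0).all()


class TestModelSerialization:
    def test_json_roundtrip(self, rotation_data, tmp_path):
        X, _ = rotation_data
        model = fit_exact_dmd(SnapshotPair.from_matrix(X, dt=0.5), r=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = DMDModel.from_json(path)
        assert np.allclose(loaded.eigenvalues, model.eigenvalues)
        assert np.allclose(loaded.modes, model.modes)
        assert np.allclose(loaded.amplitudes, model.amplitudes)
        assert loaded.dt == model.dt
        recon = reconstruct(loaded, np.arange(5))
        assert np.allclose(recon, reconstruct(model, np.arange(5)))
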