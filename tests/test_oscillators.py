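"""Glycolysis oscillator: fixed point, linearization, regimes, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from glycodmd import (
    CellTrace,
    OscillatorParams,
    PopulationSpec,
    Regime,
    classify_regime,
    fixed_point,
    jacobian_eigenvalues,
    population_analytic_spectrum,
    simulate_cell,
    simulate_population,
)
from glycodmd.errors import MarginalStabilityWarning
from glycodmd.oscillators import (
    classify_regime_from_eigenvalues,
    draw_influx,
    hill_activation,
    jacobian,
    sustained_by_simulation,
)

valid_params = st.builds(
    OscillatorParams,
    v=st.floats(5.0, 20.0),
    k1=st.floats(1.0, 8.0),
    k2=st.floats(1.0, 8.0),
    K=st.floats(1.0, 8.0),
    n_hill=st.floats(1.0, 4.0),
)


class TestFixedPoint:
    def test_flux_balance_of_linear_removal(self):
        p = OscillatorParams(v=14.5, k2=4.0)
        _, y_ss = fixed_point(p)
        assert y_ss == pytest.approx(3.625, abs=1e-12)

    def test_f16bp_linear_in_influx(self):
        p = OscillatorParams(v=6.0)
        assert fixed_point(p.with_(v=12.0))[1] == 2 * fixed_point(p)[1]

    def test_f6p_matches_root_finder(self):
        p = OscillatorParams(v=14.5)
        y_ss = p.v / p.k2
        h = hill_activation(y_ss, p.K, p.n_hill, p.basal)
        x_oracle = brentq(lambda x: p.v - p.k1 * x * h, 1e-6, 1e6,
                          xtol=1e-12)
        assert fixed_point(p)[0] == pytest.approx(x_oracle, abs=1e-9)

    @given(valid_params)
    @settings(max_examples=50, deadline=None)
    def test_derivatives_vanish_at_fixed_point(self, p):
        x_ss, y_ss = fixed_point(p)
        flux = p.k1 * x_ss * hill_activation(y_ss, p.K, p.n_hill, p.basal)
        assert abs(p.v - flux) < 1e-10 * max(1.0, p.v)
        assert abs(flux - p.k2 * y_ss) < 1e-10 * max(1.0, p.v)


class TestLinearization:
    @given(valid_params)
    @settings(max_examples=50, deadline=None)
    def test_eigenvalue_sum_and_product_identities(self, p):
        J = jacobian(p)
        l1, l2 = jacobian_eigenvalues(p)
        assert l1 + l2 == pytest.approx(np.trace(J), rel=1e-10, abs=1e-10)
        assert l1 * l2 == pytest.approx(np.linalg.det(J), rel=1e-10,
                                        abs=1e-10)

    @pytest.mark.parametrize("v,n", [(10.0, 2.0), (10.0, 3.0), (14.5, 3.0),
                                     (7.0, 3.0)])
    def test_eigenvalues_match_finite_difference_jacobian(self, v, n):
        p = OscillatorParams(v=v, n_hill=n)
        x_ss, y_ss = fixed_point(p)
        h = 1e-6

        def rhs(x, y):
            flux = p.k1 * x * hill_activation(y, p.K, p.n_hill, p.basal)
            return np.array([p.v - flux, flux - p.k2 * y])

        J_fd = np.column_stack([
            (rhs(x_ss + h, y_ss) - rhs(x_ss - h, y_ss)) / (2 * h),
            (rhs(x_ss, y_ss + h) - rhs(x_ss, y_ss - h)) / (2 * h),
        ])
        lam_fd = np.sort_complex(np.linalg.eigvals(J_fd))
        lam = np.sort_complex(np.array(jacobian_eigenvalues(p)))
        assert np.allclose(lam, lam_fd, atol=1e-6)

    def test_band_around_14_5_is_mostly_damped_focus(self):
        # most cells in the 12.5-16.5 mM/min influx band are stable foci
        vs = np.linspace(12.5, 16.5, 41)
        regs = [classify_regime(OscillatorParams(v=float(v))) for v in vs]
        damped = sum(r is Regime.DAMPED_OSCILLATION for r in regs)
        assert damped / len(regs) > 0.9
        ims = [jacobian_eigenvalues(OscillatorParams(v=float(v)))[0].imag
               for v in vs]
        assert all(im != 0 for im in ims)


class TestRegimeClassification:
    def test_hill_coefficient_controls_oscillation_onset(self):
        # damped at n = 2, sustained from n = 3 on, with k2 = 4/min
        p = OscillatorParams(k2=4.0)
        assert classify_regime(p.with_(n_hill=2.0)) is \
            Regime.DAMPED_OSCILLATION
        assert classify_regime(p.with_(n_hill=3.0)) is \
            Regime.SUSTAINED_OSCILLATION

    def test_real_negative_pair_is_stable_node(self):
        assert classify_regime_from_eigenvalues(-1.0 + 0j, -2.0 + 0j) is \
            Regime.STABLE_NODE

    def test_marginal_eigenvalue_warns(self):
        with pytest.warns(MarginalStabilityWarning):
            classify_regime_from_eigenvalues(1e-12 + 1j, 1e-12 - 1j)

    def test_agrees_with_simulation_oracle_on_grid(self):
        # independent oracle: noiseless long-horizon envelope decay test
        for v in [6.0, 9.0, 12.0, 15.0, 18.0]:
            for n in [1.5, 2.0, 2.5, 3.0, 4.0]:
                p = OscillatorParams(v=v, n_hill=n)
                by_eig = classify_regime(p) is Regime.SUSTAINED_OSCILLATION
                assert by_eig == sustained_by_simulation(p), (v, n)


class TestSimulation:
    def test_equilibrium_is_invariant(self):
        p = OscillatorParams(noise_sigma=0.0)
        p = p.with_(x0=fixed_point(p))
        trace = simulate_cell(p)
        assert np.ptp(trace.f6p) < 1e-8
        assert np.ptp(trace.f16bp) < 1e-8

    def test_matches_finer_step_reference(self):
        p = OscillatorParams(noise_sigma=0.0, t_end=5.0)
        coarse = simulate_cell(p)
        fine = simulate_cell(p.with_(dt=p.dt / 10, sample_every=100))
        scale = np.abs(fine.f6p).max()
        assert np.max(np.abs(coarse.f6p - fine.f6p)) / scale < 1e-4

    def test_sustained_amplitude_does_not_decay(self):
        p = OscillatorParams(n_hill=3.0, noise_sigma=0.0, t_end=40.0)
        trace = simulate_cell(p)
        _, y_ss = fixed_point(p)
        dev = np.abs(trace.f16bp - y_ss)
        period = int(round(2 * np.pi / abs(
            jacobian_eigenvalues(p)[0].imag) / p.dt_out))
        last = dev[-5 * period:]
        prev = dev[-10 * period:-5 * period]
        assert last.max() > 0.9 * prev.max()

    def test_seeded_reproducibility(self):
        p = OscillatorParams(seed=11)
        a, b = simulate_cell(p), simulate_cell(p)
        assert np.array_equal(a.f6p, b.f6p)

    @given(st.floats(0.0, 0.5), st.integers(0, 2 ** 16))
    @settings(max_examples=20, deadline=None)
    def test_concentrations_stay_nonnegative(self, sigma, seed):
        p = OscillatorParams(noise_sigma=sigma, seed=seed, t_end=2.0)
        trace = simulate_cell(p)
        assert (trace.f6p >= 0).all() and (trace.f16bp >= 0).all()

    def test_trace_validation_rejects_negative(self):
        with pytest.raises(ValueError):
            CellTrace(f6p=np.array([1.0, -0.1]), f16bp=np.array([1.0, 1.0]),
                      dt=1.0, params=OscillatorParams())


class TestPopulation:
    def test_population_size_and_distinct_influx(self):
        f6p, _, v = simulate_population(PopulationSpec(seed=3))
        assert f6p.n_cells == 100
        assert len(np.unique(v)) == 100

    def test_degenerate_population_rows_identical(self):
        base = OscillatorParams(noise_sigma=0.0)
        spec = PopulationSpec(n_cells=5, v_log_sd=0.0, base=base, seed=0)
        f6p, _, _ = simulate_population(spec)
        assert np.allclose(f6p.data, f6p.data[0][None, :])

    def test_influx_median_is_calibrated(self):
        spec = PopulationSpec(n_cells=1000, seed=12)
        v = draw_influx(spec)
        # log-median standard error for a log-normal sample
        se = spec.v_log_sd / np.sqrt(spec.n_cells) * np.sqrt(np.pi / 2)
        assert abs(np.log(np.median(v)) - np.log(14.5)) < 2 * se

    def test_population_deterministic_under_seed(self):
        a, _, _ = simulate_population(PopulationSpec(seed=9, n_cells=10))
        b, _, _ = simulate_population(PopulationSpec(seed=9, n_cells=10))
        assert np.array_equal(a.data, b.data)


class TestAnalyticSpectrum:
    def test_two_conjugate_eigenvalues_per_cell(self, standard_population):
        ana = standard_population["analytic"]
        assert ana.eigenvalues.shape == (100, 2)
        assert ana.flat_phases.size == 200
        assert np.allclose(ana.eigenvalues[:, 0],
                           np.conj(ana.eigenvalues[:, 1]))

    def test_phases_lie_on_unit_circle(self, standard_population):
        ana = standard_population["analytic"]
        assert np.allclose(np.abs(ana.discrete_phases), 1.0, atol=1e-12)

    def test_phases_match_direct_recomputation(self, standard_population):
        ana = standard_population["analytic"]
        for i, p in enumerate(standard_population["params_list"]):
            lam = np.array(jacobian_eigenvalues(p))
            expected = np.exp(lam * ana.dt)
            expected /= np.abs(expected)
            assert np.allclose(np.angle(ana.discrete_phases[i]),
                               np.angle(expected))

    def test_requires_at_least_one_cell(self):
        with pytest.raises(ValueError):
            population_analytic_spectrum([], dt=1.0)
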