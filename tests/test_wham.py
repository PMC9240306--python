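"""Umbrella histograms, WHAM self-consistency, PMFs, binding free energy."""

import numpy as np
import pytest
from scipy.stats import norm

from membind.synthetic import AnalyticPMF, gen_umbrella_samples
from membind.units import KB, KCAL
from membind.wham import (Histograms, PMFProfile, UmbrellaWindow,
                          WhamConvergenceError, bias_potential,
                          binding_free_energy, build_histograms, compute_pmf,
                          pmf_from_probability, wham_solve, window_overlap)


class TestBiasPotential:
    def test_zero_at_center_and_closed_form(self):
        w = UmbrellaWindow(center=1.0, samples=[1.0], force_constant=1000.0)
        assert bias_potential(1.0, w) == 0.0
        assert bias_potential(1.1, w) == pytest.approx(5.0)

    def test_symmetry(self):
        w = UmbrellaWindow(center=0.7, samples=[0.7], force_constant=500.0)
        for d in (0.01, 0.1, 0.4):
            assert bias_potential(0.7 + d, w) == \
                pytest.approx(bias_potential(0.7 - d, w), rel=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, samples=[], force_constant=1000.0)
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, samples=[np.inf], force_constant=1000.0)
        with pytest.raises(ValueError):
            UmbrellaWindow(center=1.0, samples=[1.0], force_constant=0.0)


class TestHistograms:
    def test_counts_conserved_on_shared_grid(self):
        rng = np.random.default_rng(41)
        windows = [UmbrellaWindow(center=c, samples=rng.normal(c, 0.05, 1000))
                   for c in (0.5, 0.6)]
        hist = build_histograms(windows, bin_width=0.01)
        assert hist.counts.shape[0] == 2
        np.testing.assert_array_equal(hist.counts.sum(axis=1), [1000, 1000])

    def test_single_bin_for_constant_samples(self):
        w = UmbrellaWindow(center=1.0, samples=np.full(50, 1.0))
        hist = build_histograms([w], bin_width=0.02, xi_range=(0.9, 1.1))
        assert (hist.counts[0] > 0).sum() == 1

    def test_out_of_range_samples_reported_dropped(self):
        w = UmbrellaWindow(center=1.0, samples=[0.5, 1.0, 1.05, 9.0])
        hist = build_histograms([w], bin_width=0.02, xi_range=(0.9, 1.2))
        assert hist.n_dropped[0] == 2
        assert hist.counts[0].sum() == 2

    def test_moment_oracle(self):
        """Histogram mean/sd reproduce the sample moments to < 1e-3 nm."""
        rng = np.random.default_rng(42)
        samples = rng.normal(1.0, 0.05, 50000)
        w = UmbrellaWindow(center=1.0, samples=samples)
        hist = build_histograms([w], bin_width=0.002)
        p = hist.counts[0] / hist.counts[0].sum()
        mean = np.sum(p * hist.centers)
        sd = np.sqrt(np.sum(p * (hist.centers - mean) ** 2))
        assert mean == pytest.approx(samples.mean(), abs=1e-3)
        assert sd == pytest.approx(samples.std(), abs=1e-3)


class TestWindowOverlap:
    def test_identical_and_disjoint(self):
        counts = np.array([[10.0, 0.0], [10.0, 0.0]])
        h = Histograms(counts=counts, edges=np.array([0.0, 0.5, 1.0]),
                       n_dropped=np.zeros(2, int))
        assert window_overlap(h)[0] == pytest.approx(1.0)
        counts = np.array([[10.0, 0.0], [0.0, 10.0]])
        h = Histograms(counts=counts, edges=np.array([0.0, 0.5, 1.0]),
                       n_dropped=np.zeros(2, int))
        assert window_overlap(h)[0] == 0.0

    def test_two_gaussians_two_sd_apart(self):
        """Closed form: overlap of unit-variance normals 2 sd apart is
        2*Phi(-1) ~ 0.3173."""
        rng = np.random.default_rng(43)
        w1 = UmbrellaWindow(center=0.0, samples=rng.normal(0.0, 1.0, 200000))
        w2 = UmbrellaWindow(center=2.0, samples=rng.normal(2.0, 1.0, 200000))
        hist = build_histograms([w1, w2], bin_width=0.05)
        assert window_overlap(hist)[0] == pytest.approx(2 * norm.cdf(-1.0),
                                                        abs=0.01)


class TestWhamSolve:
    def test_single_window_no_bias_returns_histogram(self):
        rng = np.random.default_rng(44)
        w = UmbrellaWindow(center=1.0, samples=rng.uniform(0.5, 1.5, 20000),
                           force_constant=1e-9)
        hist = build_histograms([w], bin_width=0.05)
        p, F, info = wham_solve(hist, [w], temperature=300.0)
        np.testing.assert_allclose(p, hist.counts[0] / hist.counts[0].sum(),
                                   rtol=1e-6)
        assert F[0] == 0.0

    def test_two_identical_windows(self):
        rng = np.random.default_rng(45)
        samples = rng.normal(1.0, 0.05, 20000)
        windows = [UmbrellaWindow(center=1.0, samples=samples),
                   UmbrellaWindow(center=1.0, samples=samples)]
        hist = build_histograms(windows, bin_width=0.01)
        p, F, _ = wham_solve(hist, windows, temperature=300.0)
        single = build_histograms([windows[0]], bin_width=0.01)
        p1, _, _ = wham_solve(single, [windows[0]], temperature=300.0)
        assert F[1] == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(p, p1, atol=1e-8)

    def test_self_consistency_at_convergence(self):
        U = AnalyticPMF("harmonic", {"curvature": 100.0, "location": 1.0},
                        (0.5, 1.5))
        windows = gen_umbrella_samples(U, centers=np.linspace(0.7, 1.3, 5),
                                       n_per_window=5000, seed=46)
        hist = build_histograms(windows, bin_width=0.02)
        kT = KB * 300.0
        p, F, _ = wham_solve(hist, windows, temperature=300.0, tol=1e-10)
        bias = np.stack([bias_potential(hist.centers, w) for w in windows])
        N = hist.counts.sum(axis=1)
        denom = (N[:, None] * np.exp((F[:, None] - bias) / kT)).sum(axis=0)
        p_new = hist.counts.sum(axis=0) / denom
        p_new /= p_new.sum()
        np.testing.assert_allclose(p_new, p, rtol=1e-6)

    def test_window_permutation_invariance(self):
        U = AnalyticPMF("harmonic", {"curvature": 100.0, "location": 1.0},
                        (0.5, 1.5))
        windows = gen_umbrella_samples(U, centers=np.linspace(0.7, 1.3, 5),
                                       n_per_window=5000, seed=47)
        hist = build_histograms(windows, bin_width=0.02)
        p, _, _ = wham_solve(hist, windows, temperature=300.0)
        perm = [2, 0, 4, 1, 3]
        hist_p = Histograms(counts=hist.counts[perm], edges=hist.edges,
                            n_dropped=hist.n_dropped[perm])
        p2, _, _ = wham_solve(hist_p, [windows[i] for i in perm],
                              temperature=300.0)
        np.testing.assert_allclose(p, p2, rtol=1e-5)

    def test_disjoint_windows_raise_with_gap_location(self):
        w1 = UmbrellaWindow(center=0.5, samples=np.full(100, 0.5))
        w2 = UmbrellaWindow(center=2.0, samples=np.full(100, 2.0))
        hist = build_histograms([w1, w2], bin_width=0.02)
        with pytest.raises(ValueError, match="0.5.*2"):
            wham_solve(hist, [w1, w2], temperature=300.0)

    def test_nonconvergence_carries_residual(self):
        U = AnalyticPMF("harmonic", {"curvature": 200.0, "location": 1.0},
                        (0.5, 1.5))
        windows = gen_umbrella_samples(U, centers=np.linspace(0.7, 1.3, 5),
                                       n_per_window=2000, seed=48)
        hist = build_histograms(windows, bin_width=0.02)
        with pytest.raises(WhamConvergenceError) as err:
            wham_solve(hist, windows, temperature=300.0, tol=1e-12, max_iter=2)
        assert err.value.residual is not None
        assert err.value.n_iter == 2

    def test_low_overlap_warns(self):
        rng = np.random.default_rng(49)
        w1 = UmbrellaWindow(center=0.5, samples=rng.normal(0.5, 0.02, 5000))
        w2 = UmbrellaWindow(center=0.62, samples=rng.normal(0.62, 0.02, 5000))
        hist = build_histograms([w1, w2], bin_width=0.005)
        with pytest.warns(RuntimeWarning, match="overlap"):
            wham_solve(hist, [w1, w2], temperature=300.0)


class TestPmfFromProbability:
    def test_uniform_probability_is_flat_zero(self):
        grid = np.linspace(0, 1, 20)
        pmf = pmf_from_probability(np.full(20, 0.05), grid, 300.0)
        np.testing.assert_allclose(pmf.free_energy, 0.0, atol=1e-12)

    def test_log_identity_oracle(self):
        """p ~ exp(-U/kBT) gives back G = U up to a constant."""
        grid = np.linspace(0.5, 1.5, 60)
        U = 80.0 * (grid - 1.0) ** 2
        p = np.exp(-U / (KB * 300.0))
        p /= p.sum()
        pmf = pmf_from_probability(p, grid, 300.0,
                                   plateau_window=(0.5, 1.5))
        diff = pmf.free_energy - U
        assert np.ptp(diff) < 1e-6

    def test_scale_invariance_of_shape(self):
        grid = np.linspace(0, 1, 30)
        rng = np.random.default_rng(50)
        p = rng.uniform(0.1, 1.0, 30)
        g1 = pmf_from_probability(p / p.sum(), grid, 300.0).free_energy
        g2 = pmf_from_probability(2 * p / p.sum() / 2, grid, 300.0).free_energy
        np.testing.assert_allclose(g1, g2, atol=1e-10)

    def test_empty_bins_are_nan_not_interpolated(self):
        grid = np.linspace(0, 1, 10)
        p = np.array([0.2, 0.2, 0.0, 0.2, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05])
        pmf = pmf_from_probability(p, grid, 300.0)
        assert np.isnan(pmf.free_energy[2])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pmf_from_probability(np.zeros(5), np.linspace(0, 1, 5), 300.0)


class TestBindingFreeEnergy:
    def test_flat_pmf_zero(self):
        grid = np.linspace(0.5, 2.0, 50)
        pmf = PMFProfile(grid=grid, free_energy=np.zeros(50))
        assert binding_free_energy(pmf, (0.5, 1.0)) == 0.0

    def test_unit_conversion_square_well(self):
        """A 46.024 kJ/mol well reads out as exactly 11.0 kcal/mol."""
        grid = np.linspace(0.5, 2.0, 150)
        G = np.zeros(150)
        G[(grid > 0.8) & (grid < 1.2)] = -11.0 * KCAL
        pmf = PMFProfile(grid=grid, free_energy=G)
        assert binding_free_energy(pmf, (0.5, 1.5), (1.8, 2.0)) == \
            pytest.approx(11.0, abs=1e-9)
        assert 11.0 * KCAL == pytest.approx(46.024)

    def test_out_of_grid_ranges_rejected(self):
        grid = np.linspace(0.5, 2.0, 50)
        pmf = PMFProfile(grid=grid, free_energy=np.zeros(50))
        with pytest.raises(ValueError):
            binding_free_energy(pmf, (5.0, 6.0))


class TestAnalyticRecovery:
    def test_harmonic_pmf_recovered(self):
        """11 windows over a 1.2 nm path reproduce U = 200 (xi-1)^2 with
        RMSE < 0.3 kJ/mol on well-sampled bins."""
        U = AnalyticPMF("harmonic", {"curvature": 200.0, "location": 1.0},
                        (0.2, 2.0))
        windows = gen_umbrella_samples(U, centers=np.linspace(0.4, 1.6, 11),
                                       n_per_window=20000, seed=51)
        pmf = compute_pmf(windows, 300.0)
        mask = (pmf.counts >= 100) & np.isfinite(pmf.free_energy)
        diff = pmf.free_energy[mask] - U.energy(pmf.grid[mask])
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff ** 2)) < 0.3

    def test_double_well_recovered(self):
        U = AnalyticPMF("double_well",
                        {"depth1_kcal": 2.0, "loc1": 0.9, "width1": 0.1,
                         "depth2_kcal": 1.0, "loc2": 1.5, "width2": 0.12},
                        (0.6, 2.0))
        windows = gen_umbrella_samples(U, centers=np.linspace(0.7, 1.9, 11),
                                       n_per_window=20000, seed=52)
        pmf = compute_pmf(windows, 300.0)
        mask = (pmf.counts >= 100) & np.isfinite(pmf.free_energy)
        diff = pmf.free_energy[mask] - U.energy(pmf.grid[mask])
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff ** 2)) < 0.3

    def test_known_well_depth_recovered_in_kcal(self):
        """Samples from a 7.5 kcal/mol well give back 7.5 +/- 0.3."""
        U = AnalyticPMF("square_well",
                        {"depth_kcal": 7.5, "location": 1.0,
                         "half_width": 0.1, "softness": 0.15},
                        (0.7, 2.4))
        windows = gen_umbrella_samples(U, centers=np.linspace(1.0, 2.2, 11),
                                       n_per_window=20000, seed=53)
        pmf = compute_pmf(windows, 300.0, plateau_window=(2.0, 2.3))
        dg = binding_free_energy(pmf, (0.8, 1.4), (2.0, 2.3))
        assert dg == pytest.approx(7.5, abs=0.3)
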