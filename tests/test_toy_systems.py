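"""Unit tests for analytic surfaces, the bead peptide system, the
quadrature PMF oracle and the synthetic weighted-sample generator."""

import numpy as np
import pytest

import pepgamd as pg
from pepgamd.errors import InvalidParameterError


def _fd_gradient(surface, x, h=1e-6):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for d in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[d] += h
        xm[d] -= h
        g[d] = (surface.energy(xp) - surface.energy(xm)) / (2 * h)
    return g


class TestDoubleWell:
    def test_analytic_minima_and_barrier(self, double_well):
        a = 1.0  # separation 2 -> minima at +-1
        assert double_well.metadata["minima"] == [(-a,), (a,)]
        assert double_well.energy(np.array([0.0])) == pytest.approx(5.0)
        assert double_well.energy(np.array([1.0])) == pytest.approx(0.0)
        assert double_well.energy(np.array([-1.0])) == pytest.approx(0.0)

    def test_gradient_zero_at_minima(self, double_well):
        for m in double_well.metadata["minima"]:
            g = double_well.gradient(np.array(m))
            assert np.all(np.abs(g) < 1e-8)

    @pytest.mark.parametrize("bad", [(0.0, 2.0), (-1.0, 2.0), (5.0, 0.0)])
    def test_nonpositive_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            pg.make_double_well(*bad)

    def test_gradient_matches_finite_differences(self, double_well, rng):
        lo, hi = double_well.domain_bounds[0]
        for _ in range(25):
            x = np.array([rng.uniform(lo + 0.1, hi - 0.1)])
            g = double_well.gradient(x)
            fd = _fd_gradient(double_well, x)
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-6)


class TestThreeStateLandscape:
    def test_planted_positions_are_local_minima(self):
        # well-separated wells mimicking activation-distance minima
        minima = [(8.6, 8.0), (11.1, 4.0), (15.3, 5.0)]
        land = pg.make_three_state_landscape(minima, [4.0, 4.0, 4.0], [1.0, 1.0, 1.0])
        from scipy.optimize import minimize

        for m in minima:
            r = minimize(lambda p: land.energy(p), np.array(m), method="Nelder-Mead")
            assert np.linalg.norm(r.x - np.array(m)) < 0.1

    def test_single_minimum_rejected(self):
        with pytest.raises(InvalidParameterError):
            pg.make_three_state_landscape([(0.0, 0.0)], [1.0], [0.5])

    def test_overlapping_minima_rejected(self):
        with pytest.raises(InvalidParameterError):
            pg.make_three_state_landscape(
                [(0.0, 0.0), (1.0, 0.0)], [1.0, 1.0], [0.6, 0.6]
            )

    def test_deeper_basin_gains_occupancy(self):
        """Doubling the depths shifts Boltzmann weight toward the deepest
        basin (independent quadrature oracle in-test)."""
        minima = [(0.0, 0.0), (6.0, 0.0)]

        def occupancy_ratio(depths):
            land = pg.make_three_state_landscape(minima, depths, [0.8, 0.8])
            pts = land.grid(401)
            w = np.exp(-land.energy(pts))
            near0 = np.linalg.norm(pts - np.array(minima[0]), axis=1) < 2.0
            near1 = np.linalg.norm(pts - np.array(minima[1]), axis=1) < 2.0
            return w[near1].sum() / w[near0].sum()

        assert occupancy_ratio([2.0, 4.0]) < occupancy_ratio([4.0, 8.0])

    def test_gradient_matches_finite_differences(self, three_state_landscape, rng):
        bounds = three_state_landscape.domain_bounds
        for _ in range(25):
            x = np.array([rng.uniform(lo + 0.2, hi - 0.2) for lo, hi in bounds])
            g = three_state_landscape.gradient(x)
            fd = _fd_gradient(three_state_landscape, x)
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-6)


class TestToyPeptideSystem:
    def test_deterministic_construction(self):
        a = pg.make_toy_peptide_system(3, seed=1)
        b = pg.make_toy_peptide_system(3, seed=1)
        assert np.array_equal(a.peptide_coords, b.peptide_coords)
        assert np.array_equal(a.environment_coords, b.environment_coords)

    @pytest.mark.parametrize("n", [1, 0, 11, 25])
    def test_bead_count_out_of_range(self, n):
        with pytest.raises(InvalidParameterError):
            pg.make_toy_peptide_system(n, seed=1)

    def test_energy_decomposition_sums_exactly(self, peptide_system, rng):
        m0 = peptide_system.initial_mobile_coords()
        for _ in range(200):
            m = m0 + 0.5 * rng.standard_normal(m0.shape)
            comp = peptide_system.energy_components(m)
            total = peptide_system.total_energy(m)
            assert abs(total - sum(comp.values())) <= 1e-9 * max(abs(total), 1.0)

    def test_interaction_decays_at_infinity(self, peptide_system):
        m = peptide_system.initial_mobile_coords()
        m = m.copy()
        m[: peptide_system.n_peptide] += np.array([1e6, 0.0])
        comp = peptide_system.energy_components(m)
        assert abs(comp["V_PL_nb"]) < 1e-12

    def test_bound_pose_below_unbound_pose(self, peptide_system):
        """The attractive funnel makes the bound configuration lower in
        V_PL,nb than the same chain displaced out of the pocket."""
        bound = peptide_system.initial_mobile_coords().copy()
        unbound = bound.copy()
        unbound[: peptide_system.n_peptide] += np.array([3.0, 0.0])
        vb = peptide_system.energy_components(bound)["V_PL_nb"]
        vu = peptide_system.energy_components(unbound)["V_PL_nb"]
        assert vb < vu

    def test_split_forces_match_finite_differences(self, peptide_system, rng):
        m = peptide_system.initial_mobile_coords() + 0.1 * rng.standard_normal(
            (peptide_system.n_mobile, 2)
        )
        vL0, vD0, fL0, fD0 = peptide_system.energy_forces(m)
        h = 1e-6
        for i in range(peptide_system.n_mobile):
            for d in range(2):
                mp = m.copy()
                mp[i, d] += h
                vLp, vDp, _, _ = peptide_system.energy_forces(mp)
                assert -(vLp - vL0) / h == pytest.approx(fL0[i, d], abs=2e-3)
                assert -(vDp - vD0) / h == pytest.approx(fD0[i, d], abs=2e-3)


class TestAnalyticPmf:
    def test_harmonic_well_closed_form(self):
        kappa = 4.0
        surf = pg.PotentialSurface(
            dimensionality=1,
            energy=lambda p: 0.5 * kappa * np.asarray(p)[..., 0] ** 2,
            gradient=lambda p: (kappa * np.asarray(p)[..., 0])[..., None],
            domain_bounds=((-3.0, 3.0),),
            name="harmonic",
        )
        # bin width chosen so the bin-averaging bias (V' h)^2 / 24 stays
        # below the quadrature tolerance asserted here
        edges = np.arange(-2.0, 2.0001, 0.01)
        prof = pg.analytic_pmf(surf, 0, 1.0, edges, n_quad=4001)
        centers = prof.bin_centers[0]
        expected = 0.5 * kappa * centers**2
        expected -= expected.min()
        mask = prof.included
        assert np.max(np.abs(prof.f[mask] - expected[mask])) < 1e-3

    def test_symmetric_double_well_profile_symmetric(self, double_well):
        edges = np.arange(-2.0, 2.001, 0.1)
        prof = pg.analytic_pmf(double_well, 0, 1.0, edges)
        f = prof.f
        assert np.allclose(f, f[::-1], atol=1e-6, equal_nan=True)

    def test_basin_free_energies_match_occupancy_quadrature(
        self, three_state_landscape
    ):
        """Basin dF from the profile equals -ln of the quadrature occupancy
        ratio computed independently."""
        land = three_state_landscape
        edges = np.arange(5.0, 20.01, 0.5)
        prof = pg.analytic_pmf(land, 0, 1.0, edges, n_quad=501)
        pts = land.grid(501)
        w = np.exp(-land.energy(pts))
        c = prof.bin_centers[0]
        p = prof.probabilities()
        # occupancy of x-slabs around the outer wells, same bin edges
        for lo, hi in ((8.0, 9.0), (14.5, 16.0)):
            sel_bins = (c > lo) & (c < hi)
            sel_pts = (pts[:, 0] > lo) & (pts[:, 0] < hi)
            ratio_profile = np.nansum(p[sel_bins])
            ratio_quad = w[sel_pts].sum() / w.sum()
            assert ratio_profile == pytest.approx(ratio_quad, rel=0.05)

    def test_constant_shift_invariance(self, double_well):
        shifted = pg.PotentialSurface(
            dimensionality=1,
            energy=lambda p: double_well.energy(p) + 37.5,
            gradient=double_well.gradient,
            domain_bounds=double_well.domain_bounds,
            name="shifted",
        )
        edges = np.arange(-2.0, 2.001, 0.1)
        a = pg.analytic_pmf(double_well, 0, 1.0, edges)
        b = pg.analytic_pmf(shifted, 0, 1.0, edges)
        # tolerance reflects float rounding of (V + const) in deep tails
        assert np.allclose(a.f, b.f, atol=1e-6, equal_nan=True)

    def test_coarse_quadrature_rejected(self, double_well):
        with pytest.raises(InvalidParameterError):
            pg.analytic_pmf(
                double_well, lambda p: p[:, 0], 1.0, np.arange(-2, 2.1, 0.5), n_quad=50
            )


class TestSyntheticWeightedSamples:
    def test_constant_boost_cancels_in_reweighting(self):
        target = lambda a: 2.0 * (a**2 - 1.0) ** 2  # noqa: E731
        s = pg.synth_weighted_samples(
            target, pg.ConstantBoost(5.0), n=200_000, seed=3, domain=(-2, 2)
        )
        prof_w = pg.reweight_profile(s.coordinate_values, s.boost_values, 0.2, 500)
        prof_0 = pg.reweight_profile(
            s.coordinate_values, np.zeros(len(s.coordinate_values)), 0.2, 500
        )
        mask = prof_w.included & prof_0.included
        assert np.allclose(prof_w.f[mask], prof_0.f[mask], atol=1e-9)

    def test_gaussian_boost_recovers_target(self):
        target = lambda a: 2.0 * (a**2 - 1.0) ** 2  # noqa: E731
        s = pg.synth_weighted_samples(
            target, pg.GaussianBoost(mean=6.0, sd=2.0), n=500_000, seed=7,
            domain=(-2, 2),
        )
        prof = pg.reweight_profile(s.coordinate_values, s.boost_values, 0.2, 500)
        centers = prof.bin_centers[0]
        expected = target(centers)
        mask = prof.included
        # compare anchored profiles on included bins
        err = np.abs(
            (prof.f[mask] - prof.f[mask].min())
            - (expected[mask] - expected[mask].min())
        )
        assert err.max() <= 0.3

    def test_state_dependent_boost_recovers_target(self):
        target = lambda a: 0.5 * a**2  # noqa: E731
        boost = pg.StateDependentBoost(mean_fn=lambda a: 4.0 + 0.5 * np.abs(a), sd=1.0)
        s = pg.synth_weighted_samples(
            target, boost, n=400_000, seed=11, domain=(-4, 4)
        )
        prof = pg.reweight_profile(s.coordinate_values, s.boost_values, 0.25, 500)
        centers = prof.bin_centers[0]
        expected = target(centers)
        mask = prof.included
        err = np.abs(
            (prof.f[mask] - prof.f[mask].min())
            - (expected[mask] - expected[mask].min())
        )
        assert err.max() <= 0.3

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            pg.synth_weighted_samples(
                lambda a: a**2, pg.ConstantBoost(1.0), n=0, seed=1, domain=(-1, 1)
            )

    def test_boost_values_nonnegative_and_aligned(self):
        s = pg.synth_weighted_samples(
            lambda a: a**2, pg.GaussianBoost(2.0, 1.0), n=5000, seed=5, domain=(-3, 3)
        )
        assert len(s.coordinate_values) == len(s.boost_values)
        assert np.all(s.boost_values >= 0)
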