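"""Synthetic-data generation and the bivariate (c, d) profile likelihood."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from auxident import (NoiseSpec, SpaceTimeGrid, confidence_threshold,
                      gaussian_ic_coefficients, log_likelihood,
                      profile_coefficients, profile_surface, simulate_dataset)

PI2 = math.pi**2
TRUTH = (1.0, 0.05)


@pytest.fixture(scope="module")
def wide_dataset():
    ic = gaussian_ic_coefficients(0.3, N=8)
    return simulate_dataset(*TRUTH, ic, NoiseSpec(), seed=7)


@pytest.fixture(scope="module")
def narrow_dataset():
    ic = gaussian_ic_coefficients(0.1, N=8)
    return simulate_dataset(*TRUTH, ic, NoiseSpec(), seed=7)


class TestGaussianInitialCondition:
    def test_boundary_values_vanish(self):
        # zero up to float round-off of sin(nπ)
        for omega in (0.1, 0.2, 0.3):
            ic = gaussian_ic_coefficients(omega, N=8)
            assert abs(float(ic(0.0))) <= 1e-15
            assert abs(float(ic(1.0))) <= 1e-15

    def test_centre_normalization_within_truncation_error(self):
        for omega, tol in ((0.1, 0.02), (0.2, 0.01), (0.3, 0.005)):
            ic = gaussian_ic_coefficients(omega, N=8)
            assert float(ic(0.5)) == pytest.approx(1.0, abs=tol)

    def test_mode_content_grows_as_bump_narrows(self):
        """|C3/C1| decreases monotonically with ω: narrow bumps carry more
        of the higher modes."""
        ratios = []
        for omega in (0.1, 0.2, 0.3):
            C = gaussian_ic_coefficients(omega, N=8).coefficients
            ratios.append(abs(C[2] / C[0]))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_wide_bump_close_to_leading_eigenfunction(self):
        ic = gaussian_ic_coefficients(0.3, N=8)
        x = np.linspace(0, 1, 201)
        lead = ic.coefficients[0] * np.sin(math.pi * x)
        rel = np.linalg.norm(ic(x) - lead) / np.linalg.norm(ic(x))
        assert rel < 0.1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gaussian_ic_coefficients(-0.1)
        with pytest.raises(ValueError):
            gaussian_ic_coefficients(0.3, N=0)


class TestSimulation:
    def test_vanishing_noise_returns_clean_field(self):
        ic = gaussian_ic_coefficients(0.3)
        ds = simulate_dataset(*TRUTH, ic, NoiseSpec(sigma=1e-14), seed=3)
        assert np.max(np.abs(ds.observations - ds.clean)) < 1e-10

    def test_empirical_spatial_covariance_matches_kernel(self):
        """Monte-Carlo covariance of the noise at a fixed time slice
        reproduces σ² e^{-η|Δx|} within three standard errors."""
        ic = gaussian_ic_coefficients(0.3)
        noise = NoiseSpec(sigma=0.3, eta=10.0)
        n_rep = 4000
        eps = np.empty((n_rep, 11))
        for r in range(n_rep):
            ds = simulate_dataset(*TRUTH, ic, noise, seed=10_000 + r)
            eps[r] = ds.observations[5] - ds.clean[5]
        emp = np.cov(eps.T, bias=True)
        x = SpaceTimeGrid.observation().x
        target = noise.covariance(x)
        se = np.sqrt((np.outer(np.diag(target), np.diag(target))
                      + target**2) / n_rep)
        assert np.all(np.abs(emp - target) <= 3.5 * se + 1e-12)

    def test_noise_independent_across_time_slices(self):
        ic = gaussian_ic_coefficients(0.3)
        noise = NoiseSpec()
        n_rep = 2000
        a = np.empty(n_rep)
        b = np.empty(n_rep)
        for r in range(n_rep):
            ds = simulate_dataset(*TRUTH, ic, noise, seed=50_000 + r)
            e = ds.observations - ds.clean
            a[r], b[r] = e[3, 5], e[7, 5]
        cross = float(np.mean(a * b))
        se = noise.sigma**2 / math.sqrt(n_rep)
        assert abs(cross) <= 3.5 * se

    def test_seed_reproducibility(self):
        ic = gaussian_ic_coefficients(0.2)
        d1 = simulate_dataset(*TRUTH, ic, NoiseSpec(), seed=99)
        d2 = simulate_dataset(*TRUTH, ic, NoiseSpec(), seed=99)
        assert np.array_equal(d1.observations, d2.observations)


class TestLikelihood:
    def test_zero_residual_leaves_only_constant_term(self):
        ic = gaussian_ic_coefficients(0.3)
        ds = simulate_dataset(*TRUTH, ic, NoiseSpec(sigma=0.3), seed=1)
        ds.observations = ds.clean.copy()
        Sigma = ds.noise.covariance(ds.grid.x)
        expected = -0.5 * 21 * (11 * math.log(2 * math.pi)
                                + float(np.linalg.slogdet(Sigma)[1]))
        assert log_likelihood(ds, *TRUTH, ic.coefficients) \
            == pytest.approx(expected, rel=1e-12)

    def test_quadratic_scaling_of_residuals(self, wide_dataset):
        """Doubling the residuals subtracts three times the original
        quadratic-form contribution (4x - x = 3x)."""
        ds = wide_dataset
        ic = ds.ic
        ll1 = log_likelihood(ds, *TRUTH, ic.coefficients)
        const = log_likelihood(ds, *TRUTH, ic.coefficients) * 0  # placeholder
        # build a dataset whose residuals are doubled
        import copy
        ds2 = copy.copy(ds)
        ds2.observations = ds.clean + 2.0 * (ds.observations - ds.clean)
        ll2 = log_likelihood(ds2, *TRUTH, ic.coefficients)
        Sigma = ds.noise.covariance(ds.grid.x)
        const_term = -0.5 * 21 * (11 * math.log(2 * math.pi)
                                  + float(np.linalg.slogdet(Sigma)[1]))
        quad = const_term - ll1
        assert ll2 == pytest.approx(const_term - 4.0 * quad, rel=1e-10)

    def test_expected_quadratic_form_is_dimension(self):
        """At the true parameters the mean per-slice quadratic form equals
        the spatial dimension (chi-square mean), Monte-Carlo over seeds."""
        ic = gaussian_ic_coefficients(0.3)
        noise = NoiseSpec()
        Sigma = noise.covariance(SpaceTimeGrid.observation().x)
        const_term = -0.5 * (11 * math.log(2 * math.pi)
                             + float(np.linalg.slogdet(Sigma)[1]))
        n_rep = 200
        qf = np.empty(n_rep)
        for r in range(n_rep):
            ds = simulate_dataset(*TRUTH, ic, noise, seed=90_000 + r)
            ll = log_likelihood(ds, *TRUTH, ic.coefficients)
            qf[r] = -2.0 * (ll - 21 * const_term) / 21
        # var of chi2_11 is 22; SE of the mean over 200*21 slices
        assert float(np.mean(qf)) == pytest.approx(11.0, abs=0.35)


class TestProfiling:
    def test_zero_noise_recovers_truth_exactly(self):
        ic = gaussian_ic_coefficients(0.3)
        ds = simulate_dataset(*TRUTH, ic, NoiseSpec(sigma=1e-12), seed=5)
        coef, _ = profile_coefficients(ds, *TRUTH)
        assert np.max(np.abs(coef - ic.coefficients)) <= 1e-8

    def test_profile_dominates_fixed_coefficients(self, wide_dataset):
        _, ll_prof = profile_coefficients(wide_dataset, *TRUTH)
        ll_true = log_likelihood(wide_dataset, *TRUTH,
                                 wide_dataset.ic.coefficients)
        assert ll_prof >= ll_true

    def test_gls_matches_numerical_optimizer(self, wide_dataset):
        """The closed-form GLS profile coincides with quasi-Newton
        maximization from several seeded starts."""
        ds = wide_dataset
        coef, ll = profile_coefficients(ds, 1.2, 0.08)
        rng = np.random.default_rng(0)

        def neg_ll(C):
            return -log_likelihood(ds, 1.2, 0.08, C)

        best = None
        for _ in range(5):
            x0 = coef + rng.normal(0, 0.5, len(coef))
            res = minimize(neg_ll, x0, method="BFGS",
                           options={"gtol": 1e-10, "maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        assert np.max(np.abs(best.x - coef)) <= 1e-6
        assert -best.fun == pytest.approx(ll, abs=1e-8)

    def test_likelihood_ratio_threshold_value(self):
        # χ²₀.₉₅(2)/2 = -ln(0.05) = 2.99573..., conventionally quoted ≈ 2.997
        assert confidence_threshold(0.95, 2) == pytest.approx(2.9957, abs=1e-4)
        assert confidence_threshold(0.95, 2) == pytest.approx(2.997, abs=2e-3)


class TestSurfaceGeometry:
    C_GRID = np.linspace(0.0, 4.0, 21)
    D_GRID = np.geomspace(1e-3, 1.0, 21)

    def test_region_follows_indistinguishable_ridge(self, wide_dataset):
        """For the wide bump the 95% region tracks c - dπ² = const: at every
        d-grid value the ridge point stays inside the region."""
        surf = profile_surface(wide_dataset, self.C_GRID, self.D_GRID)
        _, ll_max = profile_coefficients(wide_dataset, *surf.mle)
        for dv in surf.d_grid:
            cv = TRUTH[0] + (dv - TRUTH[1]) * PI2
            if not (self.C_GRID[0] <= cv <= self.C_GRID[-1]):
                continue
            _, ll = profile_coefficients(wide_dataset, float(cv), float(dv))
            assert ll - ll_max >= -surf.threshold

    def test_ridge_flat_transversal_steep(self, wide_dataset, narrow_dataset):
        """The profiled loglik varies far less along c - dπ² = const than
        across it, for narrow and wide bumps alike."""
        for ds in (wide_dataset, narrow_dataset):
            _, ll0 = profile_coefficients(ds, *TRUTH)
            h = 0.05
            _, ll_r = profile_coefficients(ds, TRUTH[0] + h * PI2, TRUTH[1] + h)
            _, ll_t = profile_coefficients(ds, TRUTH[0] - h * PI2, TRUTH[1] + h)
            assert (ll0 - ll_r) < 0.2 * (ll0 - ll_t)

    def test_narrow_bump_bounds_diffusivity_below(self, wide_dataset,
                                                  narrow_dataset):
        """ω = 0.1 data yield a positive lower bound on d; ω = 0.3 data do
        not (the region reaches the smallest grid diffusivity), and the
        d-extent of the region is wider for the wide bump."""
        s_wide = profile_surface(wide_dataset, self.C_GRID, self.D_GRID)
        s_narrow = profile_surface(narrow_dataset, self.C_GRID, self.D_GRID)
        cols_wide = np.where(s_wide.mask.any(axis=0))[0]
        cols_narrow = np.where(s_narrow.mask.any(axis=0))[0]
        assert cols_wide[0] == 0                    # wide: unbounded below
        assert cols_narrow[0] > 0                   # narrow: bounded away from 0
        extent = lambda cols, d: math.log10(d[cols[-1]]) - math.log10(d[cols[0]])
        assert extent(cols_wide, s_wide.d_grid) \
            > extent(cols_narrow, s_narrow.d_grid)

    def test_small_noise_shrinks_region_to_ridge(self):
        ic = gaussian_ic_coefficients(0.3)
        ds = simulate_dataset(*TRUTH, ic, NoiseSpec(sigma=0.01), seed=7)
        surf = profile_surface(ds, self.C_GRID, self.D_GRID)
        mu_star = TRUTH[0] - TRUTH[1] * PI2
        cc, dd = np.meshgrid(surf.c_grid, surf.d_grid, indexing="ij")
        mu = cc - dd * PI2
        assert np.max(np.abs(mu[surf.mask] - mu_star)) < 0.2

    def test_coverage_of_truth(self):
        """Across 20 seeds the 95% region contains the truth at a rate
        consistent with >= 90% coverage.

        The acceptance bound allows one-sided binomial sampling error at
        this replicate count: observing >= 16/20 hits is required (the 5%
        critical region for a true coverage of 0.90 starts at 15).
        """
        ic = gaussian_ic_coefficients(0.1, N=8)
        hits = 0
        n_rep = 20
        for r in range(n_rep):
            ds = simulate_dataset(*TRUTH, ic, NoiseSpec(), seed=300 + r)
            surf = profile_surface(ds, self.C_GRID, self.D_GRID)
            _, ll_max = profile_coefficients(ds, *surf.mle)
            _, ll_truth = profile_coefficients(ds, *TRUTH)
            if ll_truth - ll_max >= -surf.threshold:
                hits += 1
        assert hits >= 16
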