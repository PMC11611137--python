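"""Mean/SD sampling density: moments, pooling, Fourier pipeline, surfaces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import lognorm

from aawt.summary_likelihood import (
    JointDensityGrid,
    MeanSdFamily,
    QuadratureSpec,
    SummaryStatStudy,
    joint_mean_sd_density,
    loglik_surface,
    lognormal_mom,
    pool_subset_stats,
)


class TestLognormalMoM:
    def test_worked_examples(self):
        mu, sig = lognormal_mom(2.71, 0.83)
        assert (round(mu, 2), round(sig, 2)) == (0.95, 0.30)
        mu, sig = lognormal_mom(2.56, 0.59)
        assert (round(mu, 2), round(sig, 2)) == (0.91, 0.23)

    def test_degenerate_sd(self):
        assert lognormal_mom(math.e, 0.0) == (1.0, 0.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lognormal_mom(0.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_mom(1.0, -0.1)

    @given(
        mu=st.floats(-1.0, 2.0),
        sigma=st.floats(0.01, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_inverts_lognormal_moments(self, mu, sigma):
        # analytic round trip: the MoM estimator applied to the exact
        # lognormal mean/SD recovers the parameters
        mean = math.exp(mu + sigma**2 / 2)
        sd = mean * math.sqrt(math.expm1(sigma**2))
        mu_hat, sig_hat = lognormal_mom(mean, sd)
        assert mu_hat == pytest.approx(mu, abs=1e-9)
        assert sig_hat == pytest.approx(sigma, abs=1e-9)


class TestPooling:
    def test_identical_subsets(self):
        s = SummaryStatStudy(2.5, 0.4, 30, "x")
        pooled = pool_subset_stats([s, s])
        assert pooled.N == 60
        assert pooled.M == pytest.approx(2.5)
        # under the n-1 convention the pooled SD of duplicated data carries
        # the exact (2N-2)/(2N-1) factor
        assert pooled.S == pytest.approx(0.4 * math.sqrt(58 / 59), rel=1e-12)

    def test_two_degenerate_subsets(self):
        a = SummaryStatStudy(1.0, 0.0, 2, "a")
        b = SummaryStatStudy(3.0, 0.0, 2, "b")
        pooled = pool_subset_stats([a, b])
        assert pooled.M == pytest.approx(2.0)
        assert pooled.S == pytest.approx(math.sqrt(4.0 / 3.0))
        assert pooled.N == 4

    def test_against_raw_concatenation(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0.9, 0.3, 57)
        y = rng.lognormal(0.7, 0.5, 83)
        subsets = [
            SummaryStatStudy(x.mean(), x.std(ddof=1), x.size, "x"),
            SummaryStatStudy(y.mean(), y.std(ddof=1), y.size, "y"),
        ]
        pooled = pool_subset_stats(subsets)
        z = np.concatenate([x, y])
        assert pooled.M == pytest.approx(z.mean(), rel=1e-12)
        assert pooled.S == pytest.approx(z.std(ddof=1), rel=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_subset_stats([])


class TestJointMeanSdDensity:
    def test_normalizes_to_one(self):
        d = joint_mean_sd_density(0.9, 0.3, 34)
        assert d.mass == pytest.approx(1.0, abs=0.01)
        # direct integration over (M, S)
        m_lo, m_hi, _, s_hi = d.support_box()
        mg = np.linspace(m_lo, m_hi, 250)
        sg = np.linspace(1e-9, s_hi, 250)
        MM, SS = np.meshgrid(mg, sg, indexing="ij")
        mass = np.trapezoid(np.trapezoid(d.pdf(MM, SS), sg, axis=1), mg)
        assert mass == pytest.approx(1.0, abs=0.01)

    def test_mean_of_means(self):
        mu, sigma, N = 0.9, 0.3, 34
        d = joint_mean_sd_density(mu, sigma, N)
        m_lo, m_hi, _, s_hi = d.support_box()
        mg = np.linspace(m_lo, m_hi, 300)
        sg = np.linspace(1e-9, s_hi, 300)
        MM, SS = np.meshgrid(mg, sg, indexing="ij")
        F = d.pdf(MM, SS)
        e_m = np.trapezoid(np.trapezoid(F * MM, sg, axis=1), mg)
        assert e_m == pytest.approx(math.exp(mu + sigma**2 / 2), rel=0.01)

    def test_marginal_of_mean_against_mc(self):
        # integrating the joint density over S recovers the density of the
        # mean of N lognormals (change-of-variables correctness)
        mu, sigma, N = 0.8, 0.25, 20
        d = joint_mean_sd_density(mu, sigma, N)
        rng = np.random.default_rng(3)
        M = rng.lognormal(mu, sigma, size=(400_000, N)).mean(axis=1)
        hist, edges = np.histogram(M, bins=40, range=(np.quantile(M, 0.002), np.quantile(M, 0.998)), density=True)
        hist = hist * np.mean((M >= edges[0]) & (M <= edges[-1]))
        centers = 0.5 * (edges[:-1] + edges[1:])
        _, _, _, s_hi = d.support_box()
        sg = np.linspace(1e-9, s_hi, 400)
        marg = np.array([np.trapezoid(d.pdf(np.full_like(sg, m), sg), sg) for m in centers])
        bulk = hist > 0.2 * hist.max()
        rel = np.abs(marg[bulk] - hist[bulk]) / hist[bulk]
        assert rel.max() < 0.06

    def test_variance_of_mean_scales_as_1_over_n(self):
        mu, sigma = 0.85, 0.3
        varM = []
        for N in (10, 40, 160):
            d = joint_mean_sd_density(mu, sigma, N)
            m_lo, m_hi, _, s_hi = d.support_box()
            mg = np.linspace(m_lo, m_hi, 400)
            sg = np.linspace(1e-9, s_hi, 300)
            MM, SS = np.meshgrid(mg, sg, indexing="ij")
            F = d.pdf(MM, SS)
            mass = np.trapezoid(np.trapezoid(F, sg, axis=1), mg)
            e1 = np.trapezoid(np.trapezoid(F * MM, sg, axis=1), mg) / mass
            e2 = np.trapezoid(np.trapezoid(F * MM**2, sg, axis=1), mg) / mass
            varM.append(e2 - e1**2)
        assert varM[0] / varM[1] == pytest.approx(4.0, rel=0.1)
        assert varM[1] / varM[2] == pytest.approx(4.0, rel=0.1)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            joint_mean_sd_density(0.9, 0.0, 34)
        with pytest.raises(ValueError):
            joint_mean_sd_density(0.9, 0.3, 1)

    def test_quadrature_failure_reports_mass(self):
        # sigma far beyond the validated transform domain
        with pytest.raises(RuntimeError, match="mass"):
            joint_mean_sd_density(0.9, 1.4, 34, QuadratureSpec())


@pytest.fixture(scope="module")
def grids():
    study_a = SummaryStatStudy(2.71, 0.83, 34, "summary-A")
    study_b = SummaryStatStudy(2.56, 0.59, 90, "summary-B")
    kw = dict(n_mu=100, n_sigma=100)
    return (
        loglik_surface(study_a, (0.6, 1.3), (0.12, 0.6), **kw),
        loglik_surface(study_b, (0.6, 1.3), (0.12, 0.6), **kw),
    )


class TestLoglikSurface:

    def test_argmax_near_mom(self, grids):
        for grid in grids:
            mu_hat, sig_hat = grid.argmax()
            mu_mom, sig_mom = lognormal_mom(grid.study.M, grid.study.S)
            dmu, dsig = grid.grid_steps()
            assert abs(mu_hat - mu_mom) <= dmu
            assert abs(sig_hat - sig_mom) <= dsig

    def test_larger_study_more_concentrated(self, grids):
        study_a, study_b = grids
        assert study_b.concentration_area(2.0) < study_a.concentration_area(2.0)

    def test_curvature_grows_with_n(self):
        # Fisher-information scaling: doubling N sharpens the surface
        a = loglik_surface(SummaryStatStudy(2.7, 0.8, 30, "n30"), (0.7, 1.2), (0.15, 0.5), n_mu=40, n_sigma=40)
        b = loglik_surface(SummaryStatStudy(2.7, 0.8, 60, "n60"), (0.7, 1.2), (0.15, 0.5), n_mu=40, n_sigma=40)
        for grid, scale in ((a, 1.0), (b, 2.0)):
            i, j = np.unravel_index(np.argmax(grid.log_density), grid.log_density.shape)
            grid._curv = -(grid.log_density[i + 1, j] - 2 * grid.log_density[i, j] + grid.log_density[i - 1, j])
        assert b._curv > 1.5 * a._curv

    def test_boundary_argmax_warns(self):
        with pytest.warns(UserWarning, match="boundary"):
            loglik_surface(
                SummaryStatStudy(2.71, 0.83, 34, "narrow"),
                (0.2, 0.5),  # excludes the MoM estimate ~0.95
                (0.15, 0.5),
                n_mu=25,
                n_sigma=25,
            )

    def test_interpolant_consistency_off_grid(self, grids):
        # bicubic surface vs direct density evaluation at random (mu, sigma)
        grid = grids[0]
        family = MeanSdFamily(grid.study.N)
        rng = np.random.default_rng(8)
        checked = 0
        for _ in range(50):
            mu = rng.uniform(0.8, 1.1)
            sig = rng.uniform(0.2, 0.45)
            direct = float(family.logpdf(np.array(grid.study.M), np.array(grid.study.S), mu=mu, sigma=sig))
            interp = float(grid(mu, sig))
            if direct > grid.log_density.max() - 12:
                # relative density error < 1% <-> log difference < 0.01
                assert abs(interp - direct) < 0.01
                checked += 1
        assert checked >= 25

    def test_serialization_round_trip(self, grids, tmp_path):
        grid = grids[1]
        path = tmp_path / "grid.json"
        grid.save(path)
        loaded = JointDensityGrid.load(path)
        assert np.allclose(loaded.log_density, grid.log_density)
        assert loaded(0.9, 0.25) == pytest.approx(grid(0.9, 0.25), abs=1e-9)


def test_study_validation():
    with pytest.raises(ValueError):
        SummaryStatStudy(-1.0, 0.5, 10)
    with pytest.raises(ValueError):
        SummaryStatStudy(1.0, -0.5, 10)
    with pytest.raises(ValueError):
        SummaryStatStudy(1.0, 0.5, 1)
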