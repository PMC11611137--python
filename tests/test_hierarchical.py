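"""Hierarchical model: likelihood oracles, sampling, diagnostics."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from aawt.constitutive import HGOParams, invert_pressure
from aawt.hierarchical import (
    Model,
    PopulationParams,
    PosteriorDraws,
    PriorSpec,
    ThicknessSample,
    build_model,
    diagnostics,
    posterior_summary,
    sample_posterior,
)
from aawt.synthetic import CohortDesign, StudyDesign, generate_cohort

from conftest import TRUTH


def make_samples(values, pressures=None, patients=None, study="s"):
    pressures = pressures or [0.0] * len(values)
    patients = patients or [f"p{i}" for i in range(len(values))]
    return [
        ThicknessSample(study, pid, f"{pid}-{j}", t=v, p=pr)
        for j, (v, pr, pid) in enumerate(zip(values, pressures, patients))
    ]


class TestBuildModel:
    def test_degenerate_design_collapses_to_iid_lognormal(self, surface):
        # all pressures 0, one sample per patient: the marginal likelihood
        # is that of iid LN(mu_pop, sqrt(sigma_pop^2 + sigma_pat^2))
        t = np.array([1.9, 2.3, 2.8, 2.1, 2.6])
        model = build_model(make_samples(t), [], surface)
        theta = np.array([3.0, 10.0, 0.8, 0.2, 0.15])
        sig = math.hypot(0.2, 0.15)
        expected = stats.lognorm(s=sig, scale=math.exp(0.8)).logpdf(t).sum()
        assert model.log_marginal_raw(theta) == pytest.approx(expected, rel=1e-10)

    def test_map_of_mu_pop_is_mean_log_thickness(self, surface):
        t = np.array([1.9, 2.3, 2.8, 2.1, 2.6])
        model = build_model(make_samples(t), [], surface)
        target = np.log(t).mean()
        base = np.array([3.0, 10.0, target, 0.2, 0.15])
        best = model.log_marginal_raw(base)
        for d in (-0.05, -0.01, 0.01, 0.05):
            theta = base.copy()
            theta[2] += d
            assert model.log_marginal_raw(theta) < best

    def test_hand_computed_joint_log_density(self, surface):
        # 3-sample toy data: two samples from patient A (one at pressure),
        # one from patient B; fixed parameters and patient means
        c, k, mu_pop, s_pop, s_pat = 5.0, 20.0, 0.9, 0.25, 0.15
        lam16 = float(surface(c, k, 16.0))
        samples = [
            ThicknessSample("s", "A", "a1", t=2.2, p=0.0),
            ThicknessSample("s", "A", "a2", t=1.7, p=16.0),
            ThicknessSample("s", "B", "b1", t=2.9, p=0.0),
        ]
        model = build_model(samples, [], surface)
        mu = {"A": 0.82, "B": 1.0}
        mu_vec = np.array([mu[key[1]] for key in model.patient_keys])
        expected = 0.0
        for m_i in mu.values():
            expected += stats.norm(mu_pop, s_pop).logpdf(m_i)
        expected += stats.lognorm(s=s_pat, scale=math.exp(mu["A"])).logpdf(2.2)
        expected += stats.lognorm(s=s_pat, scale=math.exp(mu["A"] + math.log(lam16))).logpdf(1.7)
        expected += stats.lognorm(s=s_pat, scale=math.exp(mu["B"])).logpdf(2.9)
        got = model.log_joint(np.array([c, k, mu_pop, s_pop, s_pat]), mu_vec)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_marginal_equals_integrated_joint(self, surface):
        # quadrature over the two patient means reproduces the analytic
        # compound-symmetric marginal
        samples = [
            ThicknessSample("s", "A", "a1", t=2.2, p=0.0),
            ThicknessSample("s", "A", "a2", t=2.6, p=0.0),
            ThicknessSample("s", "B", "b1", t=1.8, p=16.0),
        ]
        model = build_model(samples, [], surface)
        theta = np.array([4.0, 15.0, 0.85, 0.3, 0.2])

        def joint(mu_a, mu_b):
            order = [k[1] for k in model.patient_keys]
            vec = np.array([mu_a if pid == "A" else mu_b for pid in order])
            return math.exp(model.log_joint(theta, vec))

        val, _ = integrate.dblquad(joint, 0.0, 1.8, 0.0, 1.8, epsabs=1e-12)
        assert math.log(val) == pytest.approx(model.log_marginal_raw(theta), abs=1e-5)

    def test_sigma_pat_zero_limit(self, surface):
        # replicate samples at equal pressure: agreeing data stay finite,
        # disagreeing data are crushed as sigma_pat -> 0
        agree = make_samples([2.0, 2.0], patients=["A", "A"])
        differ = make_samples([2.0, 2.4], patients=["A", "A"])
        theta = np.array([3.0, 10.0, math.log(2.0), 0.2, 1e-7])
        m_agree = build_model(agree, [], surface)
        m_differ = build_model(differ, [], surface)
        assert m_agree.log_marginal_raw(theta) > -100
        assert m_differ.log_marginal_raw(theta) < -1e6

    def test_uncovered_pressure_rejected(self, surface):
        with pytest.raises(ValueError, match="pressure"):
            build_model(make_samples([2.0], pressures=[80.0]), [], surface)


class TestSampling:
    def test_same_seed_reproduces_draws(self, surface):
        t = np.exp(np.random.default_rng(0).normal(0.85, 0.3, 25))
        model = build_model(make_samples(list(t)), [], surface)
        a = sample_posterior(model, chains=2, draws=200, warmup=100, thin=2, seed=7)
        b = sample_posterior(model, chains=2, draws=200, warmup=100, thin=2, seed=7)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.mu_patient, b.mu_patient)

    def test_prior_recovery_without_data(self, surface):
        # no data: the posterior must reproduce the uniform priors.  Many
        # independent chains with a few widely separated ensemble steps give
        # effectively independent draws, so the KS test is valid.
        model = build_model([], [], surface)
        post = sample_posterior(
            model, chains=12, draws=64, warmup=300, thin=150, seed=5,
            recover_patient_means=False, rhat_threshold=2.0,
        )
        bounds = PriorSpec().bounds()
        for i, name in enumerate(post.param_names):
            x = post.flat(name)
            u = (x - bounds[i, 0]) / (bounds[i, 1] - bounds[i, 0])
            stat = stats.kstest(u, "uniform").pvalue
            assert stat > 0.01, f"{name} failed prior recovery (p={stat:.4f})"

    def test_posterior_recovers_truth(self, six_fit):
        for name, truth in TRUTH.items():
            med, (lo, hi) = posterior_summary(six_fit, name)
            assert lo <= truth <= hi, f"{name}: truth {truth} outside [{lo:.3f}, {hi:.3f}]"
        # the well-identified population parameters are also close
        for name in ("mu_pop", "sigma_pop", "sigma_pat"):
            med, _ = posterior_summary(six_fit, name)
            assert med == pytest.approx(TRUTH[name], rel=0.15)

    def test_variance_decomposition_identifiability(self, surface, six_fit):
        # with replicates: both components separately constrained
        _, (lo_pop, hi_pop) = posterior_summary(six_fit, "sigma_pop")
        _, (lo_pat, hi_pat) = posterior_summary(six_fit, "sigma_pat")
        assert hi_pop - lo_pop < 0.35
        assert hi_pat - lo_pat < 0.2
        assert lo_pop > 0.05 and lo_pat > 0.05

        # singletons only: the total sqrt(s_pop^2 + s_pat^2) is pinned while
        # the individual components ride a prior-wide ridge
        design = CohortDesign(
            studies=(StudyDesign("singleton", 0.0, 220, 220),),
            material=HGOParams(**{k: TRUTH[k] for k in ("c", "k")}),
            population=PopulationParams(0.85, 0.26, 0.18),
            seed=2,
        )
        samples, _, _ = generate_cohort(design)
        model = build_model(samples, [], surface)
        post = sample_posterior(model, chains=2, draws=2000, warmup=600, thin=4,
                                seed=9, recover_patient_means=False,
                                rhat_threshold=1.05)
        tot = np.hypot(post.flat("sigma_pop"), post.flat("sigma_pat"))
        sig_truth = math.hypot(0.26, 0.18)
        assert np.quantile(tot, 0.975) - np.quantile(tot, 0.025) < 0.12
        assert np.quantile(tot, 0.025) < sig_truth < np.quantile(tot, 0.975)
        _, (lo, hi) = posterior_summary(post, "sigma_pop")
        assert hi - lo > 0.25  # ridge: individual component unidentified

    def test_summary_studies_add_information(self, six_model, six_cohort, six_fit, surface):
        samples, summaries, _ = six_cohort
        model_wo = build_model(samples, [], surface)
        post_wo = sample_posterior(model_wo, chains=2, draws=2000, seed=4,
                                   recover_patient_means=False,
                                   rhat_threshold=1.05)
        _, (lo_full, hi_full) = posterior_summary(six_fit, "mu_pop")
        _, (lo_wo, hi_wo) = posterior_summary(post_wo, "mu_pop")
        assert (hi_wo - lo_wo) > (hi_full - lo_full)

    def test_prior_robustness_of_predictive(self, six_cohort, six_fit, surface):
        # refitting under a different (still covering) prior family leaves
        # the predictive undeformed-thickness distribution unchanged
        from aawt.predictive import fit_lognormal_approx, posterior_predictive

        samples, summaries, _ = six_cohort
        alt = PriorSpec(c=(0.0, 8.0), k=(0.0, 30.0), mu_pop=(0.3, 1.5),
                        sigma_pop=(0.0, 0.8), sigma_pat=(0.0, 0.8))
        model = build_model(samples, summaries, surface, priors=alt)
        post = sample_posterior(model, chains=2, draws=2000, seed=6,
                                recover_patient_means=False,
                                rhat_threshold=1.05)
        mu_a, sig_a = fit_lognormal_approx(posterior_predictive(six_fit, 50_000, seed=1))
        mu_b, sig_b = fit_lognormal_approx(posterior_predictive(post, 50_000, seed=1))
        assert abs(mu_a - mu_b) < 0.03
        assert abs(sig_a - sig_b) < 0.03

    def test_invalid_config(self, surface):
        model = build_model([], [], surface)
        with pytest.raises(ValueError):
            sample_posterior(model, chains=0, draws=100)


class TestDiagnostics:
    def _draws(self, arr):
        return PosteriorDraws(theta=arr)

    def test_copied_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        one = rng.standard_normal((1, 4000, 5))
        rep = diagnostics(self._draws(np.repeat(one, 4, axis=0)))
        assert rep["max_rhat"] == pytest.approx(1.0, abs=0.01)

    def test_iid_chains_ess_near_total(self):
        rng = np.random.default_rng(1)
        draws = self._draws(rng.standard_normal((4, 2500, 5)))
        rep = diagnostics(draws)
        total = 4 * 2500
        for v in rep["ess"].values():
            assert v == pytest.approx(total, rel=0.2)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((4, 2000, 5))
        arr[0] += 1.0  # injected mean shift
        rep = diagnostics(self._draws(arr))
        assert rep["max_rhat"] > 1.01

    def test_single_chain_reported_undefined(self):
        rep = diagnostics(self._draws(np.zeros((1, 100, 5))))
        assert math.isnan(rep["max_rhat"])
        assert "undefined" in rep["note"]


class TestPosteriorSummary:
    def test_constant_draws(self):
        draws = PosteriorDraws(theta=np.full((2, 100, 5), 3.3))
        med, (lo, hi) = posterior_summary(draws, "c")
        assert med == lo == hi == 3.3

    def test_uniform_draws_analytic_quantiles(self):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 1, size=(1, 1_000_000, 5))
        med, (lo, hi) = posterior_summary(PosteriorDraws(theta=arr), "k")
        assert med == pytest.approx(0.5, abs=0.002)
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)


def test_sample_validation():
    with pytest.raises(ValueError):
        ThicknessSample("s", "p", "x", t=-1.0, p=0.0)
    with pytest.raises(ValueError):
        ThicknessSample("s", "p", "x", t=1.0, p=-2.0)
    with pytest.raises(ValueError):
        PopulationParams(0.8, -0.1, 0.1)
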