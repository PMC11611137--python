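"""Hierarchical Bayesian model of multi-study wall-thickness data.

Generative model: patient i has a latent mean log-thickness
mu_i ~ N(mu_pop, sigma_pop); sample j of patient i has undeformed thickness
T_ij ~ LN(mu_i, sigma_pat); the measured (deformed) thickness is
t_ij = lambda_r(c, k, p_ij) * T_ij, with lambda_r the radial compression
emulated by the response surface (lambda_r = 1 at zero contact pressure).
Studies available only as summary statistics (M_k, S_k, N_k) of undeformed
thickness enter through the exact sampling density of the mean and SD of
N_k iid LN(mu_pop, sigma) variables with sigma = sqrt(sigma_pop^2 +
sigma_pat^2) (each summary sample treated as its own patient).

Five free parameters: c, k [kPa], mu_pop, sigma_pop, sigma_pat (log-mm
scale), with independent uniform priors on configurable boxes.

Sampling: the latent mu_i are marginalized analytically -- given the
parameters, the vector of log deformed thicknesses of a patient is
multivariate normal with compound-symmetric covariance sigma_pat^2 I +
sigma_pop^2 J -- so the posterior is 5-dimensional and is explored with
emcee's affine-invariant ensemble sampler, several independent ensembles
serving as chains for R-hat/ESS.  Patient means are recovered exactly
afterwards from their conjugate normal conditional, one draw per retained
posterior draw.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

import arviz as az
import emcee

from .constitutive import ResponseSurface
from .summary_likelihood import (
    JointDensityGrid,
    QuadratureSpec,
    SummaryStatStudy,
    loglik_surface,
)

__all__ = [
    "ThicknessSample",
    "PopulationParams",
    "PriorSpec",
    "Model",
    "PosteriorDraws",
    "build_model",
    "sample_posterior",
    "diagnostics",
    "posterior_summary",
]

PARAM_NAMES = ("c", "k", "mu_pop", "sigma_pop", "sigma_pat")


@dataclass(frozen=True)
class ThicknessSample:
    """One measured (deformed) wall thickness with its provenance."""

    study_id: str
    patient_id: str
    sample_id: str
    t: float  # measured deformed thickness [mm]
    p: float  # contact pressure [kPa]

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("thickness must be positive")
        if self.p < 0:
            raise ValueError("contact pressure must be non-negative")


@dataclass(frozen=True)
class PopulationParams:
    """Population-level log-thickness parameters."""

    mu_pop: float
    sigma_pop: float
    sigma_pat: float

    def __post_init__(self) -> None:
        if self.sigma_pop < 0 or self.sigma_pat < 0:
            raise ValueError("variability parameters must be non-negative")

    @property
    def sigma_marginal(self) -> float:
        """Scale of the marginal lognormal distribution of one sample."""
        return math.hypot(self.sigma_pop, self.sigma_pat)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior boxes for the five parameters."""

    c: tuple[float, float] = (0.0, 10.0)
    k: tuple[float, float] = (0.0, 40.0)
    mu_pop: tuple[float, float] = (0.0, 2.0)
    sigma_pop: tuple[float, float] = (0.0, 1.0)
    sigma_pat: tuple[float, float] = (0.0, 1.0)

    def bounds(self) -> np.ndarray:
        return np.array([self.c, self.k, self.mu_pop, self.sigma_pop, self.sigma_pat])


class Model:
    """Joint posterior of (c, k, mu_pop, sigma_pop, sigma_pat).

    Holds the grouped raw data, the response surface, the per-summary-study
    bicubic log-likelihood interpolants, and the prior box.
    """

    #: floor applied to sigma parameters inside the marginal likelihood
    SIGMA_EPS = 1e-6

    def __init__(
        self,
        samples: Sequence[ThicknessSample],
        summaries: Sequence[SummaryStatStudy],
        surface: ResponseSurface,
        priors: PriorSpec | None = None,
        summary_grids: Sequence[JointDensityGrid] | None = None,
        quadrature: QuadratureSpec | None = None,
        sigma_grid_min: float = 0.06,
        sigma_grid_max: float = 0.85,
    ) -> None:
        self.samples = list(samples)
        self.summaries = list(summaries)
        self.surface = surface
        self.priors = priors or PriorSpec()

        pressures = sorted({s.p for s in self.samples})
        for p in pressures:
            if p > float(np.max(surface.pressures)):
                raise ValueError(
                    f"dataset pressure {p} kPa not covered by the response "
                    f"surface (built for {list(surface.pressures)})"
                )
        self.pressures = np.array(pressures)

        # group samples by (study, patient); store per-sample pressure index
        keys = [(s.study_id, s.patient_id) for s in self.samples]
        uniq = sorted(set(keys))
        self.patient_keys = uniq
        idx = {kk: i for i, kk in enumerate(uniq)}
        self._pat_idx = np.array([idx[kk] for kk in keys], dtype=int)
        self._logt = np.array([math.log(s.t) for s in self.samples])
        pidx = {p: i for i, p in enumerate(pressures)}
        self._press_idx = np.array([pidx[s.p] for s in self.samples], dtype=int)
        self.n_patients = len(uniq)
        self._n_i = np.bincount(self._pat_idx, minlength=self.n_patients).astype(float)

        # summary-study likelihood: precomputed bicubic interpolants of
        # log f_k(M_k, S_k; mu_pop, sigma) over the prior box
        if summary_grids is not None:
            if len(summary_grids) != len(self.summaries):
                raise ValueError("one summary grid per summary study required")
            self.summary_grids = list(summary_grids)
        else:
            # grid over the prior's mu range and the validated sigma domain
            # of the Fourier transform; sigma outside is clamped with a
            # smooth penalty in log_summary (that region sits hundreds of
            # nats below the posterior bulk and only needs a gradient)
            lo_mu, hi_mu = self.priors.mu_pop
            self.summary_grids = []
            for st in self.summaries:
                grid = loglik_surface(
                    st,
                    (lo_mu, hi_mu),
                    (sigma_grid_min, sigma_grid_max),
                    n_sigma=80,
                    quadrature=quadrature,
                    warn_boundary=False,
                    sigma_spacing="log",
                )
                # clamp the tabulated log-likelihood to a 60-nat range below
                # its maximum before splining: a 60-nat deficit is already
                # decisive, and bounding the step height keeps the bicubic
                # surface free of overshoot spikes at the cliff between the
                # valid region and the far-tail floor
                clamped = np.maximum(
                    grid.log_density, grid.log_density.max() - 60.0
                )
                self.summary_grids.append(
                    JointDensityGrid(st, grid.mu_grid, grid.sigma_grid, clamped)
                )
        self._sigma_grid_min = sigma_grid_min
        self._sigma_grid_max = sigma_grid_max

    # -- log densities ----------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> float:
        b = self.priors.bounds()
        if np.any(theta < b[:, 0]) or np.any(theta > b[:, 1]):
            return -np.inf
        return 0.0  # proper uniform; constant omitted

    def _log_lambda_per_sample(self, c: float, k: float) -> np.ndarray:
        lam = np.array([float(self.surface(c, k, p)) for p in self.pressures])
        return np.log(lam)[self._press_idx]

    def log_marginal_raw(self, theta: np.ndarray) -> float:
        """Raw-data log-likelihood with patient means integrated out.

        Per patient the vector y_ij = ln t_ij - ln lambda_r(c,k,p_ij) is
        N(mu_pop 1, sigma_pat^2 I + sigma_pop^2 J); the compound-symmetric
        structure gives a closed-form determinant and quadratic form.  The
        lognormal Jacobian -sum ln t_ij is included so this is the exact log
        density of the observed thicknesses.
        """
        c, k, mu_pop, s_pop, s_pat = theta
        if not self.samples:
            return 0.0
        s_pat = max(s_pat, self.SIGMA_EPS)
        s_pop = max(s_pop, 0.0)
        y = self._logt - self._log_lambda_per_sample(c, k)
        n = self._n_i
        sum_y = np.bincount(self._pat_idx, weights=y, minlength=self.n_patients)
        sum_y2 = np.bincount(self._pat_idx, weights=y * y, minlength=self.n_patients)
        ybar = sum_y / n
        ss_within = sum_y2 - n * ybar**2
        v_pat = s_pat**2
        v_tot = v_pat + n * s_pop**2
        ll = -0.5 * (
            n.sum() * math.log(2 * math.pi)
            + np.sum((n - 1) * math.log(v_pat))
            + np.sum(np.log(v_tot))
            + np.sum(ss_within) / v_pat
            + np.sum(n * (ybar - mu_pop) ** 2 / v_tot)
        )
        return float(ll - self._logt.sum())

    def log_summary(self, theta: np.ndarray) -> float:
        if not self.summary_grids:
            return 0.0
        _, _, mu_pop, s_pop, s_pat = theta
        sigma = math.hypot(s_pop, s_pat)
        s_eval = min(max(sigma, self._sigma_grid_min), self._sigma_grid_max)
        penalty = 50.0 * len(self.summary_grids) * (sigma - s_eval) ** 2
        return float(sum(g(mu_pop, s_eval) for g in self.summary_grids)) - penalty

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_marginal_raw(theta) + self.log_summary(theta)

    def log_joint(self, theta: np.ndarray, mu: np.ndarray) -> float:
        """Joint log density with explicit patient means mu (length
        n_patients): sum of the patient-level normal prior, the per-sample
        deformed-thickness lognormal likelihood, the summary-study terms and
        the (uniform) parameter prior."""
        c, k, mu_pop, s_pop, s_pat = theta
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        mu = np.asarray(mu, dtype=float)
        s_pop = max(s_pop, self.SIGMA_EPS)
        s_pat = max(s_pat, self.SIGMA_EPS)
        out = lp
        out += float(
            np.sum(
                -0.5 * math.log(2 * math.pi) - math.log(s_pop)
                - 0.5 * ((mu - mu_pop) / s_pop) ** 2
            )
        )
        loc = mu[self._pat_idx] + self._log_lambda_per_sample(c, k)
        z = (self._logt - loc) / s_pat
        out += float(
            np.sum(-np.log(np.exp(self._logt)) - math.log(s_pat)
                   - 0.5 * math.log(2 * math.pi) - 0.5 * z**2)
        )
        out += self.log_summary(theta)
        return out

    # -- conditional recovery of patient means ----------------------------

    def conditional_mu(self, theta: np.ndarray, rng: np.random.Generator):
        """One exact draw of all patient means from p(mu_i | theta, data)."""
        c, k, mu_pop, s_pop, s_pat = theta
        s_pop = max(s_pop, self.SIGMA_EPS)
        s_pat = max(s_pat, self.SIGMA_EPS)
        y = self._logt - self._log_lambda_per_sample(c, k)
        n = self._n_i
        ybar = np.bincount(self._pat_idx, weights=y, minlength=self.n_patients) / n
        prec = 1.0 / s_pop**2 + n / s_pat**2
        mean = (mu_pop / s_pop**2 + n * ybar / s_pat**2) / prec
        return mean + rng.standard_normal(self.n_patients) / np.sqrt(prec)


def build_model(
    datasets: Sequence[ThicknessSample],
    summaries: Sequence[SummaryStatStudy],
    surface: ResponseSurface,
    priors: PriorSpec | None = None,
    **kwargs,
) -> Model:
    """Assemble the hierarchical model from raw samples, summary studies and
    a response surface covering every dataset pressure."""
    return Model(datasets, summaries, surface, priors, **kwargs)


@dataclass
class PosteriorDraws:
    """Posterior draws indexed by chain and draw.

    ``theta`` has shape (chains, draws, 5) ordered as PARAM_NAMES;
    ``mu_patient`` (chains, draws, n_patients) carries the reconstructed
    patient means when requested.
    """

    theta: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES
    mu_patient: np.ndarray | None = None
    patient_keys: list | None = None
    seed: int | None = None
    divergences: int = 0
    sampler: str = "emcee affine-invariant ensemble"
    attrs: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def get(self, param: str) -> np.ndarray:
        return self.theta[..., self.param_names.index(param)]

    def flat(self, param: str) -> np.ndarray:
        return self.get(param).reshape(-1)

    def to_inference_data(self) -> "az.InferenceData":
        data = {name: self.get(name) for name in self.param_names}
        return az.from_dict(posterior=data)

    def to_frame(self):
        import pandas as pd

        rows = []
        for ci in range(self.n_chains):
            for name in self.param_names:
                vals = self.get(name)[ci]
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ci,
                            "draw": np.arange(self.n_draws),
                            "parameter": name,
                            "value": vals,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _init_walkers(model: Model, n_walkers: int, rng: np.random.Generator):
    """Importance-style initialization: walkers start at the best-scoring of
    a batch of prior draws.  With data this places the ensemble near the
    posterior bulk (fast contraction); with no data all scores tie and the
    selection reduces to iid prior draws, so a data-free run is stationary
    from the first step."""
    b = model.priors.bounds()
    lo = b[:, 0] + 0.005 * (b[:, 1] - b[:, 0])
    hi = b[:, 0] + 0.995 * (b[:, 1] - b[:, 0])
    cand = rng.uniform(lo, hi, size=(48 * n_walkers, len(b)))
    scores = np.array([model.log_posterior(x) for x in cand])
    best = np.argsort(-scores, kind="stable")[:n_walkers]
    jitter = 1e-5 * (b[:, 1] - b[:, 0]) * rng.standard_normal((n_walkers, len(b)))
    return np.clip(cand[best] + jitter, b[:, 0] + 1e-9, b[:, 1] - 1e-9)


def sample_posterior(
    model: Model,
    chains: int = 4,
    draws: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    n_walkers: int = 32,
    thin: int = 8,
    recover_patient_means: bool = True,
    rhat_threshold: float = 1.01,
) -> PosteriorDraws:
    """Sample the marginal posterior with independent ensemble chains.

    Each chain is an independent emcee ensemble of ``n_walkers`` walkers;
    after ``warmup`` ensemble steps, every ``thin``-th step is retained
    until the flattened ensemble yields ``draws`` draws per chain (thinning
    spreads the retained draws over several walker autocorrelation times).
    Reproducible given ``seed``.  A maximum R-hat above ``rhat_threshold``
    flags the result as non-converged (returned, not discarded).
    """
    if chains < 1 or draws < 1:
        raise ValueError("chains and draws must be positive")
    keep_steps = int(np.ceil(draws / n_walkers))
    all_theta = np.empty((chains, keep_steps * n_walkers, 5))
    for ci in range(chains):
        rng = np.random.default_rng((seed, ci) if seed is not None else None)
        emcee_seed = int(rng.integers(0, 2**31 - 1))
        sampler = emcee.EnsembleSampler(
            n_walkers, 5, model.log_posterior,
        )
        sampler._random = np.random.RandomState(emcee_seed)  # determinism
        state = _init_walkers(model, n_walkers, rng)
        state = sampler.run_mcmc(state, warmup + keep_steps * thin, progress=False)
        chain = sampler.get_chain(discard=warmup, thin=thin)  # (keep, walkers, 5)
        all_theta[ci] = chain.reshape(-1, 5)
    all_theta = all_theta[:, :draws, :]

    result = PosteriorDraws(
        theta=all_theta,
        seed=seed,
        divergences=0,  # not a concept for the gradient-free ensemble moves
        attrs={
            "chains": chains,
            "draws": draws,
            "warmup": warmup,
            "n_walkers": n_walkers,
        },
    )
    if model.samples and recover_patient_means:
        rng = np.random.default_rng((seed, 10_007) if seed is not None else None)
        mu = np.empty((chains, draws, model.n_patients))
        for ci in range(chains):
            for di in range(draws):
                mu[ci, di] = model.conditional_mu(all_theta[ci, di], rng)
        result.mu_patient = mu
        result.patient_keys = model.patient_keys

    rep = diagnostics(result) if chains >= 2 else None
    if rep is not None:
        result.attrs["max_rhat"] = rep["max_rhat"]
        result.attrs["min_ess"] = rep["min_ess"]
        result.attrs["converged"] = bool(rep["max_rhat"] <= rhat_threshold)
        if not result.attrs["converged"]:
            warnings.warn(
                f"max R-hat {rep['max_rhat']:.4f} > {rhat_threshold}; "
                "treat this posterior as non-converged",
                stacklevel=2,
            )
    return result


def diagnostics(draws: PosteriorDraws) -> dict:
    """Rank-normalized split R-hat and ESS per parameter, plus pairwise
    posterior-dependence summaries for (sigma_pop, sigma_pat) and (c, k)."""
    if draws.n_chains < 2:
        return {
            "rhat": {name: float("nan") for name in draws.param_names},
            "ess": {},
            "max_rhat": float("nan"),
            "min_ess": float("nan"),
            "note": "R-hat undefined for a single chain",
        }
    idata = draws.to_inference_data()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_d = {name: float(rhat[name].values) for name in draws.param_names}
    ess_d = {name: float(ess[name].values) for name in draws.param_names}

    def _corr(a: str, b: str) -> float:
        return float(np.corrcoef(draws.flat(a), draws.flat(b))[0, 1])

    return {
        "rhat": rhat_d,
        "ess": ess_d,
        "max_rhat": max(rhat_d.values()),
        "min_ess": min(ess_d.values()),
        "pairwise": {
            "sigma_pop~sigma_pat": _corr("sigma_pop", "sigma_pat"),
            "c~k": _corr("c", "k"),
        },
    }


def posterior_summary(
    draws: PosteriorDraws, param: str, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Posterior median and equal-tailed credible interval of a parameter."""
    x = draws.flat(param)
    alpha = (1.0 - ci) / 2.0
    return float(np.median(x)), (
        float(np.quantile(x, alpha)),
        float(np.quantile(x, 1.0 - alpha)),
    )
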