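"""Posterior predictive undeformed thickness and study-level corrections.

Given posterior draws of (c, k, mu_pop, sigma_pop, sigma_pat), the
undeformed thickness of a new sample from a new patient is the mixture
T ~ LN(mu_pop, sqrt(sigma_pop^2 + sigma_pat^2)) averaged over the
posterior.  The module draws from that predictive distribution, fits the
practical lognormal approximation, evaluates lower-tail probabilities
(thin-wall risk), undeforms pressure-biased study data via the radial
compression model, and quantifies how much of the inter-study spread the
pressure correction removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .constitutive import ResponseSurface
from .hierarchical import PosteriorDraws, ThicknessSample

__all__ = [
    "PredictiveDistribution",
    "StudyCorrectionRecord",
    "posterior_predictive",
    "fit_lognormal_approx",
    "tail_probability",
    "undeform_study",
    "shift_metrics",
    "theoretical_quantile_boxplot",
]


@dataclass
class PredictiveDistribution:
    """Draws of a new sample's undeformed thickness [mm] with provenance."""

    draws: np.ndarray
    seed: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.size and self.draws.min() <= 0:
            raise ValueError("thickness draws must be positive")

    def summary(self, ci: float = 0.95) -> dict:
        a = (1 - ci) / 2
        return {
            "mean_mm": float(self.draws.mean()),
            "median_mm": float(np.median(self.draws)),
            "pi_lower_mm": float(np.quantile(self.draws, a)),
            "pi_upper_mm": float(np.quantile(self.draws, 1 - a)),
            "n_draws": int(self.draws.size),
        }


@dataclass(frozen=True)
class StudyCorrectionRecord:
    """Original vs pressure-corrected mean/median thickness of one study."""

    label: str
    pressure_kpa: float
    original_mean: float
    original_median: float
    corrected_mean: float
    corrected_median: float

    def __post_init__(self) -> None:
        if self.pressure_kpa > 0:
            if self.corrected_mean < self.original_mean - 1e-12:
                raise ValueError("correction cannot shrink a compressed mean")
        else:
            if not math.isclose(self.corrected_mean, self.original_mean):
                raise ValueError("zero-pressure study must pass through unchanged")


def posterior_predictive(
    draws: PosteriorDraws, n: int, seed: int | None = 0
) -> PredictiveDistribution:
    """Sample ``n`` undeformed thicknesses from the posterior predictive.

    Per retained posterior draw (cycled if n exceeds the posterior size):
    mu_new ~ N(mu_pop, sigma_pop), then T ~ LN(mu_new, sigma_pat) --
    equivalently T ~ LN(mu_pop, sqrt(sigma_pop^2 + sigma_pat^2)).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    mu = draws.flat("mu_pop")
    s_pop = draws.flat("sigma_pop")
    s_pat = draws.flat("sigma_pat")
    idx = np.arange(n) % mu.size
    mu_new = mu[idx] + s_pop[idx] * rng.standard_normal(n)
    t = np.exp(mu_new + s_pat[idx] * rng.standard_normal(n))
    return PredictiveDistribution(t, seed=seed, source="posterior_predictive")


def fit_lognormal_approx(dist: PredictiveDistribution) -> tuple[float, float]:
    """Lognormal (mu, sigma) by moment matching on the log scale."""
    if dist.draws.size < 10_000:
        raise ValueError("need at least 1e4 draws for a stable approximation")
    logs = np.log(dist.draws)
    return float(logs.mean()), float(logs.std(ddof=1))


def tail_probability(mu: float, sigma: float, t1: float) -> float:
    """P(T < t1) in percent for T ~ LN(mu, sigma)."""
    if t1 <= 0:
        raise ValueError("threshold must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 100.0 * float(norm.cdf((math.log(t1) - mu) / sigma))


def _posterior_ck(draws: PosteriorDraws) -> tuple[float, float]:
    return float(np.median(draws.flat("c"))), float(np.median(draws.flat("k")))


def undeform_study(
    samples: Sequence[ThicknessSample],
    draws: PosteriorDraws,
    surface: ResponseSurface,
    mode: str = "median",
    label: str | None = None,
) -> StudyCorrectionRecord:
    """Correct one study's deformed thicknesses back to undeformed values.

    ``mode='median'`` divides by lambda_r at the posterior medians of
    (c, k); ``mode='average'`` averages T = t / lambda_r over a thinned set
    of posterior (c, k) draws.  Zero-pressure samples pass through exactly.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("study has no samples")
    labels = {s.study_id for s in samples}
    if label is None:
        if len(labels) != 1:
            raise ValueError("samples from several studies; pass label explicitly")
        label = labels.pop()
    t = np.array([s.t for s in samples])
    p = np.array([s.p for s in samples])
    if p.max() > float(np.max(surface.pressures)):
        raise ValueError("study pressure not covered by the response surface")

    if mode == "median":
        c_med, k_med = _posterior_ck(draws)
        lam = np.array([1.0 if pi == 0 else float(surface(c_med, k_med, pi)) for pi in p])
        corrected = t / lam
    elif mode == "average":
        cs = draws.flat("c")
        ks = draws.flat("k")
        take = np.linspace(0, cs.size - 1, min(200, cs.size)).astype(int)
        acc = np.zeros_like(t)
        for ci, ki in zip(cs[take], ks[take]):
            lam = np.array([1.0 if pi == 0 else float(surface(ci, ki, pi)) for pi in p])
            acc += t / lam
        corrected = acc / take.size
    else:
        raise ValueError("mode must be 'median' or 'average'")
    return StudyCorrectionRecord(
        label=label,
        pressure_kpa=float(p.max()),
        original_mean=float(t.mean()),
        original_median=float(np.median(t)),
        corrected_mean=float(corrected.mean()),
        corrected_median=float(np.median(corrected)),
    )


def shift_metrics(records: Sequence[StudyCorrectionRecord]) -> dict:
    """Inter-study range (max - min) of means and medians before and after
    the pressure correction, with percent reductions."""
    if len(records) < 2:
        raise ValueError("need at least two studies")
    om = np.array([r.original_mean for r in records])
    od = np.array([r.original_median for r in records])
    cm = np.array([r.corrected_mean for r in records])
    cd = np.array([r.corrected_median for r in records])
    out = {
        "mean_range_before_mm": float(om.max() - om.min()),
        "mean_range_after_mm": float(cm.max() - cm.min()),
        "median_range_before_mm": float(od.max() - od.min()),
        "median_range_after_mm": float(cd.max() - cd.min()),
    }
    for what in ("mean", "median"):
        before = out[f"{what}_range_before_mm"]
        after = out[f"{what}_range_after_mm"]
        out[f"{what}_range_reduction_pct"] = (
            100.0 * (1.0 - after / before) if before > 0 else 0.0
        )
    return out


def theoretical_quantile_boxplot(dist, n_quantiles: int = 98) -> dict:
    """Boxplot statistics from theoretical quantiles of a distribution.

    ``dist`` is either a frozen scipy distribution (with ``.ppf``) or an
    array of draws (empirical quantiles).  Quantiles are taken at plotting
    positions i/(n+1), i = 1..n; quartiles and whisker extremes are computed
    from those n values, mirroring a boxplot of an n-sample virtual data set.
    """
    q = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    if hasattr(dist, "ppf"):
        vals = np.asarray(dist.ppf(q), dtype=float)
    else:
        vals = np.quantile(np.asarray(dist, dtype=float), q)
    # quartiles extracted with the same i/(n+1) plotting-position convention
    # (Weibull method), so they are consistent across quantile counts
    return {
        "whisker_low": float(vals.min()),
        "q1": float(np.percentile(vals, 25, method="weibull")),
        "median": float(np.percentile(vals, 50, method="weibull")),
        "q3": float(np.percentile(vals, 75, method="weibull")),
        "whisker_high": float(vals.max()),
        "n_quantiles": int(n_quantiles),
    }
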