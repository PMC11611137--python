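"""Sampling distribution of (sample mean, sample SD) of lognormal data.

Several thickness studies publish only summary statistics (M, S, N) of
undeformed wall thickness.  To use them in a likelihood one needs the joint
sampling density f(M, S; mu, sigma) of the mean and SD of N iid LN(mu,
sigma) variables, for which no tractable closed form exists.  This module
computes it essentially exactly via characteristic functions:

1. (M, S) is a one-to-one function of V = (sum T_i, sum T_i^2);
2. the characteristic function of (T, T^2) is a 1-D integral over the
   lognormal density, evaluated by high-resolution quadrature;
3. the N-fold convolution is the N-th power of that characteristic
   function (convolution theorem);
4. a numerical inverse Fourier transform yields the density of V on a
   window around its mass, and the exact change of variables
   M = V1/N, S^2 = (V2 - N M^2)/(N - 1) (sample, n-1 convention) gives
   f(M, S).

Two exact reparameterizations keep the computation small: the lognormal is
scale-equivariant, f(M, S; mu, sigma) = e^{-2 mu} f(M e^{-mu}, S e^{-mu};
0, sigma), so transforms are only ever built at mu = 0; and V is rotated to
U = (V1, V2 - beta V1) with beta = Cov(T, T^2)/Var(T), which removes the
near-perfect correlation of V1 and V2 at small sigma and keeps the
frequency grid axis-aligned and compact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.stats import lognorm

__all__ = [
    "SummaryStatStudy",
    "QuadratureSpec",
    "MeanSdDensity",
    "MeanSdFamily",
    "JointDensityGrid",
    "lognormal_mom",
    "pool_subset_stats",
    "joint_mean_sd_density",
    "loglik_surface",
]

#: log-density assigned outside the computed support window
LOG_FLOOR = -1.0e4


@dataclass(frozen=True)
class SummaryStatStudy:
    """A study reported only as mean +/- SD of N undeformed thicknesses [mm]."""

    M: float
    S: float
    N: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError("sample mean must be positive")
        if self.S < 0:
            raise ValueError("sample SD must be non-negative")
        if self.N < 2:
            raise ValueError("sample count must be at least 2")


def lognormal_mom(M: float, S: float) -> tuple[float, float]:
    """Method-of-moments lognormal parameters from a sample mean and SD.

    sigma^2 = ln(1 + S^2/M^2),  mu = ln M - sigma^2/2.
    """
    if M <= 0:
        raise ValueError("mean must be positive")
    if S < 0:
        raise ValueError("SD must be non-negative")
    sigma2 = math.log1p((S / M) ** 2)
    return math.log(M) - sigma2 / 2.0, math.sqrt(sigma2)


def pool_subset_stats(subsets: Sequence[SummaryStatStudy]) -> SummaryStatStudy:
    """Exact mean and SD of the concatenation of subsets known only through
    their (M, S, N) triples (SDs in the n-1 convention)."""
    if len(subsets) == 0:
        raise ValueError("need at least one subset")
    n_tot = sum(s.N for s in subsets)
    sum_x = sum(s.N * s.M for s in subsets)
    sum_x2 = sum((s.N - 1) * s.S**2 + s.N * s.M**2 for s in subsets)
    mean = sum_x / n_tot
    var = (sum_x2 - n_tot * mean**2) / (n_tot - 1)
    return SummaryStatStudy(
        mean, math.sqrt(max(var, 0.0)), n_tot,
        label="+".join(s.label for s in subsets if s.label),
    )


@dataclass(frozen=True)
class QuadratureSpec:
    """Discretization controls for the Fourier pipeline.

    truncation : lognormal quantile at which the single-sample density is cut
    oversample : quadrature points per oscillation period of the integrand
    margins    : half-widths of the inversion window, in bulk SDs of the sum
    band_factor: frequency band limit in units of 1/bulk-scale; content
                 beyond it is rolled off smoothly (taper_flat sets where the
                 roll-off starts) and traded for sub-bulk-scale smoothing
    mass_tol   : allowed deviation of the recovered density mass from 1
    """

    truncation: float = 1e-8
    oversample: float = 10.0
    n_t_max: int = 60_000
    n_half_max: int = 3000
    n_u: tuple[int, int] = (140, 140)
    margins: tuple[float, float, float, float] = (13.0, 17.0, 13.0, 17.0)
    band_factor: float = 28.0
    taper_flat: float = 0.7
    mass_tol: float = 0.01


def _hann_taper(n: int, flat: float = 0.6) -> np.ndarray:
    """Symmetric taper: 1 on the central ``flat`` fraction, cosine roll-off
    to 0 at the edges (a Tukey window)."""
    x = np.abs(np.linspace(-1.0, 1.0, n))
    out = np.ones(n)
    roll = x > flat
    out[roll] = 0.5 * (1.0 + np.cos(np.pi * (x[roll] - flat) / (1.0 - flat)))
    return out


class _Member:
    """Density of U = (V1, V2 - beta V1) for N iid LN(0, sigma) samples."""

    def __init__(self, sigma: float, N: int, quad: QuadratureSpec) -> None:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if N < 2:
            raise ValueError("N must be at least 2")
        self.sigma = float(sigma)
        self.N = int(N)
        self.quad = quad
        self._build()

    # -- lognormal moments ------------------------------------------------

    def _moments(self):
        s2 = self.sigma**2
        m = [math.exp(j**2 * s2 / 2.0) for j in range(1, 5)]
        m1, m2, m3, m4 = m
        v11 = m2 - m1**2
        cov = m3 - m1 * m2
        v22 = m4 - m2**2
        beta = cov / v11
        v_res = v22 - cov**2 / v11  # Var(T^2 - beta T)
        return m1, m2, v11, v_res, beta

    def _robust_stats(self, beta: float):
        """IQR-based scales and medians of T and T^2 - beta T.

        For skewed sigma the moment SDs (and means) are dominated by rare
        large samples and would misplace and oversize the inversion window;
        quantile-based statistics keep the window centred on the bulk of the
        sum and sized so the grid can resolve it."""
        t = np.geomspace(self._t_lo, self._t_hi, 4000)
        w = lognorm.pdf(t, s=self.sigma) * np.gradient(t)
        scales, medians = [], []
        for vals in (t, t * t - beta * t):
            order = np.argsort(vals)
            cw = np.cumsum(w[order])
            cw /= cw[-1]
            q25, q50, q75 = np.interp([0.25, 0.5, 0.75], cw, vals[order])
            scales.append(float((q75 - q25) / 1.349))
            medians.append(float(q50))
        return scales[0], scales[1], medians[0], medians[1]

    def _t_grid(self, slope: float, t_hi: float | None = None):
        """Quadrature nodes and weights for integrals against the lognormal.

        Union of a log-spaced grid (resolves the density peak, which sits
        orders of magnitude below the upper truncation for large sigma) and
        a uniform grid fine enough for the fastest phase oscillation."""
        t_hi = self._t_hi if t_hi is None else t_hi
        n_osc = int(
            np.clip(
                self.quad.oversample * slope * (t_hi - self._t_lo) / (2 * np.pi),
                400,
                self.quad.n_t_max,
            )
        )
        t_lin = np.linspace(self._t_lo, t_hi, n_osc)
        t_log = np.geomspace(self._t_lo, t_hi, 1500)
        t = np.unique(np.concatenate([t_lin, t_log]))
        w = lognorm.pdf(t, s=self.sigma)
        w = w * np.gradient(t)
        return t, w

    def _build(self) -> None:
        q = self.quad
        N = self.N
        self._t_lo = float(lognorm.ppf(q.truncation, s=self.sigma))
        self._t_hi = float(lognorm.ppf(1.0 - q.truncation, s=self.sigma))
        m1, m2, v11, v_res, beta = self._moments()
        self.beta = beta

        s1_rob, s2_rob, med1, med2 = self._robust_stats(beta)
        s1_rob = max(s1_rob, 1e-150)
        s2_rob = max(s2_rob, 1e-150)
        bulk1 = math.sqrt(N) * s1_rob
        bulk2 = math.sqrt(N) * s2_rob
        # window sized in bulk units but containing both the robust centre
        # (N x per-sample median) and the moment mean of the sum
        sd1 = math.sqrt(N) * min(math.sqrt(v11), 1.5 * s1_rob)
        sd2 = math.sqrt(N) * min(math.sqrt(max(v_res, 1e-300)), 1.5 * s2_rob)
        c1_lo, c1_hi = sorted((N * m1, N * med1))
        c2_lo, c2_hi = sorted((N * (m2 - beta * m1), N * med2))
        lo1 = max(N * self._t_lo, c1_lo - q.margins[0] * sd1)
        hi1 = c1_hi + q.margins[1] * sd1
        lo2 = c2_lo - q.margins[2] * sd2
        hi2 = c2_hi + q.margins[3] * sd2
        self.window = (lo1, hi1, lo2, hi2)

        # frequency lattice: period = 1.6x the window so wrap-around from the
        # periodization cannot land inside it.  The band limit is set by the
        # bulk of the sum (robust per-sample scale x sqrt(N)): the Gaussian
        # bulk's characteristic function is e^-200 at 20/bulk, and whatever
        # heavy-tail micro-structure extends beyond is rolled off smoothly by
        # the taper, i.e. traded for smoothing far below the bulk scale.
        dw1 = 2 * np.pi / (1.6 * (hi1 - lo1))
        dw2 = 2 * np.pi / (1.6 * (hi2 - lo2))
        n1 = min(int(np.ceil(q.band_factor / bulk1 / dw1)), q.n_half_max)
        n2 = min(int(np.ceil(q.band_factor / bulk2 / dw2)), q.n_half_max)
        w1 = dw1 * np.arange(-n1, n1 + 1)
        w2 = dw2 * np.arange(-n2, n2 + 1)

        # the t-integral for the characteristic function may use a milder
        # truncation: dropping tail mass eps biases the cf by at most eps,
        # far below the band-limiting scale, while greatly reducing the
        # oscillation bandwidth (slope ~ omega2 * t_hi^2)
        t_hi_cf = min(self._t_hi, float(lognorm.ppf(1.0 - 1e-6, s=self.sigma)))
        slope = (w1[-1] + beta * w2[-1]) + 2.0 * w2[-1] * t_hi_cf
        t, wt = self._t_grid(slope, t_hi_cf)

        # cf of (T, T^2 - beta T) on the lattice, then N-th power
        phi = np.empty((w2.size, w1.size), dtype=complex)
        chunk = 8192
        for i0 in range(0, t.size, chunk):
            ts = t[i0 : i0 + chunk]
            ws = wt[i0 : i0 + chunk]
            W = ws * np.exp(1j * np.outer(w2, ts * ts - beta * ts))
            E = np.exp(1j * np.outer(ts, w1))
            phi += W @ E if i0 else 0.0
            if i0 == 0:
                phi = W @ E
        phi_n = phi**N
        # smooth low-pass taper (Hann roll-off over the outer 40% of each
        # frequency axis): the abrupt lattice edge would otherwise ring at
        # the amplitude of the truncated characteristic-function tail, which
        # the positivity clip then rectifies into spurious mass.  The
        # induced smoothing acts at the scale of a few inversion cells,
        # far below the statistical scale of the density.
        phi_n = phi_n * np.outer(
            _hann_taper(w2.size, q.taper_flat), _hann_taper(w1.size, q.taper_flat)
        )

        # resolve the inversion grid to the band limit (1.5x Nyquist), so the
        # spline sees every feature the transform can represent
        n_u1 = int(np.clip(np.ceil(1.5 * (hi1 - lo1) * w1[-1] / np.pi), q.n_u[0], 480))
        n_u2 = int(np.clip(np.ceil(1.5 * (hi2 - lo2) * w2[-1] / np.pi), q.n_u[1], 480))
        u1 = np.linspace(lo1, hi1, n_u1)
        u2 = np.linspace(lo2, hi2, n_u2)
        A = np.exp(-1j * np.outer(u1, w1))
        B = np.exp(-1j * np.outer(w2, u2))
        f = (A @ phi_n.T @ B).real * (dw1 * dw2 / (2 * np.pi) ** 2)

        peak = float(f.max())
        if peak <= 0:
            raise RuntimeError("mean/SD density inversion produced no mass")
        f = np.clip(f, peak * 1e-13, None)
        mass = float(np.trapezoid(np.trapezoid(f, u2, axis=1), u1))
        if abs(mass - 1.0) > q.mass_tol:
            raise RuntimeError(
                "quadrature grid too small for (sigma={:.4g}, N={}): recovered "
                "mass {:.4f} deviates from 1 by more than {:.2g}".format(
                    self.sigma, N, mass, q.mass_tol
                )
            )
        self.mass = mass
        self._u1, self._u2 = u1, u2
        self._logf = RectBivariateSpline(u1, u2, np.log(f), kx=3, ky=3, s=0)

    # -- evaluation -------------------------------------------------------

    def log_pdf_ms(self, M, S, mu: float = 0.0):
        """log f(M, S; mu, sigma) for arrays M, S (same shape)."""
        M = np.asarray(M, dtype=float)
        S = np.asarray(S, dtype=float)
        N = self.N
        scale = math.exp(-mu)
        Ms, Ss = M * scale, S * scale
        v1 = N * Ms
        v2 = (N - 1) * Ss**2 + N * Ms**2
        u2 = v2 - self.beta * v1
        lo1, hi1, lo2, hi2 = self.window
        inside = (
            (v1 >= lo1) & (v1 <= hi1) & (u2 >= lo2) & (u2 <= hi2) & (Ss > 0)
        )
        out = np.full(np.broadcast_shapes(M.shape, S.shape), LOG_FLOOR, dtype=float)
        if np.any(inside):
            jac = 2.0 * N * (N - 1) * Ss[inside]
            out[inside] = (
                self._logf.ev(v1[inside], u2[inside])
                + np.log(jac)
                - 2.0 * mu
            )
        # gentle gradient away from the window so optimizers are not stranded
        if np.any(~inside):
            d1 = np.maximum(np.maximum(lo1 - v1, v1 - hi1), 0.0) / (hi1 - lo1)
            d2 = np.maximum(np.maximum(lo2 - u2, u2 - hi2), 0.0) / (hi2 - lo2)
            pen = LOG_FLOOR * (1.0 + d1 + d2)
            out[~inside] = pen[~inside]
        return out if out.shape else float(out)


class MeanSdDensity:
    """Joint density of (sample mean, sample SD) of N iid LN(mu, sigma)."""

    def __init__(self, mu: float, sigma: float, N: int,
                 quad: QuadratureSpec | None = None) -> None:
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.N = int(N)
        self.quad = quad or QuadratureSpec()
        self._member = _Member(self.sigma, self.N, self.quad)

    @property
    def mass(self) -> float:
        """Numerically recovered total probability (should be ~1)."""
        return self._member.mass

    def logpdf(self, M, S):
        return self._member.log_pdf_ms(M, S, mu=self.mu)

    def pdf(self, M, S):
        return np.exp(self.logpdf(M, S))

    def support_box(self) -> tuple[float, float, float, float]:
        """(M_lo, M_hi, S_lo, S_hi) box containing essentially all mass."""
        lo1, hi1, lo2, hi2 = self._member.window
        N, b = self.N, self._member.beta
        scale = math.exp(self.mu)
        m_lo, m_hi = lo1 / N * scale, hi1 / N * scale
        # S bounds from the u2 window at the central mean
        v1c = 0.5 * (lo1 + hi1)
        s2_hi = (hi2 + b * v1c + b * hi1 - v1c**2 / N) / (N - 1)
        s_hi = math.sqrt(max(s2_hi, 1e-12)) * scale
        return m_lo, m_hi, 0.0, s_hi


def joint_mean_sd_density(
    mu_pop: float, sigma: float, N: int, quadrature: QuadratureSpec | None = None
) -> MeanSdDensity:
    """Density of the (mean, SD) statistic of N iid LN(mu_pop, sigma) samples.

    Raises with a mass-deficit report if the quadrature cannot represent the
    requested (mu_pop, sigma, N).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return MeanSdDensity(mu_pop, sigma, N, quadrature)


class MeanSdFamily:
    """Cache of mean/SD sampling densities for one sample count N.

    Members are built per sigma at mu = 0; evaluation at any mu uses exact
    scale equivariance.  Used to fill likelihood grids cheaply.
    """

    _global: dict[tuple[int, float], "_Member"] = {}

    def __init__(self, N: int, quad: QuadratureSpec | None = None) -> None:
        self.N = int(N)
        self.quad = quad or QuadratureSpec()

    def member(self, sigma: float) -> _Member:
        key = (self.N, round(float(sigma), 10))
        got = MeanSdFamily._global.get(key)
        if got is None or got.quad is not self.quad and got.quad != self.quad:
            got = _Member(float(sigma), self.N, self.quad)
            MeanSdFamily._global[key] = got
        return got

    def logpdf(self, M, S, mu: float, sigma: float):
        return self.member(sigma).log_pdf_ms(M, S, mu=mu)


class JointDensityGrid:
    """log f(M_k, S_k; mu_pop, sigma) on a (mu, sigma) grid with a bicubic
    interpolating surface; the summary-study likelihood used inside MCMC."""

    def __init__(self, study: SummaryStatStudy, mu_grid: np.ndarray,
                 sigma_grid: np.ndarray, log_density: np.ndarray) -> None:
        self.study = study
        self.mu_grid = np.asarray(mu_grid, dtype=float)
        self.sigma_grid = np.asarray(sigma_grid, dtype=float)
        self.log_density = np.asarray(log_density, dtype=float)
        self.interpolant = RectBivariateSpline(
            self.mu_grid, self.sigma_grid, self.log_density, kx=3, ky=3, s=0
        )

    def __call__(self, mu, sigma):
        mu = np.asarray(mu, dtype=float)
        sigma = np.asarray(sigma, dtype=float)
        out = self.interpolant.ev(mu, sigma)
        # outside the tabulated box the surface is an extrapolation; flag by
        # flooring (the prior box should live inside the grid)
        bad = (
            (mu < self.mu_grid[0]) | (mu > self.mu_grid[-1])
            | (sigma < self.sigma_grid[0]) | (sigma > self.sigma_grid[-1])
        )
        out = np.where(bad, LOG_FLOOR, out)
        return out if out.shape else float(out)

    def argmax(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.log_density), self.log_density.shape)
        return float(self.mu_grid[i]), float(self.sigma_grid[j])

    def grid_steps(self) -> tuple[float, float]:
        return (
            float(np.max(np.diff(self.mu_grid))),
            float(np.max(np.diff(self.sigma_grid))),
        )

    def concentration_area(self, delta: float = 2.0) -> float:
        """Fraction of grid cells within ``delta`` nats of the maximum; a
        smaller value means a more concentrated likelihood."""
        top = self.log_density.max()
        return float(np.mean(self.log_density > top - delta))

    def to_dict(self) -> dict:
        return {
            "study": {"M": self.study.M, "S": self.study.S,
                      "N": self.study.N, "label": self.study.label},
            "mu_grid": self.mu_grid.tolist(),
            "sigma_grid": self.sigma_grid.tolist(),
            "log_density": self.log_density.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "JointDensityGrid":
        return cls(
            SummaryStatStudy(**d["study"]),
            np.array(d["mu_grid"]),
            np.array(d["sigma_grid"]),
            np.array(d["log_density"]),
        )

    @classmethod
    def load(cls, path) -> "JointDensityGrid":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def loglik_surface(
    study: SummaryStatStudy,
    mu_range: tuple[float, float],
    sigma_range: tuple[float, float],
    n_mu: int = 100,
    n_sigma: int = 100,
    quadrature: QuadratureSpec | None = None,
    warn_boundary: bool = True,
    sigma_spacing: str = "linear",
) -> JointDensityGrid:
    """Log-likelihood of (mu_pop, sigma) given one summary-statistics study,
    tabulated on an ``n_mu x n_sigma`` grid and fitted with bicubic splines.

    The ranges should cover the study's method-of-moments point estimate;
    an argmax on the grid boundary triggers a warning (range too narrow).
    """
    family = MeanSdFamily(study.N, quadrature)
    mu_grid = np.linspace(*mu_range, n_mu)
    if sigma_spacing == "log":
        sigma_grid = np.geomspace(*sigma_range, n_sigma)
    else:
        sigma_grid = np.linspace(*sigma_range, n_sigma)
    logf = np.empty((n_mu, n_sigma))
    # scale equivariance: evaluating at mu is evaluating the mu=0 member at
    # the rescaled statistic, so one member per sigma covers every mu row
    scale = np.exp(-mu_grid)
    Ms = study.M * scale
    Ss = study.S * scale
    for j, sig in enumerate(sigma_grid):
        member = family.member(sig)
        logf[:, j] = member.log_pdf_ms(Ms, Ss, mu=0.0) - 2.0 * mu_grid
    grid = JointDensityGrid(study, mu_grid, sigma_grid, logf)
    if warn_boundary:
        i, j = np.unravel_index(np.argmax(logf), logf.shape)
        if i in (0, n_mu - 1) or j in (0, n_sigma - 1):
            import warnings

            warnings.warn(
                f"log-likelihood argmax for study {study.label!r} lies on the "
                "grid boundary; widen mu_range/sigma_range",
                stacklevel=2,
            )
    return grid
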