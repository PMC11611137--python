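# Methods

`aawt` estimates the population distribution of *undeformed* abdominal
aortic aneurysm (AAA) wall thickness by pooling studies whose thickness
measurements were taken under different device contact pressures, including
studies available only as a mean ± SD. This note documents the model, the
numerical design choices and their validated domains, and what the
synthetic benchmark does and does not demonstrate.

## The measurement problem

Aneurysm wall tissue is radially very compliant: a thickness gauge pressing
with a few kPa compresses the wall by tens of percent, so studies using
contact devices report systematically thinner walls than studies using
laser (non-contact) measurement. Pooling such data naively conflates
measurement protocol with biology. The package models the compression
explicitly and infers the common undeformed thickness distribution.

## Constitutive model of radial compression

The wall is an incompressible Holzapfel–Gasser–Ogden (HGO) solid,

Ψ = c/2·(I₁ − 3) + k/(2k₂)·Σᵢ∈{4,6} [exp(k₂(Iᵢ − 1)²) − 1],

with two symmetric fibre families at ±φ from the circumferential direction,
engaged only in tension (Iᵢ > 1). The fibre architecture constants are
fixed at φ = 0.546 rad and k₂ = 15; the two stiffness-like parameters
c (ground matrix) and k (fibre initial stiffness), both in kPa, are inferred
from the data and shared across patients. A measured (deformed) thickness t
relates to the undeformed thickness T by t = λ_r·T, where the radial
stretch λ_r solves the uniaxial-compression boundary-value problem: given
λ_r, the in-plane stretches (λ_c, λ_a) satisfy traction-free lateral faces
(σ_cc = σ_aa = 0, solved as two unknowns — the ±φ families do not make
them equal) together with incompressibility, the hydrostatic pressure is
eliminated through the lateral boundary condition, and the contact pressure
equals the radial first Piola–Kirchhoff stress magnitude
|P_rr| = |σ_rr|/λ_r.

Numerics: the in-plane equilibrium is a bracketed bisection in λ_c
(residual is monotone; the bracket [0.05, 20]·λ_r^{-1/2} always contains
the root); pressure inversion is Brent's method on λ_r ∈ [0.61, 1]. Both
are deterministic to ~1e-10. Exponents are clamped at e^500 inside root
brackets only. An energy-consistency identity — |P_rr| equals the negative
derivative of the strain-energy density along the constrained equilibrium
path — is enforced in the tests at 1e-5 relative tolerance, and the
isotropic limit k = 0 reproduces the closed-form neo-Hookean solution
|P_r| = c(λ_r⁻² − λ_r).

### Response-surface emulator

The likelihood needs λ_r(c, k, p) at every posterior evaluation, so it is
tabulated once per contact pressure on a 40×40 (c, k) grid over
c ∈ [0, 10] kPa, k ∈ [0, 40] kPa and fitted with bicubic tensor splines,
with monotone piecewise-cubic interpolation across pressure and the exact
plane λ_r ≡ 1 at p = 0. Two non-obvious choices:

- **Transformed spline axes.** λ_r varies like √(ln(1/k)) as k → 0 (the
  exponential fibre term switches on violently), which no polynomially
  spaced grid resolves. The splines are built over (√c, ln(k + 0.05)),
  where the response is mild; the achieved worst-case emulator error
  against direct inversion is ~3·10⁻⁷ over the interior and ~6·10⁻⁴ in the
  extreme sliver k < 0.3, well inside the 10⁻³ build contract (the build
  measures and records its own error and fails if the contract is missed).
- **Saturation handling.** For very soft parameters the target pressure is
  not reachable within λ_r ∈ [0.61, 1] (and at c = k = 0 not at all). The
  tabulated function inverts on an extended internal range λ_r ∈ [0.25, 1]
  so it stays smooth in (c, k), and evaluation clips to the public range.
  The clip is applied identically by the direct inversion, so emulator and
  oracle agree everywhere.

The surface serializes to JSON (grids, node values, achieved error, build
metadata) so inference runs can reuse it.

### Equibiaxial initial stiffness

For comparison with planar biaxial testing, the small-strain tangent moduli
of the predicted equibiaxial response are computed per posterior draw as
the forward-difference slope of in-plane FPK stress vs stretch at 0.1%
strain on the tension side. Closed forms E₀,circ = 6c + 8k·cos²φ and
E₀,axial = 6c + 8k·sin²φ (hand-derived, valid as strain → 0) back the
tests.

## Hierarchical population model

Patient i has a latent mean log-thickness μᵢ ~ N(μ_pop, σ_pop); sample j of
patient i has undeformed thickness T_ij ~ LN(μᵢ, σ_pat); the measurement is
t_ij = λ_r(c, k, p_ij)·T_ij with known study pressure p_ij. σ_pop is the
inter-patient and σ_pat the intra-patient variability; the marginal
distribution of a random sample is LN(μ_pop, √(σ_pop² + σ_pat²)).
Non-contact studies enter with p = 0 exactly. Priors are independent
uniforms, by default c ~ U(0,10) kPa, k ~ U(0,40) kPa, μ_pop ~ U(0,2),
σ_pop, σ_pat ~ U(0,1), all configurable.

**Marginalization.** Given the parameters, the vector of
y_ij = ln t_ij − ln λ_r for one patient is multivariate normal with
compound-symmetric covariance σ_pat²I + σ_pop²J, whose determinant and
quadratic form are closed-form. The latent μᵢ are therefore integrated out
exactly, leaving a 5-parameter posterior. Patient means are recovered
afterwards, exactly, by drawing from their conjugate normal conditional
once per retained posterior draw. Tests verify the marginal against direct
quadrature over the μᵢ of the explicit joint density on a toy dataset.

**Sampling.** The 5-dimensional marginal posterior is explored with an
affine-invariant ensemble sampler (emcee): several independent ensembles
serve as chains (default 4 chains × 32 walkers). Walkers start at the
best-scoring of a batch of prior draws — with data this places the
ensemble near the posterior bulk, and with no data all scores tie and the
selection reduces to iid prior draws, so a data-free run is stationary
from the first step. 1000 warmup ensemble steps are discarded and every
8th step is retained
until 2000 draws per chain accumulate — a retained span of ~500 steps,
several walker autocorrelation times. Rank-normalized split R-hat and ESS
(arviz) are computed per parameter; a maximum R-hat above 1.01 flags the
result as non-converged but the draws are returned — convergence judgement
belongs to the user. Divergence counts are reported as 0: the concept does
not exist for gradient-free ensemble moves. A gradient-based sampler is
unnecessary here precisely because the latent layer has been marginalized;
the remaining posterior is low-dimensional and mild.

## Likelihood for summary-statistics studies

A study reporting only (M, S, N) — sample mean and SD of N undeformed
thicknesses — contributes the exact sampling density f(M, S; μ_pop, σ) of
the mean and n−1 SD of N iid LN(μ_pop, σ) variables, σ = √(σ_pop²+σ_pat²)
(each summary sample is treated as its own patient). No closed form
exists; the package computes it by characteristic functions:

1. (M, S) is a bijection of V = (ΣTᵢ, ΣTᵢ²) with Jacobian 2N(N−1)S;
2. the characteristic function of one (T, T²) pair is a 1-D integral
   against the lognormal density;
3. the N-fold convolution is its N-th power (convolution theorem);
4. a trapezoidal inverse Fourier transform on a window around the sum's
   mass gives the density of V, and the change of variables gives f(M, S).

Four design choices make this exact-to-quadrature scheme robust and fast:

- **Scale equivariance.** f(M, S; μ, σ) = e^{−2μ} f(Me^{−μ}, Se^{−μ}; 0, σ),
  so transforms are built only at μ = 0, one per (σ, N), and cached
  process-wide.
- **Decorrelating rotation.** V₁ and V₂ are nearly perfectly correlated for
  small σ; the density is computed for U = (V₁, V₂ − βV₁) with
  β = Cov(T, T²)/Var(T), which keeps the frequency lattice axis-aligned and
  small at every σ. The phase ω₁t + ω₂(t² − βt) remains separable, so the
  characteristic function is two matrix multiplications.
- **Robust windows.** The inversion window is centred on both the moment
  mean and N× the per-sample median, and sized by an IQR-based bulk scale;
  for skewed σ the moment SD is dominated by rare large samples and would
  leave the bulk unresolved. The frequency lattice period is 1.6× the
  window so periodization wrap-around cannot land inside it.
- **Band limiting with a smooth taper.** The sum's characteristic function
  retains long, low-amplitude tails (micro-structure inherited from the
  square-root singularity of the density of T² − βT). Truncating them
  abruptly rings at the amplitude of the dropped tail; instead the lattice
  extends to 28/bulk-scale — where the Gaussian bulk's CF is ~e^{−400} —
  and a Tukey taper (flat inner 70%) rolls off whatever remains. The
  effect is a controlled smoothing at a scale far below the statistical
  scale of the density. The inversion grid is resolved to 1.5× the band's
  Nyquist rate so the bicubic spline of log f sees every representable
  feature.

The recovered density must integrate to 1 ± 0.01 over its window or the
build fails with a mass report. Against Monte-Carlo histograms (10⁶
replicates) the bulk sup-norm relative error is ≲4% at the study sample
sizes (N = 34, 90) for σ ≤ ~0.85; beyond that the heavy-tailed transform
degrades and the mass check rejects it. Inside the sampler the summary
likelihood is a precomputed bicubic interpolant of log f on a 100×80
(μ_pop, σ) grid spanning the prior box up to σ = 0.85 (log-spaced in σ).
Before splining, the tabulated log-likelihood is clamped to a 60-nat range
below its maximum: a 60-nat deficit is already decisive, and bounding the
step height keeps the bicubic surface free of overshoot spikes at the
cliff between the valid region and the far-tail floor (unbounded cliffs
produce spurious interpolation maxima that can trap ensemble walkers).
For σ outside [0.06, 0.85] the model evaluates at the clamped σ minus a
smooth quadratic penalty — under any of the study datasets that region
lies hundreds of nats below the posterior bulk, so only a well-behaved
gradient is required there, not an accurate density.

Per-study diagnostic surfaces (`loglik_surface`, 100×100 by default) peak
within one grid cell of the method-of-moments estimate
σ̂² = ln(1 + S²/M²), μ̂ = ln M − σ̂²/2, and larger studies produce visibly
more concentrated surfaces.

## Predictive distribution and pressure correction

The posterior predictive draw of a new sample is
T ~ LN(μ_pop, √(σ_pop² + σ_pat²)) per retained posterior draw. For
practical use the predictive is summarized by a lognormal fitted by moment
matching on the log scale; lower-tail probabilities P(T < t₁) (thin-wall
risk) follow as Φ((ln t₁ − μ)/σ), reported in percent.

Study-level correction divides each deformed thickness by λ_r(c, k, p)
with (c, k) at their posterior medians (default) or averaged over a
thinned set of posterior draws — the two agree to well under a percent on
the benchmark because λ_r at the study pressures is tightly identified even
though c and k individually are not. Zero-pressure studies pass through
unchanged. The inter-study spread metric is the range (max − min) of study
means and medians before and after correction. Boxplot summaries use
theoretical quantiles at plotting positions i/(n+1) with n = 98 by
default, matching the typical study size.

## Synthetic benchmark: what it shows and what it does not

`six_study_design()` mirrors the design of the published thickness
literature: four raw-data studies at 0, 25, 16 and 1 kPa with 39, 251, 90
and 92 samples (25, 113, 45 and 75 patients — surplus samples are assigned
to random patients, most patients stay singletons), and two non-contact
studies reduced to (M, S, N) with N = 34 and 90. Default truth:
μ_pop = 0.85, σ_pop = 0.26, σ_pat = 0.18 (literature-scale values, mm on
the log scale) and mid-range material stiffness c = 5, k = 20 kPa.
Generation uses the exact nonlinear inversion, not the emulator, so fits
also absorb the (≤10⁻³) emulator error.

The generator implements the model exactly: no residual measurement error
on t beyond the deterministic compression, no calcification-induced
stiffness heterogeneity, no covariate effects, and a single (c, k) for all
patients. Passing the benchmark therefore demonstrates correctness of the
inference machinery (likelihoods, transforms, sampler) and identifiability
under the realistic design — it does not validate the constitutive
assumptions against real tissue. On real data the pressure correction
removes only the protocol-induced part of the inter-study spread; on the
synthetic benchmark it removes nearly all of it, because there no other
source exists.

Desk-scale defaults (4 chains × 2000 draws) keep a full benchmark fit
around half a minute after the one-time transform-grid build; the
literature-scale setting (20 chains × 10 000 draws) is available behind
`paper_scale`. Calibration: across 20 replicate benchmark fits, all five
generating parameters fall inside their 95% credible intervals in ≥ 90% of
runs; with ≥ 2 samples per patient both variance components are separately
identified, while a singletons-only design pins only √(σ_pop² + σ_pat²)
and leaves the components on a ridge — both behaviours are asserted in the
tests.

## Known limitations

- The summary-statistics transform is validated for σ ≤ ~0.85 at the study
  sample sizes; far outside that the model substitutes a penalized clamp
  (documented above). Real thickness data live near σ ≈ 0.32.
- The constitutive layer assumes ideal unconstrained uniaxial compression;
  friction against the measurement fixture and calcifications are not
  modelled.
- c and k are population constants; patient-specific stiffness is not
  identifiable from available designs.
- The n−1 (sample) SD convention is assumed for summary studies.
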