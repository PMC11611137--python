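"""Radial compression of anisotropic, incompressible arterial tissue.

The wall is modelled as a fibre-reinforced Holzapfel--Gasser--Ogden (HGO)
solid: a neo-Hookean ground matrix of stiffness ``c`` plus two symmetric
fibre families at +/- ``phi`` from the circumferential direction, with
initial stiffness ``k`` and exponential stiffening exponent ``k2``.  A
thickness gauge pressing on a specimen applies a known contact pressure
``p_r`` [kPa]; the tissue compresses radially (stretch ``lambda_r`` < 1)
while its traction-free in-plane faces expand.  This module computes the
pressure <-> stretch relation, emulates it with a smooth response surface
``lambda_r(c, k, p)`` usable inside a likelihood, and derives the
small-strain equibiaxial stiffness implied by a parameter draw.

All stresses and stiffnesses are in kPa, stretches dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator, RectBivariateSpline
from scipy.optimize import brentq

__all__ = [
    "HGOParams",
    "DeformationState",
    "ResponseSurface",
    "strain_energy",
    "radial_stress",
    "invert_pressure",
    "build_response_surface",
    "equibiaxial_initial_stiffness",
]

# Exponents above this are clamped to avoid overflow inside root brackets;
# the admissible solution region never gets near it.
_EXP_CLAMP = 500.0

#: Default public radial-stretch range of the emulator.
DEFAULT_LAMBDA_RANGE = (0.61, 1.0)

#: Wider internal range used while inverting, so the node function stays
#: smooth in (c, k) even where the public range cannot reach the pressure.
_LAMBDA_EXTENDED = 0.25


@dataclass(frozen=True)
class HGOParams:
    """HGO constitutive parameters.

    c : ground-matrix (neo-Hookean) stiffness [kPa]
    k : fibre initial stiffness [kPa]
    k2 : fibre stiffening exponent [-]
    phi : fibre declination from the circumferential direction [rad];
          the two families sit at +phi and -phi.
    """

    c: float
    k: float
    k2: float = 15.0
    phi: float = 0.546

    def __post_init__(self) -> None:
        if self.c < 0 or self.k < 0 or self.k2 < 0:
            raise ValueError("c, k and k2 must be non-negative")
        if not 0.0 <= self.phi <= np.pi / 2:
            raise ValueError("phi must lie in [0, pi/2]")


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches of a volumetrically incompressible deformation."""

    lambda_c: float
    lambda_a: float
    lambda_r: float

    def __post_init__(self) -> None:
        if min(self.lambda_c, self.lambda_a, self.lambda_r) <= 0:
            raise ValueError("all stretches must be positive")
        if abs(self.J - 1.0) > 1e-10:
            raise ValueError(f"incompressibility violated: J = {self.J!r}")

    @property
    def J(self) -> float:
        return self.lambda_c * self.lambda_a * self.lambda_r


def _fiber_invariant(lam_c, lam_a, phi):
    """I4 = a01 . C a01 for a01 = (cos phi, sin phi, 0); equals I6."""
    return lam_c**2 * np.cos(phi) ** 2 + lam_a**2 * np.sin(phi) ** 2


def _psi4(k, k2, i4):
    """dPsi_aniso/dI4 for one fibre family, with tension-only switch."""
    ex = np.clip(k2 * (i4 - 1.0) ** 2, None, _EXP_CLAMP)
    return np.where(i4 > 1.0, k * (i4 - 1.0) * np.exp(ex), 0.0)


def strain_energy(params: HGOParams, state: DeformationState) -> float:
    """HGO strain-energy density [kPa] at an incompressible state.

    Psi = c/2 (I1 - 3) + k/(2 k2) sum_{i in {4,6}} [exp(k2 (Ii-1)^2) - 1],
    where each anisotropic term contributes only if its fibre family is
    extended (Ii > 1).  With J = 1 the deviatoric invariants coincide with
    the plain ones.
    """
    lc, la, lr = state.lambda_c, state.lambda_a, state.lambda_r
    i1 = lc**2 + la**2 + lr**2
    psi = params.c / 2.0 * (i1 - 3.0)
    # I4 == I6 for +/-phi families under diagonal stretch, but keep both
    # terms explicit.
    for i in (_fiber_invariant(lc, la, params.phi),) * 2:
        if i > 1.0 and params.k > 0 and params.k2 > 0:
            psi += params.k / (2.0 * params.k2) * (
                np.exp(min(params.k2 * (i - 1.0) ** 2, _EXP_CLAMP)) - 1.0
            )
        elif i > 1.0 and params.k > 0:
            # k2 -> 0 limit: quadratic standard-reinforcing term
            psi += params.k / 2.0 * (i - 1.0) ** 2
    return float(psi)


def _inplane_residual(lam_c, lam_r, c, k, k2, phi):
    """sigma_cc - sigma_aa with lambda_a = 1/(lambda_r lambda_c).

    Zero at in-plane equilibrium (both lateral faces traction free after the
    hydrostatic pressure is eliminated).
    """
    lam_a = 1.0 / (lam_r * lam_c)
    i4 = _fiber_invariant(lam_c, lam_a, phi)
    p4 = _psi4(k, k2, i4)
    return c * (lam_c**2 - lam_a**2) + 4.0 * p4 * (
        lam_c**2 * np.cos(phi) ** 2 - lam_a**2 * np.sin(phi) ** 2
    )


def _solve_inplane(lam_r, c, k, k2, phi, iters: int = 55):
    """Vectorized bisection for the equilibrium circumferential stretch.

    All arguments broadcast; returns lambda_c of the same shape.
    """
    lam_r = np.asarray(lam_r, dtype=float)
    s = lam_r**-0.5  # isotropic guess
    lo = np.broadcast_to(0.05 * s, np.broadcast_shapes(lam_r.shape, np.shape(c))).copy()
    hi = np.broadcast_to(20.0 * s, lo.shape).copy()
    flo = _inplane_residual(lo, lam_r, c, k, k2, phi)
    fhi = _inplane_residual(hi, lam_r, c, k, k2, phi)
    # residual -> -inf as lam_c -> 0 and +inf as lam_c -> inf
    if np.any(flo > 0) or np.any(fhi < 0):
        raise RuntimeError("in-plane equilibrium bracket failed")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = _inplane_residual(mid, lam_r, c, k, k2, phi)
        take_lo = fm <= 0
        lo = np.where(take_lo, mid, lo)
        hi = np.where(take_lo, hi, mid)
    return 0.5 * (lo + hi)


def _radial_fpk(lam_r, c, k, k2, phi):
    """Compressive radial first-Piola-Kirchhoff stress magnitude [kPa].

    Solves in-plane equilibrium, eliminates the hydrostatic pressure via the
    traction-free circumferential face, and returns |P_rr| = (p_h - c
    lambda_r^2)/lambda_r.  Vectorized over broadcastable inputs.
    """
    lam_r = np.asarray(lam_r, dtype=float)
    lam_c = _solve_inplane(lam_r, c, k, k2, phi)
    lam_a = 1.0 / (lam_r * lam_c)
    i4 = _fiber_invariant(lam_c, lam_a, phi)
    p4 = _psi4(k, k2, i4)
    p_h = c * lam_c**2 + 4.0 * p4 * lam_c**2 * np.cos(phi) ** 2
    sig_rr = c * lam_r**2 - p_h
    return -sig_rr / lam_r


def radial_stress(params: HGOParams, lambda_r: float) -> float:
    """Contact pressure [kPa] needed to hold the wall at radial stretch
    ``lambda_r`` (first Piola-Kirchhoff, force per undeformed area).

    Strictly increasing as ``lambda_r`` decreases; zero at ``lambda_r`` = 1.
    """
    if not 0.0 < lambda_r <= 1.0:
        raise ValueError(f"lambda_r must lie in (0, 1], got {lambda_r}")
    return float(_radial_fpk(lambda_r, params.c, params.k, params.k2, params.phi))


def invert_pressure(
    params: HGOParams,
    p_r: float,
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
    tol: float = 1e-10,
) -> float:
    """Radial stretch at which the wall carries contact pressure ``p_r``.

    Root of ``radial_stress(params, .) - p_r`` on ``lambda_range`` by Brent's
    method.  ``p_r = 0`` returns 1 exactly.
    """
    lo, hi = lambda_range
    if p_r < 0:
        raise ValueError("contact pressure must be non-negative")
    if p_r == 0.0:
        return 1.0
    p_max = radial_stress(params, lo)
    if p_r > p_max:
        raise ValueError(
            f"pressure {p_r} kPa outside the admissible interval [0, "
            f"{p_max:.6g}] kPa spanned by lambda_r in [{lo}, {hi}] for {params}"
        )
    try:
        return float(
            brentq(lambda l: radial_stress(params, l) - p_r, lo, hi, xtol=tol)
        )
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"pressure inversion failed for {params} at p_r={p_r}: {exc}"
        ) from exc


def _invert_nodes(c, k, k2, phi, pressure, lam_lo, iters: int = 48):
    """Vectorized bisection inverting pressure -> lambda_r over (c, k) arrays.

    Where the pressure is unreachable even at ``lam_lo`` (very soft corner of
    the grid) the result is floored at ``lam_lo``.
    """
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    lo = np.full(np.broadcast_shapes(c.shape, k.shape), lam_lo)
    hi = np.ones_like(lo)
    p_at_lo = _radial_fpk(lo, c, k, k2, phi)
    reachable = p_at_lo >= pressure
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        pm = _radial_fpk(mid, c, k, k2, phi)
        # pressure decreases as lambda_r increases
        go_up = pm >= pressure
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    out = 0.5 * (lo + hi)
    return np.where(reachable, out, lam_lo)


# Spline axes are transformed coordinates in which the response is mild:
# lambda_r varies like sqrt(ln(1/k)) as k -> 0 (the exponential fibre term
# switches on), so the k axis is logarithmic; the c axis is square-root.
_K_OFFSET = 0.05


def _c_axis(c):
    return np.sqrt(np.asarray(c, dtype=float))


def _k_axis(k):
    return np.log(np.asarray(k, dtype=float) + _K_OFFSET)


def _axis_grid(lo: float, hi: float, n: int, transform) -> np.ndarray:
    """Physical grid uniform in the transformed coordinate."""
    u = np.linspace(float(transform(lo)), float(transform(hi)), n)
    if transform is _c_axis:
        return u**2
    return np.exp(u) - _K_OFFSET


class ResponseSurface:
    """Smooth emulator of the radial stretch ``lambda_r(c, k, p)``.

    Per build pressure, a bicubic tensor spline over a non-uniform (c, k)
    grid; across pressure, monotone piecewise-cubic interpolation through
    the per-pressure values (with the exact plane lambda_r = 1 at p = 0).
    Evaluation is clipped to the public stretch range.
    """

    def __init__(
        self,
        c_grid: np.ndarray,
        k_grid: np.ndarray,
        pressures: np.ndarray,
        values: np.ndarray,
        k2: float,
        phi: float,
        lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
        metadata: dict | None = None,
        spline_degree: int = 3,
    ) -> None:
        self.c_grid = np.asarray(c_grid, dtype=float)
        self.k_grid = np.asarray(k_grid, dtype=float)
        self.pressures = np.asarray(pressures, dtype=float)
        self.values = np.asarray(values, dtype=float)  # (n_p, n_c, n_k)
        self.k2 = float(k2)
        self.phi = float(phi)
        self.lambda_range = (float(lambda_range[0]), float(lambda_range[1]))
        self.metadata = dict(metadata or {})
        self.spline_degree = int(spline_degree)
        self._splines = {}
        uc, uk = _c_axis(self.c_grid), _k_axis(self.k_grid)
        for i, p in enumerate(self.pressures):
            if p == 0.0:
                continue
            self._splines[float(p)] = RectBivariateSpline(
                uc, uk, self.values[i],
                kx=self.spline_degree, ky=self.spline_degree, s=0,
            )

    def _eval_at_pressure(self, c, k, p: float):
        if p == 0.0:
            return np.ones(np.broadcast_shapes(np.shape(c), np.shape(k)))
        vals = self._splines[float(p)].ev(_c_axis(c), _k_axis(k))
        return np.clip(vals, self.lambda_range[0], self.lambda_range[1])

    def __call__(self, c, k, p):
        """Evaluate lambda_r at (c, k, p); c, k may be arrays, p scalar."""
        c = np.asarray(c, dtype=float)
        k = np.asarray(k, dtype=float)
        p = float(p)
        if p < 0:
            raise ValueError("contact pressure must be non-negative")
        ps = [float(x) for x in self.pressures]
        if p in ps:
            out = self._eval_at_pressure(c, k, p)
        else:
            if not self.pressures.min() <= p <= self.pressures.max():
                raise ValueError(
                    f"pressure {p} kPa outside the built range "
                    f"[{self.pressures.min()}, {self.pressures.max()}] kPa"
                )
            cols = np.stack([self._eval_at_pressure(c, k, q) for q in ps], axis=-1)
            out = PchipInterpolator(self.pressures, cols, axis=-1)(p)
        return out if out.shape else float(out)

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "c_grid": self.c_grid.tolist(),
            "k_grid": self.k_grid.tolist(),
            "pressures": self.pressures.tolist(),
            "values": self.values.tolist(),
            "k2": self.k2,
            "phi": self.phi,
            "lambda_range": list(self.lambda_range),
            "metadata": self.metadata,
            "spline_degree": self.spline_degree,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseSurface":
        return cls(
            np.array(d["c_grid"]),
            np.array(d["k_grid"]),
            np.array(d["pressures"]),
            np.array(d["values"]),
            d["k2"],
            d["phi"],
            tuple(d["lambda_range"]),
            d.get("metadata"),
            d.get("spline_degree", 3),
        )

    @classmethod
    def load(cls, path) -> "ResponseSurface":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_response_surface(
    c_range: tuple[float, float] = (0.0, 10.0),
    k_range: tuple[float, float] = (0.0, 40.0),
    pressures: Sequence[float] = (0.0, 1.0, 16.0, 25.0),
    n_c: int = 40,
    n_k: int = 40,
    k2: float = 15.0,
    phi: float = 0.546,
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
    tol: float = 1e-3,
    n_check: int = 100,
    seed: int = 0,
    spline_degree: int = 3,
) -> ResponseSurface:
    """Tabulate and fit the emulator lambda_r(c, k, p).

    Nodes are found by bisecting the full nonlinear pressure-stretch relation
    on an extended stretch range (so the tabulated function stays smooth in c
    and k even where the public range saturates), fitted with per-pressure
    bicubic splines, then validated against the direct inversion on
    ``n_check`` random off-grid points.  Raises if the measured worst-case
    stretch error exceeds ``tol``.
    """
    pressures = np.sort(np.unique(np.asarray(pressures, dtype=float)))
    if pressures[0] != 0.0:
        pressures = np.concatenate([[0.0], pressures])
    c_grid = _axis_grid(*c_range, n_c, _c_axis)
    k_grid = _axis_grid(*k_range, n_k, _k_axis)
    cc, kk = np.meshgrid(c_grid, k_grid, indexing="ij")
    values = np.ones((len(pressures), n_c, n_k))
    for i, p in enumerate(pressures):
        if p == 0.0:
            continue
        values[i] = _invert_nodes(cc, kk, k2, phi, p, _LAMBDA_EXTENDED)
    surf = ResponseSurface(
        c_grid, k_grid, pressures, values, k2, phi, lambda_range,
        spline_degree=spline_degree,
    )

    rng = np.random.default_rng(seed)
    worst = 0.0
    lo, hi = lambda_range
    for _ in range(n_check):
        c = rng.uniform(*c_range)
        k = rng.uniform(*k_range)
        p = float(rng.choice(pressures))
        approx = float(surf(c, k, p))
        node = float(
            _invert_nodes(np.array(c), np.array(k), k2, phi, p, _LAMBDA_EXTENDED)
        ) if p > 0 else 1.0
        exact = min(max(node, lo), hi)
        worst = max(worst, abs(approx - exact))
    if worst > tol:
        raise RuntimeError(
            f"response surface too coarse: max |d lambda_r| = {worst:.3e} > {tol}"
        )
    surf.metadata.update(
        {
            "achieved_max_error": worst,
            "tol": tol,
            "n_c": n_c,
            "n_k": n_k,
            "c_range": list(c_range),
            "k_range": list(k_range),
            "seed": seed,
        }
    )
    return surf


def _equibiaxial_fpk(params: HGOParams, lam: float) -> tuple[float, float]:
    """In-plane FPK stresses (circ, axial) on the equibiaxial path
    lambda_c = lambda_a = lam, lambda_r = lam^-2, radial face traction-free."""
    i4 = _fiber_invariant(lam, lam, params.phi)  # = lam^2
    p4 = float(_psi4(params.k, params.k2, i4))
    p_h = params.c * lam**-4
    sig_cc = params.c * lam**2 - p_h + 4.0 * p4 * lam**2 * np.cos(params.phi) ** 2
    sig_aa = params.c * lam**2 - p_h + 4.0 * p4 * lam**2 * np.sin(params.phi) ** 2
    return sig_cc / lam, sig_aa / lam


def equibiaxial_initial_stiffness(
    params: HGOParams, strain: float = 1e-3
) -> tuple[float, float]:
    """Small-strain tangent moduli (E0_circ, E0_axial) [kPa] of the predicted
    equibiaxial tension response: forward-difference slope of FPK stress vs
    stretch at ``strain`` on the tension side (fibres engaged)."""
    p1c, p1a = _equibiaxial_fpk(params, 1.0)
    p2c, p2a = _equibiaxial_fpk(params, 1.0 + strain)
    return (p2c - p1c) / strain, (p2a - p1a) / strain
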