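"""Closed-form SFDI diffuse-reflectance models and their pencil-beam roots.

Three closed-form models give the diffuse reflectance of a semi-infinite
turbid medium under sinusoidal illumination as a function of spatial
frequency f:

* ``CUCCIA`` — the plane-illumination diffusion solution with the
  ``mu_eff -> mu_eff'`` substitution,
  R = 3 a' / [(2 A t + 3)(t + 1)] with t = mu_eff'/mu_tr.
* ``PCBC`` — obtained by Hankel-transforming the pencil-beam Green's
  function under the partial-current boundary condition and integrating
  over an exponentially distributed source depth,
  R = a' / ((4A/3) t) * (1 - exp(-(4A/3) t)) / (1 + t).
* ``EBC`` — same route under the extrapolated-boundary (image-source)
  condition, R = (a'/2) (1 + exp(-(4A/3) t)) / (1 + t).

The module also exposes the radial pencil-beam Green's functions, the
distributed source term S(z) = a' mu_tr exp(-mu_tr z), their source-depth
integral R(rho), and zeroth-order Hankel transforms (continuous and
binned), which together form the independent numerical route against
which the closed forms are validated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import special

from .optics import (
    BoundaryParams,
    DiffusionParams,
    OpticalProperties,
    derive_diffusion_params,
    mu_eff_prime,
)

__all__ = [
    "GreenFunctionInputs",
    "ModelId",
    "reflectance_model",
    "radial_green",
    "source_term",
    "radial_reflectance",
    "hankel_transform_continuous",
    "hankel_transform_binned",
]

#: First positive zero of the Bessel function J0.
_J0_FIRST_ZERO = 2.404825557695773


@dataclass(frozen=True)
class GreenFunctionInputs:
    """Scalar geometry of one Green's-function evaluation.

    ``r1`` is the distance to the real source at depth ``z0``, ``r2`` the
    distance to its image across the extrapolated boundary at ``-2 z_b``.
    """

    rho: float
    z0: float
    z_b: float

    def __post_init__(self) -> None:
        if self.rho < 0 or self.z0 < 0 or self.z_b < 0:
            raise ValueError("rho, z0 and z_b must be non-negative")
        if self.rho == 0 and self.z0 == 0:
            raise ValueError("rho = z0 = 0 is singular")

    @property
    def r1(self) -> float:
        return float(np.hypot(self.z0, self.rho))

    @property
    def r2(self) -> float:
        return float(np.hypot(self.z0 + 2.0 * self.z_b, self.rho))


class ModelId(enum.Enum):
    """Closed enumeration of the diffuse-reflectance models."""

    CUCCIA = "cuccia"
    PCBC = "pcbc"
    EBC = "ebc"

    @classmethod
    def parse(cls, name: "str | ModelId") -> "ModelId":
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name).lower())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown model {name!r}; expected one of {valid}") from None


def _expm1_ratio(x):
    """(1 - exp(-x)) / x, stable at x -> 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def reflectance_model(
    model: ModelId | str,
    props: OpticalProperties,
    f,
    boundary: BoundaryParams,
    diffusion_coefficient: str = "mus_plus_mua",
):
    """Closed-form diffuse reflectance at spatial frequency ``f`` (mm^-1).

    Vectorized over ``f``. All three models return the reduced albedo a'
    in the limit mu_eff'/mu_tr -> 0 and decrease strictly with f.
    """
    model = ModelId.parse(model)
    dp = derive_diffusion_params(props, diffusion_coefficient)
    t = np.asarray(mu_eff_prime(dp, f)) / dp.mu_tr
    a = dp.albedo_reduced
    A = boundary.A
    if model is ModelId.CUCCIA:
        out = 3.0 * a / ((2.0 * A * t + 3.0) * (t + 1.0))
    elif model is ModelId.PCBC:
        x = (4.0 * A / 3.0) * t
        out = a * _expm1_ratio(x) / (1.0 + t)
    else:  # EBC
        x = (4.0 * A / 3.0) * t
        out = 0.5 * a * (1.0 + np.exp(-x)) / (1.0 + t)
    return float(out) if out.ndim == 0 else out


def radial_green(
    model: ModelId | str,
    rho,
    z0,
    dp: DiffusionParams,
    boundary: BoundaryParams,
):
    """Radial diffuse-reflectance Green's function of a pencil beam (mm^-2).

    ``rho`` is the radial distance from the entry point on the surface and
    ``z0`` the depth of the isotropic point source. Under the
    partial-current boundary condition:

        R(rho, z0) = 1/(8 pi A D) [exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2]

    and under the extrapolated-boundary condition the familiar dipole form

        R(rho, z0) = 1/(4 pi) [ z0 (mu_eff + 1/r1) exp(-mu_eff r1)/r1^2
                     + (z0 + 2 z_b)(mu_eff + 1/r2) exp(-mu_eff r2)/r2^2 ],

    with r1 = sqrt(z0^2 + rho^2), r2 = sqrt((z0 + 2 z_b)^2 + rho^2) and
    z_b = 2 A D.
    """
    model = ModelId.parse(model)
    if model is ModelId.CUCCIA:
        raise ValueError("no pencil-beam Green's function is defined for CUCCIA")
    rho = np.asarray(rho, dtype=float)
    z0 = np.asarray(z0, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be >= 0")
    if np.any(z0 < 0) or np.any((z0 == 0) & (rho == 0)):
        raise ValueError("source depth z0 must be > 0 when rho = 0 (singular input)")
    zb = boundary.z_b(dp)
    mu = dp.mu_eff
    r1 = np.hypot(z0, rho)
    r2 = np.hypot(z0 + 2.0 * zb, rho)
    if model is ModelId.PCBC:
        out = (np.exp(-mu * r1) / r1 - np.exp(-mu * r2) / r2) / (
            8.0 * np.pi * boundary.A * dp.D
        )
    else:  # EBC
        out = (
            z0 * (mu + 1.0 / r1) * np.exp(-mu * r1) / r1**2
            + (z0 + 2.0 * zb) * (mu + 1.0 / r2) * np.exp(-mu * r2) / r2**2
        ) / (4.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def source_term(z, dp: DiffusionParams):
    """Distributed source S(z) = a' mu_tr exp(-mu_tr z) (mm^-1).

    Integrates to the reduced albedo a' over z in [0, inf).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0")
    out = dp.albedo_reduced * dp.mu_tr * np.exp(-dp.mu_tr * z)
    return float(out) if out.ndim == 0 else out


def _gauss_panels(edges: np.ndarray, order: int = 20):
    """Gauss-Legendre nodes/weights on a sequence of panels, flattened."""
    x, w = np.polynomial.legendre.leggauss(order)
    a = edges[:-1, None]
    b = edges[1:, None]
    half = 0.5 * (b - a)
    nodes = (0.5 * (a + b) + half * x[None, :]).ravel()
    weights = (half * w[None, :]).ravel()
    return nodes, weights


def _z0_edges(dp: DiffusionParams, z0_max: float) -> np.ndarray:
    """Panel edges resolving the exp(-mu_tr z0) source scale up to z0_max."""
    h = 1e-3 / dp.mu_tr
    edges = [0.0]
    while edges[-1] < z0_max:
        edges.append(min(edges[-1] + h, z0_max))
        h *= 2.0
    return np.asarray(edges)


def radial_reflectance(
    model: ModelId | str,
    rho,
    dp: DiffusionParams,
    boundary: BoundaryParams,
    z0_max: float = 100.0,
    order: int = 20,
):
    """Pencil-beam radial reflectance R(rho) = int_0^z0_max G(rho, z0) S(z0) dz0.

    Composite Gauss-Legendre quadrature on geometrically growing panels
    that resolve the exponential source scale 1/mu_tr; with the default
    ``z0_max`` = 100 mm the truncation error is far below 1e-6 relative
    for every medium on the evaluation grid. Vectorized over ``rho``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    if z0_max <= 0:
        raise ValueError("z0_max must be > 0")
    z0, w = _gauss_panels(_z0_edges(dp, z0_max), order)
    g = radial_green(model, rho[..., None], z0, dp, boundary)
    out = np.sum(g * source_term(z0, dp) * w, axis=-1)
    return float(out) if out.ndim == 0 else out


def hankel_transform_continuous(
    R_of_rho: Callable[[np.ndarray], np.ndarray],
    f: float,
    rho_max: float = 500.0,
    rtol: float = 1e-8,
    order: int = 10,
    batch: int = 256,
) -> float:
    """Zeroth-order Hankel transform 2 pi int_0^rho_max rho J0(2 pi f rho) R(rho) drho.

    ``R_of_rho`` must accept a numpy array. For f > 0 the oscillatory
    kernel is integrated panel-wise between consecutive half-periods of
    J0 (first panel up to the first zero), in batches, stopping once two
    consecutive batches each contribute less than ``rtol`` relative to the
    accumulated value; plain panel quadrature is used at f = 0 where the
    kernel is 1.
    """
    if rho_max <= 0:
        raise ValueError("rho_max must be > 0")
    k = 2.0 * np.pi * f

    def integrand(rho):
        return 2.0 * np.pi * rho * special.j0(k * rho) * np.asarray(R_of_rho(rho))

    # Panel width must resolve both the J0 half-period and the envelope of
    # R(rho), whose sharpest structure sits near the origin: use geometric
    # (one-per-octave) steps capped at the oscillation half-period.
    h0 = min(1e-3, 1e-3 * rho_max)
    half = np.pi / k if k > 0.0 else np.inf
    total = 0.0
    small_batches = 0
    edge = 0.0
    while edge < rho_max:
        edges = [edge]
        while len(edges) - 1 < batch and edges[-1] < rho_max:
            step = min(max(edges[-1], h0), half)
            edges.append(min(edges[-1] + step, rho_max))
        nodes, w = _gauss_panels(np.asarray(edges), order)
        contrib = float(np.sum(integrand(nodes) * w))
        total += contrib
        edge = edges[-1]
        if abs(contrib) <= rtol * max(abs(total), 1e-300):
            small_batches += 1
            if small_batches >= 2:
                break
        else:
            small_batches = 0
    return total


def hankel_transform_binned(rr, f_list: Sequence[float]) -> np.ndarray:
    """Hankel transform of a binned radial-reflectance profile.

    Midpoint-rule sum 2 pi sum_i rho_i J0(2 pi f rho_i) R_i drho per
    frequency. ``rr`` is a :class:`~sfdikit.montecarlo.RadialReflectance`
    or any object with ``bin_centers``, ``values`` and ``bin_width``.
    At f = 0 this equals the total detected diffuse reflectance.
    """
    centers = np.asarray(rr.bin_centers, dtype=float)
    values = np.asarray(rr.values, dtype=float)
    if centers.size == 0:
        raise ValueError("empty radial profile")
    f = np.asarray(f_list, dtype=float)
    kernel = special.j0(2.0 * np.pi * f[:, None] * centers[None, :])
    out = 2.0 * np.pi * rr.bin_width * kernel @ (centers * values)
    return out
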