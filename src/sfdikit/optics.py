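"""Fundamental optical quantities for diffuse light transport.

Defines the medium description (absorption and reduced scattering), the
derived diffusion-theory parameters, and the boundary description of a
semi-infinite turbid medium with a refractive-index mismatch: the
unpolarized Fresnel reflectance, the internal-reflection parameter ``A``
obtained from angular Fresnel integrals, the effective reflectance
``R_eff``, and the extrapolation distance ``z_b = 2 A D``.

Units are millimetres throughout: coefficients in mm^-1, distances in mm,
spatial frequency ``f`` in mm^-1 (the angular wavenumber ``k = 2 pi f`` is
internal to the model formulas).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

__all__ = [
    "OpticalProperties",
    "DiffusionParams",
    "BoundaryParams",
    "derive_diffusion_params",
    "mu_eff_prime",
    "fresnel_unpolarized",
    "compute_A",
]


@dataclass(frozen=True)
class OpticalProperties:
    """One homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1), >= 0.
    mu_s_prime : float
        Reduced scattering coefficient mu_s * (1 - g1) (mm^-1), > 0.
    """

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not self.mu_a >= 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if not self.mu_s_prime > 0:
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion-theory parameters derived from :class:`OpticalProperties`.

    Attributes
    ----------
    D : float
        Diffusion coefficient (mm).
    mu_tr : float
        Transport coefficient mu_a + mu_s' (mm^-1).
    mu_eff : float
        Effective attenuation coefficient sqrt(mu_a / D) (mm^-1).
    albedo_reduced : float
        Reduced albedo a' = mu_s' / mu_tr, in [0, 1].
    """

    D: float
    mu_tr: float
    mu_eff: float
    albedo_reduced: float


def derive_diffusion_params(
    props: OpticalProperties,
    diffusion_coefficient: str = "mus_plus_mua",
) -> DiffusionParams:
    """Derive diffusion parameters from a medium description.

    ``diffusion_coefficient`` selects whether absorption enters the
    diffusion coefficient: ``"mus_plus_mua"`` gives D = 1/(3 (mu_s' + mu_a))
    (the default, used for all comparisons here so that every model shares
    the same D), ``"mus_only"`` gives D = 1/(3 mu_s').
    """
    mu_tr = props.mu_a + props.mu_s_prime
    if diffusion_coefficient == "mus_plus_mua":
        D = 1.0 / (3.0 * mu_tr)
    elif diffusion_coefficient == "mus_only":
        D = 1.0 / (3.0 * props.mu_s_prime)
    else:
        raise ValueError(
            "diffusion_coefficient must be 'mus_plus_mua' or 'mus_only', "
            f"got {diffusion_coefficient!r}"
        )
    mu_eff = math.sqrt(props.mu_a / D)
    return DiffusionParams(
        D=D,
        mu_tr=mu_tr,
        mu_eff=mu_eff,
        albedo_reduced=props.mu_s_prime / mu_tr,
    )


def mu_eff_prime(dp: DiffusionParams, f):
    """Spatial-frequency generalized attenuation sqrt(mu_eff^2 + (2 pi f)^2).

    ``f`` is the projected spatial frequency in mm^-1 (scalar or array).
    At f = 0 this reduces exactly to ``dp.mu_eff``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("spatial frequency f must be >= 0")
    out = np.hypot(dp.mu_eff, 2.0 * np.pi * f)
    return float(out) if out.ndim == 0 else out


def fresnel_unpolarized(cos_theta, n_in: float, n_out: float):
    """Unpolarized Fresnel reflectance at the internal boundary.

    ``cos_theta`` is the cosine of the angle of incidence measured inside
    the medium of index ``n_in`` against the surface normal; ``n_out`` is
    the index of the external medium. Returns the average of the s- and
    p-polarized power reflectances, and 1 beyond the critical angle when
    ``n_in > n_out`` (total internal reflection).
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    c = np.asarray(cos_theta, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("cos_theta must lie in [0, 1]")
    if n_in == n_out:
        out = np.zeros_like(c)
        return float(out) if out.ndim == 0 else out
    sin_t = np.sqrt(1.0 - c**2)
    sin_r = (n_in / n_out) * sin_t
    with np.errstate(invalid="ignore"):
        cos_r = np.sqrt(1.0 - sin_r**2)
        rs = ((n_in * c - n_out * cos_r) / (n_in * c + n_out * cos_r)) ** 2
        rp = ((n_out * c - n_in * cos_r) / (n_out * c + n_in * cos_r)) ** 2
        rf = 0.5 * (rs + rp)
    rf = np.where(sin_r >= 1.0, 1.0, rf)
    return float(rf) if rf.ndim == 0 else rf


@lru_cache(maxsize=64)
def compute_A(n_in: float, n_out: float) -> float:
    """Internal-reflection parameter A from angular Fresnel integrals.

    A = (1 + 3 I2) / (1 - 2 I1) with
    I1 = int_0^{pi/2} R_F(cos t) cos t sin t dt,
    I2 = int_0^{pi/2} R_F(cos t) cos^2 t sin t dt.

    The quadrature splits at the critical angle, where R_F has a kink, and
    is cached per (n_in, n_out) so model evaluations never re-integrate.
    For matched indices A = 1 exactly.
    """
    if n_in <= 0 or n_out <= 0:
        raise ValueError("refractive indices must be positive")
    if n_in == n_out:
        return 1.0

    def integrand(theta: float, power: int) -> float:
        c = math.cos(theta)
        return fresnel_unpolarized(c, n_in, n_out) * c**power * math.sin(theta)

    breaks = [0.0, math.pi / 2]
    if n_in > n_out:
        breaks.insert(1, math.asin(n_out / n_in))

    vals = {}
    for power in (1, 2):
        total = 0.0
        for a, b in zip(breaks[:-1], breaks[1:]):
            res, err = integrate.quad(
                integrand, a, b, args=(power,), epsabs=1e-10, epsrel=1e-10
            )
            if err > 1e-6 * max(abs(res), 1.0):
                raise RuntimeError(
                    f"Fresnel integral quadrature did not converge on "
                    f"[{a}, {b}]: estimate {res}, error {err}"
                )
            total += res
        vals[power] = total
    return (1.0 + 3.0 * vals[2]) / (1.0 - 2.0 * vals[1])


@dataclass(frozen=True)
class BoundaryParams:
    """Boundary description of the semi-infinite medium.

    ``A`` is the internal-reflection parameter and
    ``R_eff = (A - 1)/(A + 1)`` the effective reflectance of the boundary.
    Build via :meth:`from_indices` so that A is computed consistently.
    """

    n_in: float
    n_out: float
    A: float

    @classmethod
    def from_indices(cls, n_in: float = 1.33, n_out: float = 1.00) -> "BoundaryParams":
        return cls(n_in=n_in, n_out=n_out, A=compute_A(n_in, n_out))

    @property
    def R_eff(self) -> float:
        return (self.A - 1.0) / (self.A + 1.0)

    def z_b(self, dp: DiffusionParams) -> float:
        """Extrapolation distance z_b = 2 A D (mm)."""
        return 2.0 * self.A * dp.D
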