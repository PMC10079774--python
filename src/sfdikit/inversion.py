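"""Two-frequency extraction of optical properties.

Given the diffuse reflectance at spatial frequency 0 (DC) and one AC
frequency (default 0.5 mm^-1), invert a chosen closed-form model for
(mu_a, mu_s'). With two unknowns and two equations this is a root solve;
it is posed as bounded least squares on log-transformed parameters so
that the two-decade physiological ranges are handled symmetrically and
bound constraints are available when the input is noisy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import optimize

from .models import ModelId, reflectance_model
from .optics import BoundaryParams, OpticalProperties

__all__ = ["InversionResult", "extract_properties"]


@dataclass(frozen=True)
class InversionResult:
    """Extracted properties and solver diagnostics."""

    mu_a_hat: float
    mu_s_prime_hat: float
    residual_norm: float
    converged: bool
    n_iterations: int


def extract_properties(
    model: ModelId | str,
    R_dc: float,
    R_ac: float,
    f_ac: float = 0.5,
    boundary: BoundaryParams | None = None,
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((1e-5, 1.0), (0.1, 100.0)),
    init: Tuple[float, float] = (0.01, 10.0),
    diffusion_coefficient: str = "mus_plus_mua",
) -> InversionResult:
    """Solve model(mu_a, mu_s', 0) = R_dc, model(mu_a, mu_s', f_ac) = R_ac.

    ``bounds`` and ``init`` are ((mu_a_lo, mu_a_hi), (mu_s'_lo, mu_s'_hi))
    and (mu_a0, mu_s'0) in mm^-1. On model-generated input the true
    properties are recovered to better than 1e-6 relative. A solution is
    reported with ``converged=False`` (never silently dropped) when the
    residual cannot be driven to zero within the bounds.
    """
    model = ModelId.parse(model)
    if boundary is None:
        boundary = BoundaryParams.from_indices()
    if f_ac <= 0:
        raise ValueError("f_ac must be > 0")
    if not 0 < R_ac < R_dc < 1:
        raise ValueError(
            "require 0 < R_ac < R_dc < 1 (reflectance decreases with frequency); "
            f"got R_dc={R_dc}, R_ac={R_ac}"
        )
    f_eval = np.array([0.0, f_ac])
    target = np.array([R_dc, R_ac])
    lo = np.log(np.array([bounds[0][0], bounds[1][0]]))
    hi = np.log(np.array([bounds[0][1], bounds[1][1]]))
    x0 = np.clip(np.log(np.array(init, dtype=float)), lo, hi)

    def residual(x: np.ndarray) -> np.ndarray:
        props = OpticalProperties(mu_a=float(np.exp(x[0])), mu_s_prime=float(np.exp(x[1])))
        r = reflectance_model(model, props, f_eval, boundary, diffusion_coefficient)
        return r / target - 1.0

    sol = optimize.least_squares(
        residual,
        x0,
        bounds=(lo, hi),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-12,
        max_nfev=200,
    )
    res_norm = float(np.linalg.norm(sol.fun))
    return InversionResult(
        mu_a_hat=float(np.exp(sol.x[0])),
        mu_s_prime_hat=float(np.exp(sol.x[1])),
        residual_norm=res_norm,
        converged=bool(sol.success and res_norm < 1e-8),
        n_iterations=int(sol.nfev),
    )
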