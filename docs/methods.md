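# Methods

## Models

All three closed-form reflectance models describe the diffuse component
of the reflectance of a semi-infinite homogeneous turbid medium under
sinusoidally modulated wide-field illumination. Spatial frequency `f`
(mm⁻¹) is the public unit throughout; the angular wavenumber `k = 2πf`
appears only inside formulas. The diffusion coefficient includes
absorption, `D = 1/(3(μs′ + μa))`, so that all three models share the
same `D` and differences between them reflect boundary treatment only;
`derive_diffusion_params` accepts `diffusion_coefficient="mus_only"`
for the absorption-free convention.

The Cuccia model is the classical plane-illumination diffusion solution
with `μeff` replaced by `μeff′ = sqrt(μeff² + k²)`. The PCBC and EBC
models are derived from the pencil-beam route: the radial Green's
function `R(ρ, z0)` of an isotropic point source at depth `z0`
(an image pair under the partial-current boundary condition, the
familiar dipole form under the extrapolated boundary), integrated over
an exponentially distributed source depth `S(z0) = a′ μtr e^{−μtr z0}`
and transformed with the zeroth-order Hankel transform
`R(k) = 2π ∫ ρ J0(kρ) R(ρ) dρ`. Carrying out both integrations
analytically and substituting `μeff → μeff′` gives the closed forms with
the exponent argument `(4A/3)(μeff′/μtr)`, which is identically
`2 z_b μeff′` for `z_b = 2AD`; a property test asserts this identity on
random media. The package keeps both routes: the closed forms take `f`
directly, while the numerical route keeps `μeff` in the Green's function
and lets the Hankel kernel carry `f`. The equivalence of the two routes
(closed form vs. numerical transform, better than 1% everywhere on the
evaluation grid, in practice ~1e-5) is the central correctness check.

## Boundary parameter

`A = (1 + 3∫ R_F cos²θ sinθ dθ) / (1 − 2∫ R_F cosθ sinθ dθ)` with the
unpolarized Fresnel reflectance `R_F` of the internal incidence angle.
The quadrature (adaptive Gauss–Kronrod, absolute tolerance 1e-10) splits
the domain at the critical angle, where `R_F` has a derivative
discontinuity, and the result is cached per index pair, so model
evaluations never re-integrate. For 1.33/1.00 this gives A = 2.51536.
Matched indices short-circuit to A = 1 exactly; the matched-index
Fresnel function returns 0 even at grazing incidence, where the general
expression is 0/0.

## Numerical quadrature

* Source-depth integration (`radial_reflectance`): composite 20-point
  Gauss–Legendre on geometrically growing panels starting at
  `1e-3/μtr`, so both the source scale `1/μtr` and the near-origin
  structure of the dipole kernel (sharp at `z0 ≈ ρ` for small `ρ`) are
  resolved. Default truncation `z0_max = 100` mm; doubling it changes
  results by < 1e-6 relative.
* Hankel transform of a continuous profile: panel-wise 10-point
  Gauss–Legendre with panel widths `min(max(ρ, 1e-3), π/k)` — geometric
  (one-per-octave) near the origin to resolve the envelope of `R(ρ)`,
  capped at the `J0` half-period to resolve the oscillation. Panels are
  evaluated in batches of 256 and summation stops after two consecutive
  batches each contribute < 1e-8 relative, bounded by
  `rho_max = 500` mm. Plain oscillation-period panels without the
  geometric refinement were found to lose ~10% at low `k`, where a
  single panel spanned the entire envelope.
* Binned (Monte Carlo) profiles use the midpoint rule
  `2π Σ ρᵢ J0(2πf ρᵢ) Rᵢ Δρ`; at `f = 0` this reproduces the detector
  bookkeeping (total detected weight per launched photon) exactly.

## Monte Carlo

MCML-style weighted-photon transport: pencil beam entering at the
origin; step lengths `−ln ξ / μt` with `μt = μa + μs`; fractional weight
deposition `μa/μt` per interaction; scattering by inverse-CDF sampling
of the Henyey–Greenstein cosine, either a single lobe or a two-term
mixture chosen per event by its weight. The scattering coefficient
follows the similarity relation `μs = μs′/(1 − g1)` with `g1` the
phase-function mean cosine, since media are specified by `μs′`. At an
upward surface crossing the photon is split deterministically: the
transmitted fraction `1 − R_F` (unpolarized Fresnel at the internal
incidence angle, total internal reflection beyond the critical angle)
is recorded in the radial bin of the exit point regardless of exit
angle, and the reflected fraction continues with the remaining step.
Deterministic splitting has the same expectation as stochastic
accept/reject but lower variance. Specular reflection at entry is
excluded by default (`include_specular=False`): the models describe
light delivered into the tissue, and SFDI calibration absorbs source
constants; when enabled, photons launch with weight `1 − R_spec` and the
specular fraction is carried in the energy audit.

Termination is by Russian roulette (survival probability 0.1,
weight × 10 on survival) triggered on the *importance-weighted* weight
`w · exp(−μeff z)`: a photon's expected future contribution to the
surface signal decays like the diffusion attenuation over its depth, so
deep photons whose eventual contribution is negligible are terminated
early. This is ordinary roulette with a position-dependent trigger and
therefore unbiased; with near-conservative media (`μa/μs′` down to
2·10⁻⁵ on the evaluation grid) it is the difference between feasible
and infeasible run times. With `q = 0` the trigger reduces to the plain
weight threshold. The default threshold is 1e-4 (MCML convention); the
scaled-down study uses 1e-2, where the added variance (of order
`threshold² / survival` per event) is far below the photon-counting
noise of its budget. Every run is reproduced bitwise by its seed; the
per-bin sum of squared deposits is accumulated so the standard error of
any transformed quantity can be propagated (deposits are treated as
independent, which slightly understates the error when one photon
deposits repeatedly).

Energy audit: detected + absorbed + overflow (+ specular) = 1 up to
roulette noise; asserted at 1e-3 with the default threshold.

## Evaluation study

Study conditions follow the validation design: media are all
combinations of `μa ∈ {0.001, 0.005, 0.01, 0.05, 0.1}` mm⁻¹ and
`μs′ ∈ {1, 5, 10, 20, 50}` mm⁻¹, each simulated with an HG phase
function (`g1 = 0.9`) and a two-term HG (forward lobe g = 0.95 weight
0.9, backward lobe g = −0.2 weight 0.1; the 0.45/0.05 weights in
common use sum to 0.5 and are normalized here, giving `g1 = 0.835`).
Frequencies per medium satisfy `μs′/f` log-spaced from 0.1 to 1000 in
20 steps. Errors are `|R_model − R_MC| / R_MC`, summarized by median and
interquartile range over the same record set for every model (paired
comparison); records with non-positive transformed MC reflectance
(possible at extreme frequencies under noise) are excluded from the
summaries for all models alike.

The diffusion-validity filter is implemented in two modes because the
conventional exclusion rule is stated ambiguously in this literature:
the *literal* mode excludes `f > 15 μtr`, which excludes nothing on
this grid (max `f = 10 μs′`); the *strict* mode reads the intent
`f ≪ μtr` and excludes `f > μtr/15`. The default is literal, with a
logged warning, and the study reports summaries under both modes. The
choice matters enormously: subdiffuse records (`μs′/f ≲ 5`) carry
relative errors of tens of percent for every diffuse model — the
diffuse component is a fraction of the total reflectance there — so
literal-mode medians sit an order of magnitude above strict-mode
medians, which isolate the diffuse band where the models are designed
to work. Historically quoted few-per-mil median errors for such
comparisons are consistent only with a strict-style exclusion.

The extraction study inverts each model from the MC reflectance at
`f = 0` and `f = 0.5` mm⁻¹ for every medium — the AC frequency is fixed
regardless of medium, even where 0.5 mm⁻¹ is subdiffuse for low `μs′`;
that choice is deliberate and is what makes extraction errors non-zero.
The inverse solver is bounded trust-region least squares on
`(log μa, log μs′)` (bounds `μa ∈ [1e-5, 1]`, `μs′ ∈ [0.1, 100]` mm⁻¹,
initial guess (0.01, 10) mm⁻¹, gradient tolerance 1e-12, ≤ 200
evaluations); with two equations and two unknowns it finds the exact
root on noise-free input (round-trip error < 1e-9 relative) and reports
`converged=False` with the residual otherwise. Failures are counted and
excluded from medians, never silently dropped.

Physical consistency: the diffuse component can never exceed the total
reflectance, so at subdiffuse frequencies (`μs′/f ≤ 10`) each model is
compared against `R_MC + 2·SE`. The PCBC model respects the bound on the
whole grid; the Cuccia and EBC models violate it, and the violation
counts are reported per model.

## Problem sizes

The shipped test suite runs the study at desk scale: the full 50-medium
grid, 2·10⁴ photons per medium (10⁶ total), bins of 0.004 mm × 5·10⁴
(200 mm), one repeat, roulette threshold 1e-2. At this budget the
relative MC standard error is ~0.7% at DC and ~1.5% in the mid-band, so
the study asserts the *ordering* of the median model errors
(PCBC < Cuccia < EBC) rather than their full-scale magnitudes. The
full-fidelity configuration (`sfdikit evaluate --scale full`: 10⁷
photons × 3 repeats per medium, 0.001 mm × 4·10⁵ bins, threshold 1e-4)
reproduces the magnitudes and takes hours. The equivalence check uses
four frequencies per medium spanning `μs′/f` from 1 to 1000; the
continuous transforms agree with the closed forms to ~1e-5, far inside
the asserted 1%.

## What the generator does and does not emulate

The Monte Carlo is a model-free solver of the same physical problem the
analytic models approximate — semi-infinite homogeneous medium, pencil
beam, index mismatch, angle-integrated detection — so agreement
demonstrates the quality of the diffusion approximation and boundary
conditions, not instrument realism. Not represented: finite source and
detector apertures, detector numerical aperture and angular response,
specular handling of real projection optics, layered or heterogeneous
tissue, polarization, and camera demodulation noise. Binned transforms
alias when the `J0` half-period approaches the bin width (only relevant
at the most subdiffuse frequencies of the highest-`μs′` media, and
identical for every model compared). Conclusions about real SFDI
instruments additionally depend on calibration against a reference
phantom, which is out of scope here.

## Known limitations

* The evaluation grid treats the two phase functions as fixed study
  conditions; the models themselves carry no phase-function dependence
  beyond `μs′`, so subdiffuse phase-function sensitivity appears only
  through the MC truth.
* `transform_se` underestimates the variance contribution of correlated
  multi-deposit photons; the 2-SE consistency band is therefore slightly
  conservative in the other direction and the margin of the PCBC bound
  is monitored in the study records.
* The depth-importance roulette assumes the diffusion attenuation
  `exp(−μeff z)` is a fair importance estimate; for strongly subdiffuse
  paths near the source it is only approximate, which affects variance,
  not expectation.
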