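# sfdikit

Analytical models, Monte Carlo ground truth, and optical-property
inversion for the diffuse reflectance in **spatial frequency domain
imaging (SFDI)**.

SFDI projects sinusoidal intensity patterns onto tissue and measures how
strongly the pattern amplitude is attenuated as a function of the
projected spatial frequency `f`. In the diffuse regime this attenuation
is governed by the absorption coefficient `μa` and the reduced
scattering coefficient `μs′`, so measuring the reflectance at two or
more frequencies lets one image both properties over a wide field. Doing
that requires a forward model `R(f; μa, μs′)`; this package implements
and compares three closed-form models, all expressed through

    μtr  = μa + μs′          (transport coefficient, mm⁻¹)
    a′   = μs′ / μtr          (reduced albedo)
    D    = 1 / (3 μtr)        (diffusion coefficient, mm)
    μeff = sqrt(μa / D)       (effective attenuation, mm⁻¹)
    μeff′ = sqrt(μeff² + k²),  k = 2πf
    A    = (1 + Reff) / (1 − Reff)   (internal-reflection parameter)

with `t = μeff′/μtr`:

* **Cuccia** (plane-illumination diffusion solution):
  `R = 3a′ / [(2At + 3)(t + 1)]`
* **PCBC** (pencil-beam Green's function under the partial-current
  boundary condition, source-integrated and Hankel-transformed):
  `R = a′ · [1 − exp(−(4A/3) t)] / [(4A/3) t (1 + t)]`
* **EBC** (same route under the extrapolated-boundary condition):
  `R = (a′/2) · [1 + exp(−(4A/3) t)] / (1 + t)`

The package also provides:

* the radial Green's functions `R(ρ, z0)` for both boundary conditions,
  the distributed source term `S(z) = a′ μtr exp(−μtr z)`, and
  zeroth-order Hankel transforms (continuous and binned), so the
  closed forms can be validated against the numerical pencil-beam route;
* a weighted-photon Monte Carlo simulator (pencil beam, semi-infinite
  medium, Fresnel boundary splitting, Henyey–Greenstein or two-term HG
  scattering, Russian roulette) as the model-free ground truth;
* two-frequency inversion of any model for `(μa, μs′)`;
* an evaluation study that sweeps a 5×5 grid of `μa`/`μs′` crossed with
  two phase functions, compares each model to the Monte Carlo truth via
  the relative error `|R_model − R_MC| / R_MC`, and summarizes
  median/interquartile errors per model.

## Worked example

Evaluate the PCBC model for a typical soft-tissue medium
(`μa = 0.01 mm⁻¹`, `μs′ = 5 mm⁻¹`, tissue–air boundary n = 1.33/1.00):

```sh
$ sfdikit model --model pcbc --mua 0.01 --musp 5 --f 0 --f 0.1 --f 0.5
model,f_mm_inv,reflectance
pcbc,0,0.81587797
pcbc,0.1,0.68630988
pcbc,0.5,0.2539423
```

The DC reflectance (f = 0) is 0.816: about 82% of the delivered light
re-emerges diffusely. At f = 0.5 mm⁻¹ the modulated reflectance has
dropped to 0.254 — that decay rate is what encodes the optical
properties. Feeding those two numbers back through the inverse solver
recovers the medium:

```sh
$ sfdikit invert --model pcbc --r-dc 0.81587797 --r-ac 0.2539423
{
  "mu_a_hat": 0.010000000053866481,
  "mu_s_prime_hat": 4.999999987415545,
  "residual_norm": 2.482534153247273e-16,
  "converged": true,
  "n_iterations": 6
}
```

The same library calls are available in Python
(`sfdikit.reflectance_model`, `sfdikit.extract_properties`, …), and
`sfdikit mc` / `sfdikit evaluate` run the Monte Carlo simulator and the
full model-comparison study (`--scale ci` for a desk-scale run,
`--scale full` for the full-fidelity configuration).

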