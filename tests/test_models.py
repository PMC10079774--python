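"""Closed-form models, Green's functions, source integration, Hankel transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from sfdikit import (
    BoundaryParams,
    ModelId,
    OpticalProperties,
    derive_diffusion_params,
    hankel_transform_binned,
    hankel_transform_continuous,
    mu_eff_prime,
    radial_green,
    radial_reflectance,
    reflectance_model,
    source_term,
)


PROPS = OpticalProperties(0.01, 5.0)


class TestClosedForms:
    @pytest.mark.parametrize(
        "model, expected",
        [
            (ModelId.CUCCIA, 0.8199268166),
            (ModelId.PCBC, 0.8158779706),
            (ModelId.EBC, 0.8204522070),
        ],
    )
    def test_dc_values(self, boundary, model, expected):
        # frozen from independent scalar evaluation of the three formulas
        assert reflectance_model(model, PROPS, 0.0, boundary) == pytest.approx(
            expected, rel=1e-8
        )

    def test_albedo_limit_zero_absorption(self, boundary):
        props = OpticalProperties(0.0, 5.0)
        for m in ModelId:
            assert reflectance_model(m, props, 0.0, boundary) == pytest.approx(1.0)

    def test_high_frequency_kills_reflectance(self, boundary):
        for m in ModelId:
            assert reflectance_model(m, PROPS, 1e4, boundary) < 1e-4

    def test_strictly_decreasing_and_bounded(self, boundary):
        f = np.logspace(-3, 2, 80)
        ap = derive_diffusion_params(PROPS).albedo_reduced
        for m in ModelId:
            r = reflectance_model(m, PROPS, f, boundary)
            assert np.all(np.diff(r) < 0)
            assert np.all(r > 0) and np.all(r <= ap)

    def test_string_model_names_accepted(self, boundary):
        assert reflectance_model("pcbc", PROPS, 0.1, boundary) == reflectance_model(
            ModelId.PCBC, PROPS, 0.1, boundary
        )
        with pytest.raises(ValueError, match="unknown model"):
            reflectance_model("farrell", PROPS, 0.1, boundary)

    @settings(deadline=None, derandomize=True)
    @given(
        mu_a=st.floats(1e-4, 0.5),
        mu_s_prime=st.floats(0.5, 60.0),
        f=st.floats(0.0, 50.0),
    )
    def test_exponent_argument_algebra(self, mu_a, mu_s_prime, f):
        # the PCBC/EBC exponent (4A/3)(mu_eff'/mu_tr) is exactly 2 z_b mu_eff'
        boundary = BoundaryParams.from_indices(1.33, 1.0)
        dp = derive_diffusion_params(OpticalProperties(mu_a, mu_s_prime))
        mep = mu_eff_prime(dp, f)
        lhs = 2.0 * boundary.z_b(dp) * mep
        rhs = (4.0 * boundary.A / 3.0) * (mep / dp.mu_tr)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestRadialGreen:
    def test_pcbc_zero_attenuation_limit(self, boundary):
        dp = derive_diffusion_params(OpticalProperties(0.0, 5.0))
        zb = boundary.z_b(dp)
        rho, z0 = 0.7, 0.3
        r1 = math.hypot(z0, rho)
        r2 = math.hypot(z0 + 2 * zb, rho)
        expected = (1 / r1 - 1 / r2) / (8 * math.pi * boundary.A * dp.D)
        assert radial_green(ModelId.PCBC, rho, z0, dp, boundary) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected > 0

    def test_pcbc_snapshot(self, boundary):
        # independent transcription of the image-pair formula
        dp = derive_diffusion_params(PROPS)
        rho, z0 = 1.0, 0.2
        zb = 2 * boundary.A * dp.D
        r1 = math.sqrt(z0**2 + rho**2)
        r2 = math.sqrt((z0 + 2 * zb) ** 2 + rho**2)
        expected = (
            math.exp(-dp.mu_eff * r1) / r1 - math.exp(-dp.mu_eff * r2) / r2
        ) / (4 * math.pi * 2 * boundary.A * dp.D)
        assert radial_green(ModelId.PCBC, rho, z0, dp, boundary) == pytest.approx(
            expected, rel=1e-12
        )

    def test_ebc_decay_and_positivity(self, boundary):
        dp = derive_diffusion_params(PROPS)
        rho = np.array([0.5, 1.0, 2.0, 5.0, 20.0])
        g = radial_green(ModelId.EBC, rho, 0.2, dp, boundary)
        assert np.all(g > 0)
        assert np.all(np.diff(g) < 0)
        assert radial_green(ModelId.EBC, 200.0, 0.2, dp, boundary) < 1e-30

    def test_singular_and_invalid_inputs(self, boundary):
        dp = derive_diffusion_params(PROPS)
        with pytest.raises(ValueError, match="singular"):
            radial_green(ModelId.PCBC, 0.0, 0.0, dp, boundary)
        with pytest.raises(ValueError, match="CUCCIA"):
            radial_green(ModelId.CUCCIA, 1.0, 0.2, dp, boundary)


class TestGreenFunctionInputs:
    def test_geometry(self, boundary):
        from sfdikit import GreenFunctionInputs

        dp = derive_diffusion_params(PROPS)
        gi = GreenFunctionInputs(rho=1.0, z0=0.2, z_b=boundary.z_b(dp))
        assert gi.r1 == pytest.approx(math.hypot(0.2, 1.0))
        assert gi.r2 == pytest.approx(math.hypot(0.2 + 2 * boundary.z_b(dp), 1.0))
        assert gi.rho <= gi.r1 <= gi.r2

    def test_singular_rejected(self):
        from sfdikit import GreenFunctionInputs

        with pytest.raises(ValueError, match="singular"):
            GreenFunctionInputs(rho=0.0, z0=0.0, z_b=0.1)
        with pytest.raises(ValueError):
            GreenFunctionInputs(rho=-1.0, z0=0.2, z_b=0.1)


class TestSourceTerm:
    def test_values_and_integral(self):
        dp = derive_diffusion_params(PROPS)
        ap, mutr = dp.albedo_reduced, dp.mu_tr
        assert source_term(0.0, dp) == pytest.approx(ap * mutr, rel=1e-12)
        assert source_term(1 / mutr, dp) == pytest.approx(ap * mutr / math.e, rel=1e-12)
        total, _ = integrate.quad(lambda z: source_term(z, dp), 0, np.inf)
        assert total == pytest.approx(ap, rel=1e-9)


class TestRadialReflectance:
    def test_monotone(self, boundary):
        dp = derive_diffusion_params(PROPS)
        r1, r2, r5 = radial_reflectance(ModelId.PCBC, np.array([1.0, 2.0, 5.0]), dp, boundary)
        assert r1 > r2 > r5 > 0

    def test_truncation_converged(self, boundary):
        dp = derive_diffusion_params(PROPS)
        a = radial_reflectance(ModelId.PCBC, 1.0, dp, boundary, z0_max=100.0)
        b = radial_reflectance(ModelId.PCBC, 1.0, dp, boundary, z0_max=200.0)
        assert abs(a - b) / a < 1e-6

    @pytest.mark.parametrize("model", [ModelId.PCBC, ModelId.EBC])
    def test_against_adaptive_quadrature(self, boundary, model):
        dp = derive_diffusion_params(PROPS)
        rho = 1.0
        oracle, _ = integrate.quad(
            lambda z0: radial_green(model, rho, z0, dp, boundary) * source_term(z0, dp),
            0,
            100.0,
            epsabs=1e-13,
            epsrel=1e-12,
            limit=200,
        )
        assert radial_reflectance(model, rho, dp, boundary) == pytest.approx(
            oracle, rel=1e-8
        )


class TestHankelContinuous:
    def test_point_mass(self):
        # narrow unit-mass Gaussian at the origin transforms to ~1 at any f
        sigma = 1e-3
        fn = lambda rho: np.exp(-0.5 * (rho / sigma) ** 2) / (2 * np.pi * sigma**2)
        for f in (0.0, 0.5, 5.0):
            assert hankel_transform_continuous(fn, f, rho_max=1.0) == pytest.approx(
                1.0, rel=2e-3
            )

    def test_f_zero_is_area_integral(self, boundary):
        dp = derive_diffusion_params(PROPS)
        fn = lambda rho: radial_reflectance(ModelId.PCBC, rho, dp, boundary)
        area, _ = integrate.quad(
            lambda rho: 2 * np.pi * rho * fn(np.array([rho]))[0], 0, 50.0,
            epsabs=1e-12, limit=200,
        )
        assert hankel_transform_continuous(fn, 0.0, rho_max=50.0) == pytest.approx(
            area, rel=1e-7
        )

    @pytest.mark.parametrize("f", [0.05, 0.5, 5.0])
    def test_monopole_closed_form(self, f):
        # 2 pi int rho J0(k rho) exp(-mu r)/r drho = 2 pi exp(-z0 m)/m, m=sqrt(mu^2+k^2)
        mu, z0 = 1.3, 0.4
        fn = lambda rho: np.exp(-mu * np.hypot(rho, z0)) / np.hypot(rho, z0)
        m = math.hypot(mu, 2 * math.pi * f)
        expected = 2 * math.pi * math.exp(-z0 * m) / m
        assert hankel_transform_continuous(fn, f, rho_max=100.0) == pytest.approx(
            expected, rel=1e-7
        )

    @pytest.mark.parametrize("model", [ModelId.PCBC, ModelId.EBC])
    @pytest.mark.parametrize("f", [0.05, 0.5, 5.0])
    def test_matches_closed_form(self, boundary, model, f):
        # numerical pencil-beam route equals the closed form well inside 1%
        dp = derive_diffusion_params(PROPS)
        num = hankel_transform_continuous(
            lambda rho: radial_reflectance(model, rho, dp, boundary), f
        )
        closed = reflectance_model(model, PROPS, f, boundary)
        assert num == pytest.approx(closed, rel=1e-3)


class TestHankelBinned:
    def test_empty_profile_rejected(self):
        class Empty:
            bin_centers = np.array([])
            values = np.array([])
            bin_width = 0.1

        with pytest.raises(ValueError, match="empty"):
            hankel_transform_binned(Empty(), [0.0])

    def test_zero_profile(self, small_profile):
        from dataclasses import replace

        zero = replace(small_profile, values=np.zeros_like(small_profile.values))
        assert np.all(hankel_transform_binned(zero, [0.0, 0.5, 2.0]) == 0.0)

    def test_single_bin(self):
        class One:
            bin_centers = np.array([0.35])
            values = np.array([2.0])
            bin_width = 0.1

        f = 0.7
        expected = 2 * np.pi * 0.35 * 0.1 * 2.0 * np.real(
            __import__("scipy.special", fromlist=["j0"]).j0(2 * np.pi * f * 0.35)
        )
        assert hankel_transform_binned(One(), [f])[0] == pytest.approx(expected, rel=1e-12)

    def test_dc_equals_detected_fraction(self, small_profile):
        # f=0 sum reproduces the detector bookkeeping exactly
        dc = hankel_transform_binned(small_profile, [0.0])[0]
        assert dc == pytest.approx(small_profile.detected_fraction, rel=1e-12)
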