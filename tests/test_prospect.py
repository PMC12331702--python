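"""Radiative-transfer core: interface optics, plate absorption, plate-stack
composition, and the parameter-to-trait mapping."""

import numpy as np
import pytest
from scipy.integrate import quad

from spectraits import (
    LeafParams,
    LeafSpectrum,
    OpticalConstants,
    absorption_spectrum,
    elementary_transmission,
    latin_hypercube,
    leaf_rt,
    load_optical_constants,
    params_to_traits,
    synthetic_optical_constants,
    tav,
)
from spectraits.prospect import PARAM_NAMES
from spectraits.synth import ParamRanges


# ---------------------------------------------------------------------------
# oracles


def fresnel_transmissivity(theta, n):
    st = np.sin(theta) / n
    if st > 1:
        return 0.0
    ci, ct = np.cos(theta), np.sqrt(1 - st**2)
    rs = ((ci - n * ct) / (ci + n * ct)) ** 2
    rp = ((n * ci - ct) / (n * ci + ct)) ** 2
    return 1 - 0.5 * (rs + rp)


def tav_quadrature(alpha_deg, n):
    """Adaptive-quadrature oracle for the cone-averaged transmissivity."""
    a = np.deg2rad(alpha_deg)
    num = quad(lambda t: fresnel_transmissivity(t, n) * np.sin(t) * np.cos(t),
               0, a, limit=200)[0]
    den = quad(lambda t: np.sin(t) * np.cos(t), 0, a)[0]
    return num / den


# value frozen from the adaptive-quadrature oracle above
TAV_40_14 = 0.9708952040917468
# E1(1) frozen from quad of int_1^inf e^-t / t dt; tau(1) = E1(1)
E1_OF_1 = 0.21938393439551238


# ---------------------------------------------------------------------------
# optical constants I/O


def _constants_frame(small_constants):
    return small_constants.to_frame()


class TestLoadOpticalConstants:
    def test_roundtrip_minimal(self, tmp_path, small_constants):
        path = tmp_path / "oc.csv"
        small_constants.to_frame().head(3).to_csv(path, index=False)
        oc = load_optical_constants(path)
        assert len(oc) == 3
        np.testing.assert_allclose(oc.k_w, small_constants.k_w[:3])

    def test_missing_column_is_schema_error(self, tmp_path, small_constants):
        df = small_constants.to_frame().drop(columns=["k_w"])
        path = tmp_path / "oc.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="k_w"):
            load_optical_constants(path)

    def test_duplicate_wavelength_is_ordering_error(self, tmp_path, small_constants):
        df = small_constants.to_frame().head(4)
        df.loc[1, "wavelength_nm"] = df.loc[0, "wavelength_nm"]
        path = tmp_path / "oc.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="increasing"):
            load_optical_constants(path)

    def test_negative_coefficient_rejected(self, tmp_path, small_constants):
        df = small_constants.to_frame().head(4)
        df.loc[2, "k_ab"] = -0.1
        path = tmp_path / "oc.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="k_ab"):
            load_optical_constants(path)

    def test_refractive_index_below_one_rejected(self, tmp_path, small_constants):
        df = small_constants.to_frame().head(4)
        df.loc[1, "n"] = 0.9
        path = tmp_path / "oc.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="refractive_index"):
            load_optical_constants(path)


class TestSyntheticConstants:
    def test_deterministic_given_seed(self):
        a = synthetic_optical_constants(seed=5)
        b = synthetic_optical_constants(seed=5)
        np.testing.assert_array_equal(a.k_w, b.k_w)
        np.testing.assert_array_equal(a.refractive_index, b.refractive_index)

    def test_chlorophyll_band_placement(self, constants):
        wl = constants.wavelengths_nm
        assert constants.k_ab[np.argmin(abs(wl - 670))] > \
            constants.k_ab[np.argmin(abs(wl - 1600))]

    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_invariants_all_seeds(self, seed):
        oc = synthetic_optical_constants(seed=seed)
        for name in ("k_ab", "k_cx", "k_an", "k_bp", "k_w", "k_m"):
            assert np.all(getattr(oc, name) >= 0)
        assert np.all(oc.refractive_index >= 1.3)
        assert np.all(oc.refractive_index <= 1.5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            synthetic_optical_constants(grid=np.array([]))


# ---------------------------------------------------------------------------
# interface optics


class TestTav:
    def test_no_index_mismatch_is_unity(self):
        assert tav(90, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_matches_frozen_quadrature_value(self):
        assert tav(40, 1.4) == pytest.approx(TAV_40_14, abs=1e-6)

    @pytest.mark.parametrize("alpha", [40, 59, 90])
    @pytest.mark.parametrize("n", [1.0, 1.2, 1.4, 1.6])
    def test_matches_adaptive_quadrature(self, alpha, n):
        assert tav(alpha, n) == pytest.approx(tav_quadrature(alpha, n), abs=1e-6)

    def test_more_mismatch_more_reflection(self):
        assert tav(90, 1.2) > tav(90, 1.5)

    def test_vectorized_over_n(self):
        ns = np.array([1.0, 1.3, 1.5])
        vals = tav(40, ns)
        assert vals.shape == (3,)
        for ni, vi in zip(ns, vals):
            assert vi == pytest.approx(tav(40, float(ni)), abs=1e-14)

    @pytest.mark.parametrize("alpha,n", [(0, 1.2), (95, 1.2), (40, 0.9)])
    def test_domain_errors(self, alpha, n):
        with pytest.raises(ValueError):
            tav(alpha, n)


class TestElementaryTransmission:
    def test_no_absorber_is_transparent(self):
        assert elementary_transmission(0.0) == 1.0

    def test_opaque_limit(self):
        assert elementary_transmission(50.0) < 1e-10

    def test_k1_equals_exponential_integral(self):
        # tau(1) = (1-1)e^-1 + 1^2 E1(1) = E1(1)
        assert elementary_transmission(1.0) == pytest.approx(E1_OF_1, abs=1e-8)

    def test_strictly_decreasing(self):
        k = np.linspace(0, 10, 200)
        tau = elementary_transmission(k)
        assert np.all(np.diff(tau) < 0)
        assert np.all((tau > 0) & (tau <= 1))

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            elementary_transmission(-0.1)


# ---------------------------------------------------------------------------
# absorption mixing


class TestAbsorptionSpectrum:
    def test_zero_concentrations_zero_depth(self, small_constants):
        p = LeafParams(Cab=0, Ccx=0, Can=0, Cbp=0, Cw=0, Cm=0)
        assert np.all(absorption_spectrum(p, small_constants) == 0)

    def test_linear_in_concentrations(self, small_constants):
        p1 = LeafParams(N=1.4, Cab=30, Ccx=8, Can=1.3, Cbp=0.2, Cw=0.02, Cm=0.006)
        p2 = LeafParams(N=1.4, Cab=60, Ccx=16, Can=2.6, Cbp=0.4, Cw=0.04, Cm=0.012)
        np.testing.assert_allclose(
            absorption_spectrum(p2, small_constants),
            2 * absorption_spectrum(p1, small_constants), rtol=1e-12,
        )

    def test_hand_arithmetic_single_band(self):
        oc = OpticalConstants(
            wavelengths_nm=np.array([670.0]), refractive_index=np.array([1.4]),
            k_ab=np.array([0.1]), k_cx=np.zeros(1), k_an=np.zeros(1),
            k_bp=np.zeros(1), k_w=np.zeros(1), k_m=np.zeros(1),
        )
        p = LeafParams(N=2.0, Cab=50, Ccx=0, Can=0, Cbp=0, Cw=0, Cm=0)
        # (50 * 0.1) / 2 = 2.5
        assert absorption_spectrum(p, oc)[0] == pytest.approx(2.5, abs=1e-12)


# ---------------------------------------------------------------------------
# plate stack


def single_layer_oracle(params, constants, alpha_deg=40.0):
    """Independent single-plate (N=1) composition from the interface terms."""
    n = constants.refractive_index
    k = absorption_spectrum(params, constants)
    tau = elementary_transmission(k)
    talf = tav(alpha_deg, n)
    t12 = tav(90.0, n)
    t21 = t12 / n**2
    r21 = 1 - t21
    denom = 1 - r21**2 * tau**2
    Ta = talf * tau * t21 / denom
    Ra = (1 - talf) + r21 * tau * Ta
    return Ra, Ta


class TestLeafRT:
    def test_energy_conserved_without_absorption(self, constants):
        p = LeafParams(N=1.7, Cab=0, Ccx=0, Can=0, Cbp=0, Cw=0, Cm=0)
        s = leaf_rt(p, constants)
        np.testing.assert_allclose(
            s.reflectance + s.transmittance, 1.0, atol=1e-8)

    def test_n1_matches_single_layer_formula(self, constants):
        p = LeafParams(N=1.0, Cab=40, Ccx=10, Can=1.5, Cbp=0.3, Cw=0.02, Cm=0.006)
        s = leaf_rt(p, constants)
        Ra, Ta = single_layer_oracle(p, constants)
        np.testing.assert_allclose(s.reflectance, Ra, atol=1e-10)
        np.testing.assert_allclose(s.transmittance, Ta, atol=1e-10)

    def test_property_sweep_physical_bounds(self, constants):
        mat = latin_hypercube(ParamRanges(), 200, seed=11)
        for row in mat:
            p = LeafParams(**dict(zip(PARAM_NAMES, row)))
            s = leaf_rt(p, constants)
            assert np.all(s.reflectance >= 0) and np.all(s.transmittance >= 0)
            assert np.all(s.reflectance + s.transmittance <= 1 + 1e-9)

    def test_reflectance_decreasing_in_cab_at_red_band(self, constants):
        i = np.argmin(abs(constants.wavelengths_nm - 670))
        vals = [leaf_rt(LeafParams(Cab=c), constants).reflectance[i]
                for c in (0.1, 10, 30, 60, 100)]
        assert np.all(np.diff(vals) < 0)

    def test_transmittance_decreasing_in_cw_at_water_band(self, constants):
        i = np.argmin(abs(constants.wavelengths_nm - 1940))
        vals = [leaf_rt(LeafParams(Cw=c), constants).transmittance[i]
                for c in (0.01, 0.02, 0.035, 0.05)]
        assert np.all(np.diff(vals) < 0)

    def test_opaque_limit_no_nan(self, small_constants):
        p = LeafParams(N=1.9, Cab=100, Ccx=25, Can=1.8, Cbp=1.0, Cw=0.05, Cm=0.009)
        s = leaf_rt(p, small_constants)
        assert np.all(np.isfinite(s.reflectance))
        assert np.all(np.isfinite(s.transmittance))

    def test_continuous_in_n_across_integer(self, small_constants):
        p_lo = LeafParams(N=1.999)
        p_hi = LeafParams(N=2.001)
        lo = leaf_rt(p_lo, small_constants).reflectance
        hi = leaf_rt(p_hi, small_constants).reflectance
        assert np.max(np.abs(lo - hi)) < 1e-3


class TestParamsToTraits:
    def test_identity_and_unit_conventions(self):
        t = params_to_traits(LeafParams(Cab=50, Cw=0.02, Cm=0.005))
        assert t["CHL"] == 50
        assert t["EWT"] == pytest.approx(0.02)
        assert t["LMA"] == pytest.approx(0.005)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            LeafParams(N=0.5)
        with pytest.raises(ValueError):
            LeafParams(Cw=-0.01)


class TestLeafSpectrumInvariants:
    def test_conservation_violation_rejected(self):
        with pytest.raises(ValueError):
            LeafSpectrum(np.array([500.0]), np.array([0.7]), np.array([0.4]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            LeafSpectrum(np.array([500.0]), np.array([-0.1]), np.array([0.4]))
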