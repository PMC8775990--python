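"""Closed-form rate laws, structural identities, thresholds and FOMs."""

import math
import warnings

import numpy as np
import pytest

from mpbleach.beam_optics import LevelScheme, brute_force_observed_rate
from mpbleach.exceptions import (
    DomainWarning,
    InvalidParameterError,
    ParameterMissingError,
)
from mpbleach.rate_models import (
    K2,
    K3,
    K4,
    MolecularPhotophysics,
    a2_coefficient,
    a4_coefficient,
    critical_wavelength,
    figure_of_merit,
    k1_bracket,
    k1_homogeneous,
    photons_required,
    predict_threshold_power,
    saturation_parameter_uniform,
    saturation_power,
    total_rate,
)


class TestMolecularPhotophysics:
    def test_yield_range_enforced(self):
        with pytest.raises(InvalidParameterError):
            MolecularPhotophysics(phi1=1.5)

    def test_negative_cross_section_rejected(self):
        with pytest.raises(InvalidParameterError):
            MolecularPhotophysics(sigma_mn=-1e-17)

    def test_product_consistency_enforced(self):
        with pytest.raises(InvalidParameterError):
            MolecularPhotophysics(
                sigma_mn=5e-17, sigma_nc=3e-19, product_mn_nc_explicit=1e-35
            )
        ok = MolecularPhotophysics(
            sigma_mn=5e-17, sigma_nc=3e-19, product_mn_nc_explicit=1.5e-35
        )
        assert ok.product_mn_nc == pytest.approx(1.5e-35)

    def test_missing_sigma2_raises_named_error(self):
        with pytest.raises(ParameterMissingError, match="sigma2"):
            MolecularPhotophysics(phi1=1e-5).sigma2_cm4s


class TestRateLaws:
    def test_zero_power_all_orders(self, colony_geometry, oscillator, mcherry_780):
        laser, geom = oscillator(780), colony_geometry(780)
        assert float(K2(0.0, mcherry_780, laser, geom)) == 0.0
        mol = mcherry_780.evolve(phin=1e-3)
        assert float(K3(0.0, mol, laser, geom)) == 0.0
        assert float(K4(0.0, mcherry_780, laser, geom)) == 0.0

    def test_quadratic_and_quartic_scaling(
        self, colony_geometry, oscillator, mcherry_780
    ):
        laser, geom = oscillator(780), colony_geometry(780)
        assert float(K2(0.02, mcherry_780, laser, geom)) == pytest.approx(
            4 * float(K2(0.01, mcherry_780, laser, geom)), rel=1e-12
        )
        assert float(K4(0.02, mcherry_780, laser, geom)) == pytest.approx(
            16 * float(K4(0.01, mcherry_780, laser, geom)), rel=1e-12
        )

    @pytest.mark.parametrize("order,rel", [(2, 1e-4), (3, 1e-3), (4, 1e-3)])
    def test_unsaturated_laws_match_oracle(
        self, geometry_with_eta, oscillator, order, rel
    ):
        laser = oscillator(780)
        geom = geometry_with_eta(1.4, lambda_nm=780)
        mol = MolecularPhotophysics(
            sigma2_gm=42, phim=8.5e-5, phin=2e-3, sigma_mn=5e-17, sigma_nc=3.4e-19
        )
        fn = {2: K2, 3: K3, 4: K4}[order]
        Ka = float(fn(0.03, mol, laser, geom))
        Kb = brute_force_observed_rate(
            LevelScheme(order, saturated=False), mol, laser, geom, P=0.03
        )
        assert Ka == pytest.approx(Kb, rel=rel)

    def test_saturated_cubic_reduces_to_unsaturated(
        self, colony_geometry, oscillator, three_photon_molecule
    ):
        # the first bracket term of the slight-saturation law with Ps
        # substituted must reproduce the cubic law exactly as P/Ps -> 0
        laser, geom = oscillator(760), colony_geometry(760)
        mol = three_photon_molecule
        Ps = saturation_power(mol, laser, geom)
        for frac in (1e-5, 1e-7):
            P = frac * Ps
            ratio = float(K3(P, mol, laser, geom, saturated=True)) / float(
                K3(P, mol, laser, geom, saturated=False)
            )
            assert ratio == pytest.approx(1.0, abs=5 * frac)

    def test_saturated_cubic_domain_warning(
        self, colony_geometry, oscillator, three_photon_molecule
    ):
        laser, geom = oscillator(760), colony_geometry(760)
        Ps = saturation_power(three_photon_molecule, laser, geom)
        with pytest.warns(DomainWarning):
            K3(10 * Ps, three_photon_molecule, laser, geom, saturated=True)

    def test_saturated_quartic_high_power_slope_is_three(
        self, colony_geometry, oscillator, mcherry_780
    ):
        laser, geom = oscillator(780), colony_geometry(780)
        Ps = saturation_power(mcherry_780, laser, geom)
        P = np.array([50.0, 55.0]) * Ps
        K = K4(P, mcherry_780, laser, geom, saturated=True)
        slope = np.diff(np.log(K)) / np.diff(np.log(P))
        assert slope[0] == pytest.approx(3.0, abs=0.1)

    def test_saturated_quartic_matches_oracle_at_strong_saturation(
        self, geometry_with_eta, oscillator, mcherry_780
    ):
        laser = oscillator(780)
        geom = geometry_with_eta(1.4, lambda_nm=780)
        Ps = saturation_power(mcherry_780, laser, geom)
        Ka = float(K4(10 * Ps, mcherry_780, laser, geom, saturated=True))
        Kb = brute_force_observed_rate(
            LevelScheme(4, saturated=True), mcherry_780, laser, geom, P=10 * Ps
        )
        assert Ka == pytest.approx(Kb, rel=0.05)

    def test_total_rate_reduces_to_k2_and_bounds_components(
        self, colony_geometry, oscillator, mcherry_1100, mcherry_780
    ):
        laser, geom = oscillator(), colony_geometry()
        only2 = total_rate(0.05, mcherry_1100, laser, geom)
        assert float(only2) == pytest.approx(
            float(K2(0.05, mcherry_1100, laser, geom)), rel=1e-12
        )
        laser780, geom780 = oscillator(780), colony_geometry(780)
        mol = mcherry_780.evolve(phin=2e-3)
        tot = float(total_rate(0.05, mol, laser780, geom780))
        for fn in (K2, K3, K4):
            assert tot >= float(fn(0.05, mol, laser780, geom780))

    def test_total_rate_bend_slope_2_to_4(
        self, colony_geometry, oscillator, mcherry_780
    ):
        # quadratic + quartic terms: log-log slope ~2 below the threshold,
        # approaching 4 well above it
        laser, geom = oscillator(800), colony_geometry(800, w0_um=3.78)
        mol = MolecularPhotophysics(
            sigma2_gm=22, phim=1.0e-4, product_mn_nc_explicit=5.0e-36
        )
        Pstar = predict_threshold_power(mol, laser, geom)

        def slope(P):
            eps = 1.01
            k1 = float(K2(P, mol, laser, geom) + K4(P, mol, laser, geom))
            k2 = float(K2(eps * P, mol, laser, geom) + K4(eps * P, mol, laser, geom))
            return math.log(k2 / k1) / math.log(eps)

        assert slope(Pstar / 10) == pytest.approx(2.0, abs=0.05)
        assert slope(Pstar * 10) == pytest.approx(4.0, abs=0.05)


class TestThreshold:
    def test_equals_sqrt_a2_over_a4(self, colony_geometry, oscillator, mcherry_780):
        laser, geom = oscillator(780), colony_geometry(780, w0_um=3.70)
        a2 = a2_coefficient(mcherry_780, laser, geom)
        a4 = a4_coefficient(mcherry_780, laser, geom)
        assert predict_threshold_power(mcherry_780, laser, geom) == pytest.approx(
            math.sqrt(a2 / a4), rel=1e-9
        )

    def test_sqrt_phi_scaling(self, colony_geometry, oscillator, mcherry_780):
        laser, geom = oscillator(780), colony_geometry(780)
        base = predict_threshold_power(mcherry_780, laser, geom)
        quarter = mcherry_780.evolve(phim=mcherry_780.phim / 4)
        assert predict_threshold_power(quarter, laser, geom) == pytest.approx(
            base / 2, rel=1e-12
        )

    def test_zero_product_undefined(self, colony_geometry, oscillator):
        mol = MolecularPhotophysics(phim=1e-4, product_mn_nc_explicit=0.0)
        with pytest.raises(InvalidParameterError):
            predict_threshold_power(mol, oscillator(), colony_geometry())


class TestHomogeneousBeam:
    def test_bracket_zero_at_zero(self):
        assert float(k1_bracket(0.0)) == 0.0

    @pytest.mark.parametrize("X", [1e-4, 1e-3, 1e-2])
    def test_bracket_small_x_limit_is_x4_over_6(self, X):
        assert float(k1_bracket(X)) / X**4 == pytest.approx(1.0 / 6.0, rel=1e-2)

    def test_bracket_negative_x_rejected(self):
        with pytest.raises(InvalidParameterError):
            k1_bracket(-0.1)

    def test_uniform_beam_saturation_parameter_reconstruction(self):
        # 11.4 W/cm^2 average, 1 kHz, 780 nm, sigma_mn = 5e-17 cm^2 -> X ~ 4.5
        hnu = 1239.841984 / 780 * 1.602176634e-19
        photons_per_pulse = 11.4 / (1e3 * hnu)
        X = saturation_parameter_uniform(5.0e-17, photons_per_pulse)
        assert X == pytest.approx(4.5, rel=0.02)

    def test_small_x_limit_matches_unsaturated_quartic_local_rate(self):
        # k1 -> (1/12) sigma2 sigma_mn sigma_nc f dtau^3 I^4 as X -> 0
        mol = MolecularPhotophysics(sigma2_gm=42, sigma_mn=5e-17, sigma_nc=3.4e-19)
        f, dtau = 1e3, 350e-15
        I = 1e25
        X = 2 * mol.sigma_mn * I * dtau
        expected = (
            mol.sigma2_cm4s * mol.sigma_mn * mol.sigma_nc * I**4 * dtau**3 / 12.0 * f
        )
        assert float(k1_homogeneous(X, mol, f, dtau)) == pytest.approx(
            expected, rel=1e-4
        )


class TestPhotonBudget:
    @pytest.mark.parametrize(
        "vde,lam,n",
        [(5.52, 790, 4), (5.61, 790, 4), (7.24, 790, 5), (5.52, 1100, 5)],
    )
    def test_photon_counts(self, vde, lam, n):
        assert photons_required(vde, lam) == n

    def test_critical_wavelengths_two_sig_figs(self):
        assert round(critical_wavelength(5.52, 4), -1) == 900
        assert round(critical_wavelength(5.61, 4), -1) == 880

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            photons_required(-1.0, 800)
        with pytest.raises(InvalidParameterError):
            critical_wavelength(5.5, 0)


class TestFigureOfMerit:
    def test_order4_published_rows(self):
        rows = [
            (22, 5.0e-36, 0.24, 5.0),  # mCherry 800
            (80, 2.3e-36, 0.72, 43.0),  # tdTomato 1100
            (43, 1.6e-35, 0.13, 2.1),  # mPlum 790
        ]
        for sigma2, prod, phiF, expected_1e8 in rows:
            mol = MolecularPhotophysics(
                sigma2_gm=sigma2, product_mn_nc_explicit=prod, phiF=phiF
            )
            assert figure_of_merit(4, mol) / 1e-8 == pytest.approx(
                expected_1e8, rel=0.05
            )

    def test_order2_published_row(self):
        mol = MolecularPhotophysics(phi1=1.6e-5, phiF=0.24)
        assert figure_of_merit(2, mol) / 1e3 == pytest.approx(15.0, rel=0.05)

    def test_scaling_with_sigma2_and_product(self):
        mol = MolecularPhotophysics(
            sigma2_gm=22, product_mn_nc_explicit=5e-36, phiF=0.24
        )
        base = figure_of_merit(4, mol)
        assert figure_of_merit(
            4, mol.evolve(sigma2_gm=44)
        ) == pytest.approx(base * math.sqrt(2), rel=1e-12)
        assert figure_of_merit(
            4, mol.evolve(product_mn_nc_explicit=1e-35)
        ) == pytest.approx(base / math.sqrt(2), rel=1e-12)

    def test_zero_fluorescence_yield_gives_zero(self):
        mol = MolecularPhotophysics(phi1=1e-5, sigma2_gm=10, phiF=0.0)
        for order in (2, 3, 4):
            assert figure_of_merit(order, mol) == 0.0

    def test_missing_parameter_named(self):
        mol = MolecularPhotophysics(phiF=0.24, sigma2_gm=22)
        with pytest.raises(ParameterMissingError, match="sigma_mn"):
            figure_of_merit(4, mol)
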