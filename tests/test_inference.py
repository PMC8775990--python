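"""Power-series fitting: exponents, thresholds, segment fits, saturated fits
and the staged pipeline."""

import math

import numpy as np
import pytest

from mpbleach.beam_optics import BeamGeometry, LaserConfig
from mpbleach.exceptions import (
    ContaminationWarning,
    InsufficientDataError,
    NonIdentifiableError,
    RegimeMismatchError,
)
from mpbleach.inference import (
    PowerSeries,
    SeriesContext,
    detect_threshold,
    fit_cubic,
    fit_quadratic_segment,
    fit_quartic_excess,
    fit_saturated_3photon,
    fit_saturated_4photon,
    infer_pipeline,
    power_exponent,
)
from mpbleach.rate_models import (
    K2,
    K3,
    K4,
    MolecularPhotophysics,
    a2_coefficient,
    a3_coefficient,
    a4_coefficient,
    predict_threshold_power,
    saturation_power,
)


def make_context(lambda_nm=780.0, sigma2_gm=42.0, w0_um=3.70):
    laser = LaserConfig(lambda_nm=lambda_nm, f=80e6, dtau=109e-15)
    geometry = BeamGeometry.from_units(
        w0_um=w0_um, lambda_nm=lambda_nm, n0=1.33, l_um=200.0
    )
    return SeriesContext(laser=laser, geometry=geometry, sigma2_gm=sigma2_gm)


def series_from_model(P, K, ctx=None, rel_se=0.1):
    K = np.asarray(K, float)
    return PowerSeries(P=P, K=K, K_se=rel_se * K, context=ctx)


class TestPowerSeries:
    def test_sorted_ascending_stable(self):
        s = PowerSeries(P=np.array([0.03, 0.01, 0.02]), K=np.array([3.0, 1.0, 2.0]))
        assert np.all(np.diff(s.P) > 0)
        assert np.allclose(s.K, [1.0, 2.0, 3.0])

    def test_nonpositive_power_rejected(self):
        with pytest.raises(Exception):
            PowerSeries(P=np.array([0.0, 0.01]), K=np.array([1.0, 2.0]))


class TestPowerExponent:
    @pytest.mark.parametrize("n", [2.0, 8.0])
    def test_exact_power_law(self, n):
        P = np.logspace(-2, -1, 8)
        est = power_exponent(PowerSeries(P=P, K=3.0 * P**n))
        assert est.value == pytest.approx(n, abs=1e-9)

    def test_bend_series_between_two_and_four(self):
        ctx = make_context()
        mol = MolecularPhotophysics(
            sigma2_gm=42, phim=8.5e-5, product_mn_nc_explicit=1.7e-35
        )
        P = np.logspace(math.log10(0.005), math.log10(0.12), 12)
        K = K2(P, mol, ctx.laser, ctx.geometry) + K4(P, mol, ctx.laser, ctx.geometry)
        est = power_exponent(PowerSeries(P=P, K=K))
        assert 2.0 < est.value < 4.0
        high = power_exponent(PowerSeries(P=P[-4:], K=K[-4:]))
        assert high.value > 3.4

    def test_nonpositive_rates_excluded_with_warning(self):
        P = np.array([0.01, 0.02, 0.04, 0.08])
        K = np.array([1.0, 4.0, -1.0, 64.0])
        with pytest.warns(UserWarning, match="excluded"):
            est = power_exponent(PowerSeries(P=P, K=K))
        assert np.isfinite(est.value)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            power_exponent(PowerSeries(P=np.array([0.01, 0.02]), K=np.array([1.0, 4.0])))


class TestQuadraticSegment:
    def test_noiseless_inversion_recovers_phi(self):
        ctx = make_context(lambda_nm=1100.0, sigma2_gm=24.0, w0_um=4.5)
        mol = MolecularPhotophysics(sigma2_gm=24.0, phi1=1.6e-5)
        P = np.linspace(0.02, 0.12, 8)
        series = series_from_model(P, K2(P, mol, ctx.laser, ctx.geometry), ctx)
        fit = fit_quadratic_segment(series)
        assert fit.phi.value == pytest.approx(1.6e-5, rel=1e-6)
        assert fit.a2.value == pytest.approx(
            a2_coefficient(mol, ctx.laser, ctx.geometry), rel=1e-6
        )

    def test_contaminated_segment_warns(self):
        P = np.logspace(-2, -0.5, 10)
        with pytest.warns(ContaminationWarning):
            fit_quadratic_segment(PowerSeries(P=P, K=5.0 * P**3.5))


class TestDetectThreshold:
    def test_pure_quadratic_gives_none(self):
        P = np.logspace(-2.5, -1, 10)
        rng = np.random.default_rng(3)
        K = 1.0 * P**2 * np.exp(0.05 * rng.standard_normal(P.size))
        assert detect_threshold(series_from_model(P, K, rel_se=0.05)) is None

    def test_closed_form_from_known_coefficients(self):
        a2, a4 = 1e-3, 1.0
        P = np.logspace(-2.5, -0.8, 12)
        K = a2 * P**2 + a4 * P**4
        thr = detect_threshold(series_from_model(P, K, rel_se=0.02))
        assert thr is not None
        assert thr.Pstar.value == pytest.approx(math.sqrt(1e-3), rel=1e-6)

    def test_insufficient_span_rejected(self):
        P = np.linspace(0.02, 0.04, 8)
        with pytest.raises(InsufficientDataError):
            detect_threshold(series_from_model(P, P**2))

    def test_synthetic_bend_recovery_within_15_percent(self):
        # generated at the published molecular parameters for the 780 nm
        # quadratic+quartic regime; the detected bend must sit near the
        # generating threshold sqrt(a2/a4)
        ctx = make_context()
        mol = MolecularPhotophysics(
            sigma2_gm=42, phim=8.5e-5, product_mn_nc_explicit=1.7e-35
        )
        true_Pstar = predict_threshold_power(mol, ctx.laser, ctx.geometry)
        P = np.logspace(math.log10(0.005), math.log10(0.12), 12)
        K = np.asarray(
            K2(P, mol, ctx.laser, ctx.geometry) + K4(P, mol, ctx.laser, ctx.geometry)
        )
        rng = np.random.default_rng(42)
        Kn = K * np.exp(0.1 * rng.standard_normal(K.size))
        thr = detect_threshold(series_from_model(P, Kn))
        assert thr is not None
        assert thr.Pstar.value == pytest.approx(true_Pstar, rel=0.15)


class TestSegmentFits:
    def test_quartic_excess_exact_recovery(self):
        ctx = make_context()
        mol = MolecularPhotophysics(
            sigma2_gm=42, phim=8.5e-5, product_mn_nc_explicit=1.7e-35
        )
        P = np.logspace(math.log10(0.01), math.log10(0.12), 10)
        K = np.asarray(
            K2(P, mol, ctx.laser, ctx.geometry) + K4(P, mol, ctx.laser, ctx.geometry)
        )
        a2 = a2_coefficient(mol, ctx.laser, ctx.geometry)
        fit = fit_quartic_excess(series_from_model(P, K, ctx), a2=a2)
        assert fit.product_mn_nc.value == pytest.approx(1.7e-35, rel=1e-6)
        assert fit.a4.value == pytest.approx(
            a4_coefficient(mol, ctx.laser, ctx.geometry), rel=1e-6
        )

    def test_quartic_excess_regime_mismatch(self):
        P = np.logspace(-2, -1, 8)
        K = 1.0 * P**2  # pure quadratic: excess is ~0/negative
        with pytest.raises(RegimeMismatchError):
            fit_quartic_excess(series_from_model(P, K), a2=1.1)

    def test_cubic_exact_recovery(self):
        ctx = make_context(lambda_nm=900.0, sigma2_gm=35.0, w0_um=4.2)
        mol = MolecularPhotophysics(sigma2_gm=35.0, sigma_mn=1e-17, phin=2e-3)
        P = np.linspace(0.01, 0.07, 8)
        K = K3(P, mol, ctx.laser, ctx.geometry)
        fit = fit_cubic(series_from_model(P, K, ctx))
        assert fit.sigma_mn_phi_n.value == pytest.approx(2e-20, rel=1e-6)
        assert fit.a3.value == pytest.approx(
            a3_coefficient(mol, ctx.laser, ctx.geometry), rel=1e-6
        )


class TestSaturatedFits:
    def test_saturated_3photon_noiseless_recovery(self, three_photon_molecule):
        ctx = make_context(lambda_nm=760.0, sigma2_gm=8.7, w0_um=3.63)
        mol = three_photon_molecule
        P = np.linspace(0.02, 0.12, 10)
        K = K3(P, mol, ctx.laser, ctx.geometry, saturated=True)
        series = series_from_model(P, K, ctx, rel_se=0.01)
        fit = fit_saturated_3photon(series, seed=1, n_boot=50)
        assert fit.sigma_mn.value == pytest.approx(1.4e-17, rel=1e-2)
        assert fit.phin.value == pytest.approx(2.2e-3, rel=1e-2)
        assert fit.sigma_mn_phi_n.value == pytest.approx(3.08e-20, rel=1e-2)

    def test_saturated_3photon_noisy_recovery_in_ci(self, three_photon_molecule):
        ctx = make_context(lambda_nm=760.0, sigma2_gm=8.7, w0_um=3.63)
        mol = three_photon_molecule
        P = np.linspace(0.02, 0.12, 10)
        K_true = np.asarray(K3(P, mol, ctx.laser, ctx.geometry, saturated=True))
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            K = K_true * np.exp(0.1 * rng.standard_normal(K_true.size))
            try:
                fit = fit_saturated_3photon(
                    series_from_model(P, K, ctx), seed=rep, n_boot=120
                )
            except NonIdentifiableError:
                continue
            ci = fit.phin.ci95
            if ci is not None and ci[0] <= 2.2e-3 <= ci[1]:
                hits += 1
        assert hits / n_rep >= 0.7

    def test_unsaturated_data_non_identifiable(self):
        # far below the saturation power the likelihood is flat in sigma_mn
        ctx = make_context(lambda_nm=900.0, sigma2_gm=35.0, w0_um=4.2)
        mol = MolecularPhotophysics(sigma2_gm=35.0, sigma_mn=1e-17, phin=2e-3)
        P = np.linspace(0.0005, 0.003, 8)
        K = K3(P, mol, ctx.laser, ctx.geometry)  # pure cubic
        with pytest.raises(NonIdentifiableError):
            fit_saturated_3photon(series_from_model(P, K, ctx), seed=0, n_boot=10)

    def test_saturated_4photon_noiseless_recovery(self, mcherry_780):
        ctx = make_context()
        P = np.linspace(0.03, 0.15, 12)
        K = K4(P, mcherry_780, ctx.laser, ctx.geometry, saturated=True)
        fit = fit_saturated_4photon(
            series_from_model(P, K, ctx, rel_se=0.01), seed=2, n_boot=50
        )
        assert fit.sigma_mn.value == pytest.approx(5.0e-17, rel=1e-2)
        assert fit.sigma_nc.value == pytest.approx(3.4e-19, rel=1e-2)
        assert fit.product_mn_nc.value == pytest.approx(1.7e-35, rel=1e-2)


class TestPipeline:
    def test_pure_quadratic_reports_phi_and_no_threshold(self):
        ctx = make_context(lambda_nm=1100.0, sigma2_gm=24.0, w0_um=4.5)
        mol = MolecularPhotophysics(sigma2_gm=24.0, phi1=1.6e-5)
        P = np.logspace(math.log10(0.01), math.log10(0.12), 8)
        rng = np.random.default_rng(5)
        K = np.asarray(K2(P, mol, ctx.laser, ctx.geometry))
        K = K * np.exp(0.05 * rng.standard_normal(K.size))
        result = infer_pipeline(series_from_model(P, K, ctx, rel_se=0.05), seed=0)
        assert result.Pstar is None
        assert result.phi is not None
        assert result.phi.value == pytest.approx(1.6e-5, rel=0.15)
        assert any("no threshold" in d for d in result.diagnostics)

    def test_full_range_bend_recovers_phi_product_and_threshold(self):
        ctx = make_context(lambda_nm=800.0, sigma2_gm=22.0, w0_um=3.78)
        mol = MolecularPhotophysics(
            sigma2_gm=22.0, phim=1.0e-4, product_mn_nc_explicit=5.0e-36
        )
        true_Pstar = predict_threshold_power(mol, ctx.laser, ctx.geometry)
        P = np.logspace(math.log10(0.01), math.log10(0.2), 14)
        K = np.asarray(
            K2(P, mol, ctx.laser, ctx.geometry) + K4(P, mol, ctx.laser, ctx.geometry)
        )
        rng = np.random.default_rng(9)
        K = K * np.exp(0.08 * rng.standard_normal(K.size))
        result = infer_pipeline(series_from_model(P, K, ctx, rel_se=0.08), seed=0)
        assert result.Pstar is not None
        assert result.Pstar.value == pytest.approx(true_Pstar, rel=0.2)
        assert result.phi.value == pytest.approx(1.0e-4, rel=0.25)
        assert result.product_mn_nc.value == pytest.approx(5.0e-36, rel=0.35)

    def test_high_exponent_regime_reports_exponent_only(self):
        P = np.logspace(math.log10(0.045), math.log10(0.06), 8)
        K = 1e-3 * (P / 0.045) ** 8
        result = infer_pipeline(series_from_model(P, K, rel_se=0.05), seed=0)
        assert result.alpha.value == pytest.approx(8.0, abs=0.3)
        assert result.phi is None and result.product_mn_nc is None
        assert any("exponent only" in d for d in result.diagnostics)

    def test_pipeline_deterministic_under_seed(self, three_photon_molecule):
        ctx = make_context(lambda_nm=760.0, sigma2_gm=8.7, w0_um=3.63)
        P = np.linspace(0.02, 0.12, 10)
        K_true = np.asarray(
            K3(P, three_photon_molecule, ctx.laser, ctx.geometry, saturated=True)
        )
        rng = np.random.default_rng(21)
        K = K_true * np.exp(0.1 * rng.standard_normal(K_true.size))
        series = series_from_model(P, K, ctx)
        r1 = infer_pipeline(series, seed=7, n_boot=60)
        r2 = infer_pipeline(series, seed=7, n_boot=60)
        assert r1.to_dict() == r2.to_dict()
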