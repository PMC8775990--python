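"""Shared fixtures: standard colony geometry, laser operating points, and
molecular parameter sets used across the suite."""

import math

import numpy as np
import pytest

from mpbleach.beam_optics import BeamGeometry, LaserConfig
from mpbleach.rate_models import MolecularPhotophysics


@pytest.fixture
def colony_geometry():
    """Factory: colony slab geometry at a given wavelength / waist."""

    def make(lambda_nm=1000.0, w0_um=4.5, l_um=200.0, n0=1.33):
        return BeamGeometry.from_units(
            w0_um=w0_um, lambda_nm=lambda_nm, n0=n0, l_um=l_um
        )

    return make


@pytest.fixture
def oscillator():
    """Factory: the 80 MHz / 109 fs imaging oscillator at a wavelength."""

    def make(lambda_nm=1000.0, P=0.0):
        return LaserConfig(lambda_nm=lambda_nm, f=80e6, dtau=109e-15, P=P)

    return make


@pytest.fixture
def geometry_with_eta(colony_geometry):
    """Factory: colony geometry adjusted to an exact eta value."""

    def make(eta, lambda_nm=1000.0, w0_um=4.5):
        base = colony_geometry(lambda_nm=lambda_nm, w0_um=w0_um)
        return BeamGeometry(
            w0=base.w0,
            lambda_vac=base.lambda_vac,
            n0=base.n0,
            l=eta * 2.0 * base.zR,
        )

    return make


@pytest.fixture
def mcherry_1100():
    return MolecularPhotophysics(sigma2_gm=24.0, phi1=1.6e-5, phiF=0.24, vde_ev=5.52)


@pytest.fixture
def mcherry_780():
    return MolecularPhotophysics(
        sigma2_gm=42.0,
        phim=8.5e-5,
        sigma_mn=5.0e-17,
        sigma_nc=3.4e-19,
        phiF=0.24,
        vde_ev=5.52,
    )


@pytest.fixture
def three_photon_molecule():
    """A 2+1 bleacher with the separable sigma_mn / phin of the red Ca2+
    sensor at its saturating wavelength."""
    return MolecularPhotophysics(
        sigma2_gm=8.7, sigma_mn=1.4e-17, phin=2.2e-3, phiF=0.21
    )
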