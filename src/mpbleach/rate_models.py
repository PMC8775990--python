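"""Closed-form multiphoton photobleaching rate laws and derived predictors.

The observed initial bleaching rate of fluorophores in a slab illuminated by
a focused Gaussian-Lorentzian (GL) beam decomposes into contributions of
increasing photon order,

    K = K(2) + K(3) + K(4) + ...,

each a closed-form function of average power P, the laser operating point
(f, dtau, hnu), the focal geometry (w0, eta) and molecular photophysics:

* ``K2``   -- two-photon excitation followed by reaction with yield phi1
  (from S1, Kasha pathway) or phim (from a higher state Sm);
  K(2) = (1/pi^2) sigma2 phi Gamma3(eta) / (dtau f hnu^2 w0^4) * P^2.
* ``K3``   -- 2+1 photon process through a one-photon m->n step
  (cross section sigma_mn) with reaction yield phin from n; cubic in P when
  the step is far from saturation, with a quadratic-in-P/Ps correction
  bracket when it is slightly saturated.
* ``K4``   -- 2+1+1 photon process terminating in photoionization
  (electron photodetachment) with cross section sigma_nc; quartic in P
  unsaturated, slope -> 3 under strong saturation of the m->n step.

The saturation power Ps = (pi/4) f hnu w0^2 / sigma_mn sets the scale of the
dimensionless pumping parameter X = P/Ps (equivalently 2 sigma_mn * photons
per cm^2 per pulse).  ``predict_threshold_power`` gives the power P* at which
K(2) = K(4) -- the recommended operating point for two-photon microscopy --
and ``photons_required`` / ``critical_wavelength`` implement the energy
budget n * hnu >= VDE for photodetachment-driven bleaching.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .beam_optics import BeamGeometry, LaserConfig, gamma_factor
from .constants import GM_CM4S, HC_EV_NM
from .exceptions import (
    DomainWarning,
    InvalidParameterError,
    ParameterMissingError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MolecularPhotophysics",
    "SaturationState",
    "K2",
    "K3",
    "K4",
    "total_rate",
    "saturation_power",
    "saturation_parameter_uniform",
    "a2_coefficient",
    "a3_coefficient",
    "a4_coefficient",
    "phi_from_a2",
    "sigma_mn_phi_n_from_a3",
    "product_mn_nc_from_a4",
    "predict_threshold_power",
    "k1_homogeneous",
    "k1_bracket",
    "photons_required",
    "critical_wavelength",
    "figure_of_merit",
]


@dataclass(frozen=True)
class MolecularPhotophysics:
    """Photophysical parameters of one fluorophore at one wavelength.

    All yields are dimensionless in [0, 1]; ``sigma2_gm`` is the two-photon
    absorption cross section in GM; one-photon cross sections in cm^2;
    ``product_mn_nc`` (cm^4) may be supplied when the individual factors are
    unknown.  ``vde_ev`` is the vertical electron detachment energy in eV and
    ``phiF`` the fluorescence quantum yield.
    """

    sigma2_gm: Optional[float] = None
    phi1: Optional[float] = None
    phim: Optional[float] = None
    phin: Optional[float] = None
    sigma_mn: Optional[float] = None
    sigma_nc: Optional[float] = None
    product_mn_nc_explicit: Optional[float] = None
    vde_ev: Optional[float] = None
    phiF: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("phi1", "phim", "phin", "phiF"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "sigma2_gm",
            "sigma_mn",
            "sigma_nc",
            "product_mn_nc_explicit",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if (
            self.product_mn_nc_explicit is not None
            and self.sigma_mn is not None
            and self.sigma_nc is not None
        ):
            implied = self.sigma_mn * self.sigma_nc
            if abs(self.product_mn_nc_explicit - implied) > 1e-9 * abs(implied):
                raise InvalidParameterError(
                    "product_mn_nc inconsistent with sigma_mn * sigma_nc"
                )

    @property
    def sigma2_cm4s(self) -> float:
        if self.sigma2_gm is None:
            raise ParameterMissingError("sigma2 (2PA cross section) is not set")
        return self.sigma2_gm * GM_CM4S

    @property
    def phi_quadratic(self) -> float:
        """Reaction yield of the quadratic regime: phi1 if set, else phim."""
        if self.phi1 is not None:
            return self.phi1
        if self.phim is not None:
            return self.phim
        raise ParameterMissingError("neither phi1 nor phim is set")

    @property
    def product_mn_nc(self) -> float:
        """sigma_mn * sigma_nc (cm^4), explicit or from the factors."""
        if self.product_mn_nc_explicit is not None:
            return self.product_mn_nc_explicit
        if self.sigma_mn is not None and self.sigma_nc is not None:
            return self.sigma_mn * self.sigma_nc
        raise ParameterMissingError(
            "sigma_mn*sigma_nc is not set (neither product nor both factors)"
        )

    def evolve(self, **kwargs) -> "MolecularPhotophysics":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SaturationState:
    """Saturation power Ps (W) and dimensionless parameter X = P/Ps."""

    Ps: float
    X: float


# ---------------------------------------------------------------------------
# Slope coefficients a_n of K = a_n P^n and their inversions
# ---------------------------------------------------------------------------


def a2_coefficient(
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    phi: Optional[float] = None,
) -> float:
    """Quadratic slope a2 = K(2)/P^2 (s^-1 W^-2)."""
    if phi is None:
        phi = molecule.phi_quadratic
    return (
        molecule.sigma2_cm4s
        * phi
        * gamma_factor(3, geometry.eta)
        / (math.pi**2 * laser.dtau * laser.f * laser.hnu**2 * geometry.w0**4)
    )


def a3_coefficient(
    molecule: MolecularPhotophysics, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Cubic slope a3 = K(3)/P^3 (s^-1 W^-3), unsaturated 2+1 process."""
    if molecule.sigma_mn is None or molecule.phin is None:
        raise ParameterMissingError("a3 requires sigma_mn and phin")
    return (
        4.0
        * molecule.sigma2_cm4s
        * molecule.sigma_mn
        * molecule.phin
        * gamma_factor(4, geometry.eta)
        / (
            5.0
            * math.pi**3
            * laser.dtau
            * laser.f**2
            * laser.hnu**3
            * geometry.w0**6
        )
    )


def a4_coefficient(
    molecule: MolecularPhotophysics, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Quartic slope a4 = K(4)/P^4 (s^-1 W^-4), unsaturated 2+1+1 process."""
    return (
        4.0
        * molecule.sigma2_cm4s
        * molecule.product_mn_nc
        * gamma_factor(5, geometry.eta)
        / (
            9.0
            * math.pi**4
            * laser.dtau
            * laser.f**3
            * laser.hnu**4
            * geometry.w0**8
        )
    )


def phi_from_a2(
    a2: float, sigma2_gm: float, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Invert the quadratic slope for the reaction quantum yield phi1 or phim."""
    return (
        a2
        * math.pi**2
        * laser.dtau
        * laser.f
        * laser.hnu**2
        * geometry.w0**4
        / (sigma2_gm * GM_CM4S * gamma_factor(3, geometry.eta))
    )


def sigma_mn_phi_n_from_a3(
    a3: float, sigma2_gm: float, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Invert the cubic slope for the product sigma_mn * phin (cm^2)."""
    return (
        a3
        * 5.0
        * math.pi**3
        * laser.dtau
        * laser.f**2
        * laser.hnu**3
        * geometry.w0**6
        / (4.0 * sigma2_gm * GM_CM4S * gamma_factor(4, geometry.eta))
    )


def product_mn_nc_from_a4(
    a4: float, sigma2_gm: float, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Invert the quartic slope for sigma_mn * sigma_nc (cm^4)."""
    return (
        a4
        * 9.0
        * math.pi**4
        * laser.dtau
        * laser.f**3
        * laser.hnu**4
        * geometry.w0**8
        / (4.0 * sigma2_gm * GM_CM4S * gamma_factor(5, geometry.eta))
    )


# ---------------------------------------------------------------------------
# Rate laws
# ---------------------------------------------------------------------------


def saturation_power(
    molecule: MolecularPhotophysics, laser: LaserConfig, geometry: BeamGeometry
) -> float:
    """Saturation power Ps = (pi/4) f hnu w0^2 / sigma_mn (W)."""
    if molecule.sigma_mn is None or molecule.sigma_mn <= 0:
        raise ParameterMissingError("Ps requires a positive sigma_mn")
    return math.pi / 4.0 * laser.f * laser.hnu * geometry.w0**2 / molecule.sigma_mn


def saturation_parameter_uniform(sigma_mn: float, photons_per_pulse_cm2: float) -> float:
    """X for a spatially uniform beam: X = 2 sigma_mn * (photons/cm^2/pulse).

    Consistent with X = P/Ps for the focused GL beam, where the on-axis
    photons per pulse per area is I0 * dtau.
    """
    return 2.0 * sigma_mn * photons_per_pulse_cm2


def K2(
    P,
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    phi: Optional[float] = None,
):
    """Observed two-photon bleaching rate (s^-1); exactly quadratic in P (W)."""
    return a2_coefficient(molecule, laser, geometry, phi=phi) * np.asarray(P) ** 2


def K3(
    P,
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    saturated: bool = False,
):
    """Observed 2+1-photon bleaching rate (s^-1).

    Unsaturated: cubic in P.  ``saturated=True`` evaluates the slight-
    saturation fitting function, a bracket quadratic in P/Ps that reduces to
    the cubic law as P/Ps -> 0; a :class:`DomainWarning` is emitted where the
    bracket turns negative (beyond the approximation's validity).
    """
    P = np.asarray(P, dtype=float)
    if not saturated:
        return a3_coefficient(molecule, laser, geometry) * P**3
    if molecule.phin is None:
        raise ParameterMissingError("saturated K3 requires phin")
    Ps = saturation_power(molecule, laser, geometry)
    x = P / Ps
    eta = geometry.eta
    g4, g5 = gamma_factor(4, eta), gamma_factor(5, eta)
    bracket = g4 / 5.0 * x - g5 / 18.0 * x**2
    if np.any(bracket < 0):
        warnings.warn(
            "saturated K3 bracket negative: P/Ps beyond the quadratic "
            "approximation's validity domain",
            DomainWarning,
            stacklevel=2,
        )
    pref = molecule.sigma2_cm4s * molecule.phin / (
        math.pi**2 * laser.dtau * laser.f * laser.hnu**2 * geometry.w0**4
    )
    return pref * bracket * P**2


def K4(
    P,
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    saturated: bool = False,
):
    """Observed 2+1+1-photon bleaching rate (s^-1).

    Unsaturated: quartic in P (needs only the product sigma_mn*sigma_nc).
    ``saturated=True`` evaluates the strong-saturation law (needs the
    individual cross sections), whose high-power log-log slope tends to 3.
    """
    P = np.asarray(P, dtype=float)
    if not saturated:
        return a4_coefficient(molecule, laser, geometry) * P**4
    if molecule.sigma_mn is None or molecule.sigma_nc is None:
        raise ParameterMissingError("saturated K4 requires sigma_mn and sigma_nc")
    Ps = saturation_power(molecule, laser, geometry)
    X = P / Ps
    eta = geometry.eta
    g2, g3, g4 = (gamma_factor(i, eta) for i in (2, 3, 4))
    bracket = g4 / 10.0 * X**2 - g3 / 4.0 * X + g2 / 3.0
    if np.any(bracket < 0):  # cannot happen for the GL gammas; guard anyway
        warnings.warn(
            "saturated K4 bracket negative", DomainWarning, stacklevel=2
        )
    pref = (
        molecule.sigma2_cm4s
        * molecule.sigma_nc
        / (
            4.0
            * math.pi
            * molecule.sigma_mn**2
            * laser.hnu
            * laser.dtau
            * geometry.w0**2
        )
    )
    return pref * bracket * P


def total_rate(
    P,
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    saturated: bool = False,
):
    """Sum of K(2), K(3) and K(4); terms with missing parameters contribute 0."""
    P = np.asarray(P, dtype=float)
    total = np.zeros_like(P, dtype=float)
    contributed = []
    for name, fn in (
        ("K2", lambda: K2(P, molecule, laser, geometry)),
        ("K3", lambda: K3(P, molecule, laser, geometry, saturated=saturated)),
        ("K4", lambda: K4(P, molecule, laser, geometry, saturated=saturated)),
    ):
        try:
            total = total + fn()
            contributed.append(name)
        except ParameterMissingError:
            logger.info("total_rate: %s parameters missing, term skipped", name)
    if not contributed:
        raise ParameterMissingError("no rate-law term has its parameters set")
    return total


# ---------------------------------------------------------------------------
# Threshold, homogeneous beam, photon budget, figures of merit
# ---------------------------------------------------------------------------


def predict_threshold_power(
    molecule: MolecularPhotophysics,
    laser: LaserConfig,
    geometry: BeamGeometry,
    phi: Optional[float] = None,
) -> float:
    """Power P* (W) at which K(2) equals K(4).

    P* = (3 pi / 2) sqrt(phi_m / (sigma_mn sigma_nc)) sqrt(Gamma3/Gamma5)
         * f * hnu * w0^2,
    identical to sqrt(a2/a4) built from the two slope coefficients.
    """
    if phi is None:
        phi = molecule.phi_quadratic
    product = molecule.product_mn_nc
    if product <= 0:
        raise InvalidParameterError(
            "threshold undefined: sigma_mn*sigma_nc must be positive"
        )
    eta = geometry.eta
    return (
        1.5
        * math.pi
        * math.sqrt(phi / product)
        * math.sqrt(gamma_factor(3, eta) / gamma_factor(5, eta))
        * laser.f
        * laser.hnu
        * geometry.w0**2
    )


def k1_bracket(X):
    """Saturation bracket (1/2)X^3 - X^2 + X - X e^{-X}; ~ X^4/6 as X -> 0."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise InvalidParameterError("X must be >= 0")
    exact = 0.5 * X**3 - X**2 - X * np.expm1(-X)
    # alternating series X^4/6 - X^5/24 + X^6/120 - ... for the cancelling region
    series = X**4 / 6.0 - X**5 / 24.0 + X**6 / 120.0 - X**7 / 720.0
    return np.where(X < 1e-2, series, exact)


def k1_homogeneous(
    X, molecule: MolecularPhotophysics, f: float, dtau: float
):
    """Molecular bleaching rate k1 (s^-1) in a spatially uniform pulsed beam.

    The four-photon (2+1+1) pathway with a saturable m<->n step, solved
    per pulse without any spatial averaging:

        k1 = (1/32) (sigma2 sigma_nc / sigma_mn^3) (f/dtau)
             * [X^3/2 - X^2 + X - X e^{-X}]

    with X = 2 sigma_mn * (photons per cm^2 per pulse).
    """
    if molecule.sigma_mn is None or molecule.sigma_nc is None:
        raise ParameterMissingError("k1 requires sigma_mn and sigma_nc")
    return (
        molecule.sigma2_cm4s
        * molecule.sigma_nc
        / (32.0 * molecule.sigma_mn**3)
        * (f / dtau)
        * k1_bracket(X)
    )


def photons_required(vde_ev: float, lambda_nm: float) -> int:
    """Minimum photon count n with n * hnu >= VDE at the given wavelength."""
    if vde_ev <= 0 or lambda_nm <= 0:
        raise InvalidParameterError("VDE and wavelength must be positive")
    hnu_ev = HC_EV_NM / lambda_nm
    return int(math.ceil(vde_ev / hnu_ev - 1e-12))


def critical_wavelength(vde_ev: float, n: int) -> float:
    """Longest wavelength (nm) at which n photons reach the detachment energy."""
    if vde_ev <= 0 or n < 1:
        raise InvalidParameterError("VDE must be positive and n >= 1")
    return n * HC_EV_NM / vde_ev


def figure_of_merit(order: int, molecule: MolecularPhotophysics) -> float:
    """Figure of merit for two-photon imaging: fluorescence photons obtainable
    before bleaching, for the bleaching mechanism of the given order.

    order 2: phiF / phi_{1,m}
    order 3: phiF * sigma2^(1/3) / (sigma_mn phin)^(2/3)
    order 4: phiF * sigma2^(1/2) / (sigma_mn sigma_nc)^(1/2)

    with sigma2 in cm^4 s.  Comparisons across proteins or wavelengths are
    meaningful only at equal peak photon flux and equal mechanism.
    """
    if order not in (2, 3, 4):
        raise InvalidParameterError("figure of merit defined for orders 2, 3, 4")
    if molecule.phiF is None:
        raise ParameterMissingError("figure of merit requires phiF")
    if molecule.phiF == 0.0:
        return 0.0
    if order == 2:
        return molecule.phiF / molecule.phi_quadratic
    if order == 3:
        if molecule.sigma_mn is None or molecule.phin is None:
            raise ParameterMissingError("FOM(3) requires sigma_mn and phin")
        return (
            molecule.phiF
            * molecule.sigma2_cm4s ** (1.0 / 3.0)
            / (molecule.sigma_mn * molecule.phin) ** (2.0 / 3.0)
        )
    return molecule.phiF * math.sqrt(molecule.sigma2_cm4s / molecule.product_mn_nc)
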