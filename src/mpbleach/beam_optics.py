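"""Gaussian-Lorentzian focal field and the geometry factors of the rate laws.

A femtosecond beam focused by a low-NA objective is described by the paraxial
Gaussian-Lorentzian (GL) intensity distribution

    I(r, z) = I0 * (w0^2 / w(z)^2) * exp(-2 r^2 / w(z)^2),
    w(z)^2  = w0^2 * (1 + ((z - z0)/zR)^2),      zR = n0 pi w0^2 / lambda,

with a rectangular temporal pulse of width ``dtau`` repeating at rate ``f``.
The observed photobleaching rate is the initial decay rate of the two-photon
fluorescence signal, i.e. the I^2-weighted volume average of the local
bleaching rate over a sample slab of thickness ``l``.  All such averages of
integer powers of the GL field reduce to the axial moments

    J_i(eta) = Integral_{-eta}^{eta} (1 + zeta^2)^(-i) dzeta,
    eta      = l / (2 zR),

and enter the closed-form rate laws through the ratios
``Gamma_i(eta) = J_i(eta) / J_1(eta)``.  ``Gamma_i`` equals 1 for a thin slab
and decreases towards ``J_i(inf)/pi`` for a thick one; only ratios such as
``Gamma_3/Gamma_5`` (threshold prediction) exceed 1.

The module also provides a brute-force observed-rate oracle that integrates
the per-pulse solution of the level-scheme rate equations over the focal
volume numerically; the closed-form laws in :mod:`mpbleach.rate_models` are
validated against it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Union

import numpy as np
from numpy.polynomial.legendre import leggauss

from .constants import (
    DEFAULT_COLONY_N0,
    DEFAULT_COLONY_THICKNESS_CM,
    EV_J,
    HC_EV_NM,
)
from .exceptions import (
    AccuracyWarning,
    InvalidParameterError,
    UnsupportedOrderError,
)

__all__ = [
    "BeamGeometry",
    "LaserConfig",
    "GammaFactors",
    "LevelScheme",
    "MonomialScheme",
    "intensity_field",
    "peak_flux_from_power",
    "power_from_peak_flux",
    "photon_energy_j",
    "gamma_factor",
    "axial_moment",
    "per_pulse_bleach_probability",
    "brute_force_observed_rate",
]


def photon_energy_j(lambda_nm: float) -> float:
    """Photon energy in joules at vacuum wavelength ``lambda_nm``."""
    if lambda_nm <= 0:
        raise InvalidParameterError("wavelength must be positive")
    return HC_EV_NM / lambda_nm * EV_J


# ---------------------------------------------------------------------------
# Geometry and laser configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamGeometry:
    """Focal field geometry and the sample slab it illuminates.

    Parameters
    ----------
    w0:
        Beam waist radius at focus (cm).
    lambda_vac:
        Vacuum wavelength (cm).
    n0:
        Refractive index of the medium (1.33 for the aqueous colony).
    z0:
        Axial position of the focal plane relative to the slab centre (cm).
        The slab occupies ``[-l/2, l/2]``; ``z0 = 0`` is the focus-at-centre
        configuration obtained experimentally by maximising the signal.
    l:
        Sample slab thickness (cm).
    """

    w0: float
    lambda_vac: float
    n0: float = DEFAULT_COLONY_N0
    z0: float = 0.0
    l: float = DEFAULT_COLONY_THICKNESS_CM

    def __post_init__(self) -> None:
        if self.w0 <= 0:
            raise InvalidParameterError("beam waist w0 must be positive")
        if self.lambda_vac <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if self.n0 < 1:
            raise InvalidParameterError("refractive index must be >= 1")
        if self.l < 0:
            raise InvalidParameterError("slab thickness must be >= 0")

    @classmethod
    def from_units(
        cls,
        w0_um: float,
        lambda_nm: float,
        n0: float = DEFAULT_COLONY_N0,
        z0_um: float = 0.0,
        l_um: float = DEFAULT_COLONY_THICKNESS_CM * 1e4,
    ) -> "BeamGeometry":
        """Construct from micrometre / nanometre inputs."""
        return cls(
            w0=w0_um * 1e-4,
            lambda_vac=lambda_nm * 1e-7,
            n0=n0,
            z0=z0_um * 1e-4,
            l=l_um * 1e-4,
        )

    @property
    def zR(self) -> float:
        """Rayleigh length in the medium (cm): zR = n0 pi w0^2 / lambda."""
        return self.n0 * math.pi * self.w0**2 / self.lambda_vac

    @property
    def eta(self) -> float:
        """Slab half-thickness in Rayleigh units: eta = l / (2 zR)."""
        return self.l / (2.0 * self.zR)

    def w2(self, z):
        """Squared beam radius w(z)^2 at axial position ``z`` (cm^2)."""
        return self.w0**2 * (1.0 + ((np.asarray(z) - self.z0) / self.zR) ** 2)

    def w(self, z):
        """Beam radius w(z) (cm)."""
        return np.sqrt(self.w2(z))


@dataclass(frozen=True)
class LaserConfig:
    """Pulsed-laser operating point.

    ``lambda_nm`` in nm, repetition rate ``f`` in Hz, pulse duration ``dtau``
    in s, average power ``P`` in W.  ``hnu`` is the photon energy in J.
    """

    lambda_nm: float
    f: float
    dtau: float
    P: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_nm <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if self.f < 0 or self.dtau < 0 or self.P < 0:
            raise InvalidParameterError("f, dtau and P must be >= 0")
        if self.f * self.dtau >= 1:
            raise InvalidParameterError("duty cycle f*dtau must be < 1")

    @property
    def hnu(self) -> float:
        """Photon energy (J)."""
        return photon_energy_j(self.lambda_nm)

    def with_power(self, P: float) -> "LaserConfig":
        return replace(self, P=P)


# ---------------------------------------------------------------------------
# Field and flux conversions
# ---------------------------------------------------------------------------


def intensity_field(r, z, geometry: BeamGeometry, I0: float):
    """Local photon flux of the GL field (photons / cm^2 / s) during the pulse.

    Equals ``I0`` on axis in the focal plane and falls off as a radial
    Gaussian and an axial Lorentzian.
    """
    if np.any(np.asarray(I0) < 0):
        raise InvalidParameterError("peak flux I0 must be >= 0")
    w2 = geometry.w2(z)
    return I0 * (geometry.w0**2 / w2) * np.exp(-2.0 * np.asarray(r) ** 2 / w2)


def peak_flux_from_power(
    laser: LaserConfig, geometry: BeamGeometry, P: float | None = None
):
    """Peak on-axis photon flux I0 (photons / cm^2 / s) at average power P.

    Inverts P = (pi/2) f hnu dtau w0^2 I0, the time- and focal-plane-area
    integral of the GL field.
    """
    if P is None:
        P = laser.P
    if laser.f <= 0 or laser.dtau <= 0:
        raise InvalidParameterError("f and dtau must be positive")
    if geometry.w0 <= 0:  # pragma: no cover - enforced at construction
        raise InvalidParameterError("w0 must be positive")
    return 2.0 * np.asarray(P) / (
        math.pi * laser.f * laser.hnu * laser.dtau * geometry.w0**2
    )


def power_from_peak_flux(I0, laser: LaserConfig, geometry: BeamGeometry):
    """Average power P (W) producing peak flux ``I0``; inverse of
    :func:`peak_flux_from_power`."""
    return (
        math.pi / 2.0 * laser.f * laser.hnu * laser.dtau * geometry.w0**2
    ) * np.asarray(I0)


# ---------------------------------------------------------------------------
# Gamma factors
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4096)
def axial_moment(i: int, eta: float) -> float:
    """Axial moment J_i(eta) = Integral_{-eta}^{eta} (1+x^2)^(-i) dx.

    Evaluated by the exact reduction formula; even and strictly increasing in
    eta with finite limit as eta -> inf.
    """
    if i < 1:
        raise UnsupportedOrderError("axial moment defined for i >= 1")
    if eta <= 0:
        raise InvalidParameterError("eta must be positive")
    J = 2.0 * math.atan(eta)
    for m in range(2, i + 1):
        J = eta / ((m - 1) * (1.0 + eta**2) ** (m - 1)) + (
            (2 * m - 3) / (2.0 * (m - 1))
        ) * J
    return J


def gamma_factor(i: int, eta: float) -> float:
    """Geometry factor Gamma_i(eta) = J_i(eta) / J_1(eta) for i in {2..5}.

    These are the volume/time-averaging factors through which the slab
    geometry enters the closed-form rate laws: the I^2-weighted average of
    I^(2(i-1)) over the GL field inside the slab is proportional to
    Gamma_i(eta) * I0^(2(i-2)).
    """
    if i not in (2, 3, 4, 5):
        raise UnsupportedOrderError(
            f"Gamma factor index must be in {{2,3,4,5}}, got {i}"
        )
    return axial_moment(i, eta) / axial_moment(1, eta)


@dataclass(frozen=True)
class GammaFactors:
    """The four geometry factors at a fixed ``eta``, as a mapping i -> Gamma_i."""

    eta: float
    gamma: Mapping[int, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gamma is None:
            object.__setattr__(
                self, "gamma", {i: gamma_factor(i, self.eta) for i in (2, 3, 4, 5)}
            )

    @classmethod
    def from_geometry(cls, geometry: BeamGeometry) -> "GammaFactors":
        return cls(eta=geometry.eta)

    def __getitem__(self, i: int) -> float:
        return self.gamma[i]


def _validate_gamma_closed_forms() -> None:
    """Cross-check the reduction-formula moments against direct quadrature."""
    from scipy.integrate import quad

    for eta in (0.1, 1.0, 10.0):
        for i in (2, 3, 4, 5):
            ref, _ = quad(lambda x, i=i: (1.0 + x * x) ** (-i), -eta, eta)
            val = axial_moment(i, eta)
            if abs(val - ref) > 1e-8 * abs(ref):  # pragma: no cover
                raise AssertionError(
                    f"Gamma closed form disagrees with quadrature: i={i}, eta={eta}"
                )


_validate_gamma_closed_forms()


# ---------------------------------------------------------------------------
# Level schemes and the brute-force observed-rate oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelScheme:
    """Mechanistic bleaching pathway of order 2, 3 or 4.

    order 2: two-photon excitation followed by reaction with yield phi1 (from
    S1) or phim (from Sm).  order 3: two-photon excitation plus one saturable
    one-photon step m->n, reaction from n with yield phin.  order 4: as order
    3 plus photoionization n->continuum with cross section sigma_nc.

    ``saturated=True`` uses the exact per-pulse two-level solution of the
    m<->n pumping (equal absorption and stimulated-emission rates
    sigma_mn * I); ``saturated=False`` uses the weak-pumping limit.
    """

    order: int
    saturated: bool = True

    def __post_init__(self) -> None:
        if self.order not in (2, 3, 4):
            raise UnsupportedOrderError(
                f"level scheme order must be 2, 3 or 4, got {self.order}"
            )


@dataclass(frozen=True)
class MonomialScheme:
    """Phenomenological local rate: per-pulse bleach probability c * I^n * dtau.

    Used for regimes without a mechanistic equation (e.g. the alpha ~ 8
    power law) and as a pure power-law probe of the volume averaging.
    """

    n: float
    c: float = 1.0

    def __post_init__(self) -> None:
        if not (1.0 <= self.n <= 12.0):
            raise InvalidParameterError("monomial order n must be in [1, 12]")
        if self.c < 0:
            raise InvalidParameterError("monomial coefficient must be >= 0")


Scheme = Union[LevelScheme, MonomialScheme]


def per_pulse_bleach_probability(I, scheme: Scheme, molecule, dtau: float):
    """Probability that a molecule at local flux ``I`` bleaches during one pulse.

    ``molecule`` must expose ``sigma2_cm4s``, ``phi_quadratic``/``phin`` and
    ``sigma_mn``/``sigma_nc`` as required by the scheme order (duck-typed so
    this low-level module does not depend on :mod:`mpbleach.rate_models`).

    The expressions are the exact solutions of the within-pulse rate
    equations for a rectangular pulse: a two-photon excitation-event rate
    ``g = sigma2 I^2 / 2``, a saturable two-level m<->n step pumped at rate
    ``a = 2 sigma_mn I`` (absorption + stimulated emission, equilibrium
    population 1/2), and a perturbative ionization branch ``sigma_nc I``.
    """
    I = np.asarray(I, dtype=float)
    g = 0.5 * molecule.sigma2_cm4s * I**2
    if isinstance(scheme, MonomialScheme):
        return scheme.c * I**scheme.n * dtau

    if scheme.order == 2:
        return molecule.phi_quadratic * g * dtau

    X = 2.0 * molecule.sigma_mn * I * dtau
    small = X < 1e-3  # series branch for the cancelling expm1 combinations

    if scheme.order == 3:
        if scheme.saturated:
            # time-averaged n population over entry times:
            #   (1/2) * [1 - (1 - exp(-X))/X]  ->  X/4 as X -> 0
            Xs = np.where(X > 0, X, 1.0)
            exact = 0.5 * (1.0 + np.expm1(-Xs) / Xs)
            series = X / 4.0 - X**2 / 12.0 + X**3 / 48.0
            return molecule.phin * g * dtau * np.where(small, series, exact)
        return molecule.phin * g * molecule.sigma_mn * I * dtau**2 / 2.0

    # order 4
    if scheme.saturated:
        # bracket = X^2/2 - X + 1 - exp(-X)  ->  X^3/6 as X -> 0;
        # per-pulse probability g * sigma_nc * I * bracket / (2 a^2), a = X/dtau
        exact = 0.5 * X**2 - X - np.expm1(-np.where(X > 0, X, 1.0))
        exact = np.where(X > 0, exact, 0.0)
        series = X**3 / 6.0 - X**4 / 24.0 + X**5 / 120.0
        bracket = np.where(small, series, exact)
        a = np.where(X > 0, X / dtau, 1.0)
        return np.where(
            X > 0, g * molecule.sigma_nc * I * bracket / (2.0 * a**2), 0.0
        )
    return (
        molecule.sigma2_cm4s
        * molecule.sigma_mn
        * molecule.sigma_nc
        * I**4
        * dtau**3
        / 12.0
    )


def brute_force_observed_rate(
    scheme: Scheme,
    molecule,
    laser: LaserConfig,
    geometry: BeamGeometry,
    P: float | None = None,
    n_z: int = 201,
    n_v: int = 96,
    check_convergence: bool = False,
    rtol: float = 1e-6,
) -> float:
    """Observed initial bleaching rate K (1/s) by direct numerical averaging.

    Integrates the I^2-weighted per-pulse bleaching probability of the level
    scheme over the slab: Gauss-Legendre nodes along z and, per slice, along
    the substituted radial variable v = exp(-2 r^2 / w(z)^2) which maps the
    radial Gaussian onto [0, 1].  Serves as the reference oracle for every
    closed-form rate law.
    """
    I0 = float(peak_flux_from_power(laser, geometry, P))
    if I0 == 0.0:
        return 0.0

    def _rate(nz: int, nv: int) -> float:
        xz, wz = leggauss(nz)
        z = 0.5 * geometry.l * xz  # slab [-l/2, l/2]
        wz = 0.5 * geometry.l * wz
        xv, wv = leggauss(nv)
        v = 0.5 * (xv + 1.0)  # (0, 1)
        wv = 0.5 * wv

        w2 = geometry.w2(z)  # (nz,)
        u = geometry.w0**2 / w2
        Imax = I0 * u
        I_local = Imax[:, None] * v[None, :]
        p = per_pulse_bleach_probability(I_local, scheme, molecule, laser.dtau)
        # numerator: sum_z wz * (pi w^2 / 2) Imax^2 * int v p dv
        num = np.sum(
            wz * (math.pi * w2 / 2.0) * Imax**2 * np.sum(wv * v * p, axis=1)
        )
        den = np.sum(wz * (math.pi * w2 / 2.0) * Imax**2) * 0.5
        return laser.f * num / den

    K = _rate(n_z, n_v)
    if check_convergence:
        K2 = _rate(2 * n_z + 1, 2 * n_v)
        if abs(K2 - K) > rtol * max(abs(K2), 1e-300):
            warnings.warn(
                f"observed-rate quadrature not converged: rel change "
                f"{abs(K2 - K) / max(abs(K2), 1e-300):.2e}",
                AccuracyWarning,
                stacklevel=2,
            )
        K = K2
    return float(K)
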