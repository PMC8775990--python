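"""Beam, pulse and spectrum calibration fits.

* Knife-edge scans: transmitted power vs razor position follows a cumulative
  Gaussian (erf) profile whose width is the local beam radius w(z).
* Waist profile: w(z) follows the Gaussian-beam hyperbola
  w(z) = w0 sqrt(1 + (lambda (z-z0) / (pi w0^2))^2) (in air).
* Fluorescence z-profile through a colony: the per-slice two-photon signal of
  the Gaussian-Lorentzian field is the area integral of I^2, a Lorentzian
  1/(1+(z/zR)^2); a uniform fluorophore slab of thickness l therefore
  produces the convolution rect(l) * Lorentzian, which integrates to a
  difference of arctangents.  Fitting it yields l, the in-medium Rayleigh
  length and hence w0 = sqrt(lambda zR / (n0 pi)).
* Relative pulse duration vs wavelength from a thick reference-dye cuvette:
  for l >> zR the two-photon signal obeys F2 = C sigma2(lambda) / (lambda
  dtau(lambda)) P^2, inverted and anchored to a known dtau at one wavelength.
* Corrected two-photon excitation spectra by the reference-ratio method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .exceptions import (
    InsufficientDataError,
    InvalidParameterError,
    PlausibilityWarning,
    UnconstrainedFitError,
    ValidationError,
)

__all__ = [
    "KnifeEdgeScan",
    "ZProfile",
    "CalibrationFit",
    "knife_edge_fit",
    "waist_profile_fit",
    "zprofile_fit",
    "pulse_duration_calibration",
    "corrected_2pe_spectrum",
]

#: plausible beam-waist band for the low-NA objective of this instrument (cm)
WAIST_PLAUSIBLE_CM = (3.5e-4, 5.5e-4)


@dataclass(frozen=True)
class KnifeEdgeScan:
    """Razor-blade scan: knife positions x (cm), transmitted power (W)."""

    x: np.ndarray
    Ptrans: np.ndarray
    z: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        P = np.asarray(self.Ptrans, dtype=float)
        if x.shape != P.shape or x.ndim != 1:
            raise InvalidParameterError("x and Ptrans must match in length")
        dx = np.diff(x)
        if not (np.all(dx > 0) or np.all(dx < 0)):
            raise InvalidParameterError("knife positions must be monotonic")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "Ptrans", P)


@dataclass(frozen=True)
class ZProfile:
    """Axial fluorescence profile through a colony (z in cm, F arbitrary)."""

    z: np.ndarray
    F: np.ndarray
    stitched: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if z.shape != F.shape or z.ndim != 1:
            raise InvalidParameterError("z and F must match in length")
        order = np.argsort(z, kind="stable")
        object.__setattr__(self, "z", z[order])
        object.__setattr__(self, "F", F[order])


@dataclass(frozen=True)
class CalibrationFit:
    """Collected beam/sample calibration parameters (all lengths in cm)."""

    w0: Optional[float] = None
    z0: Optional[float] = None
    zR: Optional[float] = None
    l: Optional[float] = None
    C: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("w0", "zR", "l"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidParameterError(f"{name} must be positive")


# ---------------------------------------------------------------------------


def _se_from_cov(pcov, i: int) -> float:
    v = pcov[i, i]
    return float(math.sqrt(v)) if np.isfinite(v) and v >= 0 else float("nan")


def knife_edge_fit(scan: KnifeEdgeScan):
    """Fit P(x) = offset + (A/2)(1 + erf(sqrt(2)(x - xc)/w)).

    Returns ``(w, w_se, xc, xc_se)``.  The scan must traverse the full edge:
    the normalized signal has to reach below 10% and above 90% of its range,
    otherwise the width is unconstrained.
    """
    x, P = scan.x, scan.Ptrans
    if x.size < 6:
        raise InsufficientDataError("knife-edge fit needs >= 6 points")
    rng = P.max() - P.min()
    if rng <= 0:
        raise UnconstrainedFitError("flat knife-edge scan")
    norm = (P - P.min()) / rng
    # sort ascending in x for the model; direction only flips the sign of A
    order = np.argsort(x)
    xs, Ps = x[order], P[order]

    def model(x, A, offset, xc, w):
        return offset + 0.5 * A * (1.0 + erf(math.sqrt(2.0) * (x - xc) / w))

    span = xs[-1] - xs[0]
    A0 = Ps[-1] - Ps[0]
    p0 = [A0, Ps[0], xs[xs.size // 2], span / 4.0]
    popt, pcov = curve_fit(model, xs, Ps, p0=p0, maxfev=20000)
    w = abs(float(popt[3]))
    xc = float(popt[2])
    if not (xs[0] <= xc <= xs[-1]) or w > span:
        raise UnconstrainedFitError(
            "knife-edge scan does not span the beam edge"
        )
    # spans-both-asymptotes check after the fit: plateau coverage
    if norm.min() > 0.1 or norm.max() < 0.9:  # pragma: no cover - rng-normalized
        raise UnconstrainedFitError("scan does not reach both asymptotes")
    return w, _se_from_cov(pcov, 3), xc, _se_from_cov(pcov, 2)


def waist_profile_fit(
    w_by_z: Sequence[Tuple[float, float]], lambda_vac: float
):
    """Fit w(z) = w0 sqrt(1 + (lambda (z-z0)/(pi w0^2))^2) to (z, w) pairs.

    Returns ``(w0, w0_se, z0, z0_se)``.  Warns when the fitted waist falls
    outside the instrument's plausible 3.5-5.5 um band or when all points
    lie on one side of the focus (poorly constrained z0).
    """
    pts = np.asarray(w_by_z, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise InsufficientDataError("waist fit needs >= 4 (z, w) pairs")
    z, wv = pts[:, 0], pts[:, 1]

    def model(z, w0, z0):
        return w0 * np.sqrt(1.0 + (lambda_vac * (z - z0) / (math.pi * w0**2)) ** 2)

    p0 = [float(wv.min()), float(z[np.argmin(wv)])]
    popt, pcov = curve_fit(model, z, wv, p0=p0, maxfev=20000)
    w0, z0 = abs(float(popt[0])), float(popt[1])
    if np.all(z > z0) or np.all(z < z0):
        warnings.warn(
            "all scan positions on one side of focus; z0 poorly constrained",
            UserWarning,
            stacklevel=2,
        )
    if not (WAIST_PLAUSIBLE_CM[0] <= w0 <= WAIST_PLAUSIBLE_CM[1]):
        warnings.warn(
            f"fitted waist {w0 * 1e4:.2f} um outside the plausible "
            "3.5-5.5 um band of this instrument",
            PlausibilityWarning,
            stacklevel=2,
        )
    return w0, _se_from_cov(pcov, 0), z0, _se_from_cov(pcov, 1)


def zprofile_shape(z, zc, l, zR):
    """Rect(l) * Lorentzian convolution, normalized to unit peak at l -> inf.

    Integral of 1/(1+((z-z')/zR)^2) over the slab z' in [zc-l/2, zc+l/2],
    divided by (pi zR) so the thick-slab plateau is 1.
    """
    z = np.asarray(z, dtype=float)
    return (
        np.arctan((z - zc + l / 2.0) / zR) - np.arctan((z - zc - l / 2.0) / zR)
    ) / math.pi


def zprofile_fit(profile: ZProfile, lambda_vac: float, n0: float):
    """Fit the axial fluorescence profile for colony thickness and zR.

    Returns a dict with ``l``, ``zR``, ``z_centre``, their standard errors,
    and the derived in-colony waist ``w0 = sqrt(lambda zR / (n0 pi))``.
    """
    z, F = profile.z, profile.F
    if z.size < 8:
        raise InsufficientDataError("z-profile fit needs >= 8 points")
    if np.any(F < -1e-9 * max(F.max(), 1.0)):
        raise InvalidParameterError("fluorescence must be nonnegative")

    def model(z, A, zc, l, zR):
        return A * zprofile_shape(z, zc, l, zR)

    span = z[-1] - z[0]
    p0 = [float(F.max()), float(z[np.argmax(F)]), span / 3.0, span / 10.0]
    popt, pcov = curve_fit(
        model,
        z,
        F,
        p0=p0,
        bounds=([0, z[0] - span, 1e-9, 1e-9], [np.inf, z[-1] + span, 10 * span, span]),
        maxfev=20000,
    )
    A, zc, l, zR = (float(v) for v in popt)
    fwhm_kernel = 2.0 * zR
    if l < fwhm_kernel / 10.0:
        raise InsufficientDataError(
            "colony thinner than the axial resolution; thickness degenerate"
        )
    w0 = math.sqrt(lambda_vac * zR / (n0 * math.pi))
    return {
        "l": l,
        "l_se": _se_from_cov(pcov, 2),
        "zR": zR,
        "zR_se": _se_from_cov(pcov, 3),
        "z_centre": zc,
        "z_centre_se": _se_from_cov(pcov, 1),
        "w0": w0,
    }


def pulse_duration_calibration(
    lambda_nm: np.ndarray,
    F2_ref: np.ndarray,
    sigma2_ref: np.ndarray,
    anchor_lambda_nm: float,
    anchor_dtau_s: float,
):
    """Relative pulse duration dtau(lambda) from a thick reference-dye signal.

    For a cuvette much thicker than the Rayleigh length the two-photon
    signal of the GL field at constant average power obeys

        F2 = C sigma2(lambda) lambda / dtau(lambda) * P^2

    (the zR ~ w0^2/lambda axial extent cancels the waist and trades the two
    hnu factors for lambda^2/lambda).  Inverting, dtau is proportional to
    lambda sigma2 / F2, with the constant fixed so that dtau(anchor) equals
    the known anchor value (e.g. the transform-limited 109 fs at 1100 nm).
    """
    lam = np.asarray(lambda_nm, dtype=float)
    F2 = np.asarray(F2_ref, dtype=float)
    s2 = np.asarray(sigma2_ref, dtype=float)
    if lam.shape != F2.shape or lam.shape != s2.shape:
        raise InvalidParameterError("wavelength grids must match")
    if np.any(F2 <= 0) or np.any(s2 <= 0):
        raise InvalidParameterError("reference signal and sigma2 must be positive")
    shape = lam * s2 / F2
    anchor_shape = np.interp(anchor_lambda_nm, lam, shape)
    if not (lam.min() <= anchor_lambda_nm <= lam.max()):
        raise InvalidParameterError("anchor wavelength outside the scanned range")
    return shape / anchor_shape * anchor_dtau_s


def corrected_2pe_spectrum(
    lambda_sample: np.ndarray,
    F2_sample: np.ndarray,
    lambda_ref: np.ndarray,
    F2_ref: np.ndarray,
    f2pe_ref: np.ndarray,
):
    """Relative corrected 2PE spectrum of a sample by the reference method:

        f_sample(lambda) = F2_sample / F2_ref * f_ref(lambda),

    with sample and reference measured under identical excitation.  The
    reference curves are interpolated onto the sample grid (with a warning);
    extrapolation beyond the reference grid is refused.
    """
    lam_s = np.asarray(lambda_sample, dtype=float)
    F2s = np.asarray(F2_sample, dtype=float)
    lam_r = np.asarray(lambda_ref, dtype=float)
    F2r = np.asarray(F2_ref, dtype=float)
    fr = np.asarray(f2pe_ref, dtype=float)
    if lam_r.shape != F2r.shape or lam_r.shape != fr.shape:
        raise InvalidParameterError("reference arrays must match in length")
    if lam_s.min() < lam_r.min() or lam_s.max() > lam_r.max():
        raise ValidationError(
            "sample wavelengths extend beyond the reference grid; "
            "extrapolation refused"
        )
    if not np.array_equal(lam_s, lam_r):
        warnings.warn(
            "wavelength grids differ; interpolating the reference",
            UserWarning,
            stacklevel=2,
        )
    F2r_i = np.interp(lam_s, lam_r, F2r)
    fr_i = np.interp(lam_s, lam_r, fr)
    if np.any(F2r_i <= 0):
        raise InvalidParameterError("reference signal must be positive")
    return F2s / F2r_i * fr_i
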