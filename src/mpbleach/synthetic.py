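"""Synthetic data generation from the forward bleaching model.

Everything the analysis pipeline consumes can be generated here: decay
traces, K(P) power series, knife-edge scans, axial fluorescence profiles and
reference spectra signals -- all from the same Gaussian-Lorentzian field and
level-scheme kinetics that the closed-form rate laws describe, with seeded
noise.

Decay traces are built without shortcuts: the local per-pulse bleaching
probability of the level scheme gives a local rate k(r, z) = f * p(I(r, z));
every volume element then decays exponentially at its own rate, and the
detected signal is the I^2-weighted volume integral

    F(t) = Integral I^2(r,z) exp(-k(r,z) t) dV  /  Integral I^2 dV,

which is non-monoexponential (slower than exp(-K t) at long times) exactly
as spatially averaged bleaching kinetics are in a real focal volume.

Default noise is multiplicative lognormal with 10% relative magnitude on
each sample (detector statistics of the instrument are not characterized;
this is the package's own choice, documented in the methods note); a
Poisson photon-count mode is available for realism studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import erf

from .beam_optics import (
    BeamGeometry,
    LaserConfig,
    LevelScheme,
    MonomialScheme,
    peak_flux_from_power,
    per_pulse_bleach_probability,
)
from .calibration import KnifeEdgeScan, ZProfile, zprofile_shape
from .exceptions import InvalidParameterError
from .inference import PowerSeries, SeriesContext
from .kinetics import DecayTrace
from .rate_models import K2, K3, K4, MolecularPhotophysics

__all__ = [
    "NoiseModel",
    "PhenomenologicalScheme",
    "SimulationSpec",
    "simulate_decay",
    "simulate_power_series",
    "simulate_scans",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise: 'lognormal' (multiplicative, sigma_rel) or
    'poisson' (counts, scaled so the initial signal is ``counts_at_start``)."""

    kind: str = "lognormal"
    sigma_rel: float = 0.1
    counts_at_start: float = 1e4

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "poisson", "none"):
            raise InvalidParameterError(
                "noise kind must be 'lognormal', 'poisson' or 'none'"
            )
        if self.sigma_rel < 0 or self.counts_at_start <= 0:
            raise InvalidParameterError("invalid noise magnitude")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or (
            self.kind == "lognormal" and self.sigma_rel == 0
        ):
            return values
        if self.kind == "lognormal":
            return values * np.exp(self.sigma_rel * rng.standard_normal(values.shape))
        counts = rng.poisson(np.clip(values, 0, None) * self.counts_at_start)
        return counts / self.counts_at_start


@dataclass(frozen=True)
class PhenomenologicalScheme:
    """Pure power law K = k_ref (P/P_ref)^n for regimes without a mechanistic
    rate equation (e.g. the alpha ~ 8 high-order ionization ladder)."""

    n: float
    k_ref: float
    P_ref: float

    def __post_init__(self) -> None:
        if not (2.0 <= self.n <= 10.0):
            raise InvalidParameterError("phenomenological exponent must be in [2, 10]")
        if self.k_ref < 0 or self.P_ref <= 0:
            raise InvalidParameterError("k_ref must be >= 0 and P_ref > 0")


SchemeSpec = Union[
    LevelScheme, MonomialScheme, PhenomenologicalScheme, Sequence[LevelScheme]
]


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one simulated experiment."""

    molecule: MolecularPhotophysics
    laser: LaserConfig
    geometry: BeamGeometry
    scheme: SchemeSpec
    seed: int
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_z: int = 129
    n_v: int = 64

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def context(self) -> SeriesContext:
        return SeriesContext(
            laser=self.laser,
            geometry=self.geometry,
            sigma2_gm=self.molecule.sigma2_gm,
        )


def _scheme_list(scheme: SchemeSpec):
    if isinstance(scheme, (LevelScheme, MonomialScheme, PhenomenologicalScheme)):
        return [scheme]
    return list(scheme)


def _local_rates(spec: SimulationSpec, P: float):
    """Local bleaching rate k(z, v) and I^2 detection weights on the
    quadrature grid (v is the substituted radial variable)."""
    geometry, laser = spec.geometry, spec.laser
    I0 = float(peak_flux_from_power(laser, geometry, P))
    xz, wz = leggauss(spec.n_z)
    z = 0.5 * geometry.l * xz
    wz = 0.5 * geometry.l * wz
    xv, wv = leggauss(spec.n_v)
    v = 0.5 * (xv + 1.0)
    wv = 0.5 * wv

    w2 = geometry.w2(z)
    Imax = I0 * geometry.w0**2 / w2
    I_local = Imax[:, None] * v[None, :]

    k = np.zeros_like(I_local)
    for sch in _scheme_list(spec.scheme):
        if isinstance(sch, PhenomenologicalScheme):
            raise InvalidParameterError(
                "phenomenological schemes define K(P) directly and have no "
                "local rate; use simulate_power_series"
            )
        k += laser.f * per_pulse_bleach_probability(
            I_local, sch, spec.molecule, laser.dtau
        )
    # detection weight of each node: wz * (pi w^2/2) * Imax^2 * wv * v
    weight = (wz * (math.pi * w2 / 2.0) * Imax**2)[:, None] * (wv * v)[None, :]
    return k, weight


def simulate_decay(
    spec: SimulationSpec,
    t: Optional[np.ndarray] = None,
    duration_s: float = 10.0,
    n_samples: int = 250,
    P: Optional[float] = None,
) -> DecayTrace:
    """Simulate a fluorescence decay trace F(t), normalized to F(0) = 1
    before noise.

    ``t`` may be given explicitly; otherwise ``n_samples`` uniform samples
    over ``duration_s`` (the instrument's typical 10 s dwell with 100-sample
    binning of its 2.5 kHz stream).
    """
    if t is None:
        t = np.linspace(0.0, duration_s, n_samples)
    t = np.asarray(t, dtype=float)
    P = spec.laser.P if P is None else P
    k, weight = _local_rates(spec, P)
    wsum = weight.sum()
    F = np.array(
        [np.sum(weight * np.exp(-k * ti)) / wsum for ti in t]
    )
    F = spec.noise.apply(F, spec.rng())
    return DecayTrace(
        t=t,
        F=F,
        meta={"P_w": P, "lambda_nm": spec.laser.lambda_nm, "bin": 1},
    )


def analytic_rate(spec: SimulationSpec, P) -> np.ndarray:
    """Noise-free K(P) from the closed-form laws of the scheme(s)."""
    P = np.asarray(P, dtype=float)
    K = np.zeros_like(P)
    for sch in _scheme_list(spec.scheme):
        if isinstance(sch, PhenomenologicalScheme):
            K = K + sch.k_ref * (P / sch.P_ref) ** sch.n
        elif isinstance(sch, MonomialScheme):
            raise InvalidParameterError(
                "monomial schemes are a brute-force probe; no closed form"
            )
        elif sch.order == 2:
            K = K + K2(P, spec.molecule, spec.laser, spec.geometry)
        elif sch.order == 3:
            K = K + K3(
                P, spec.molecule, spec.laser, spec.geometry, saturated=sch.saturated
            )
        else:
            K = K + K4(
                P, spec.molecule, spec.laser, spec.geometry, saturated=sch.saturated
            )
    return K


def simulate_power_series(
    spec: SimulationSpec,
    powers: np.ndarray,
    path: str = "analytic",
    n_replicates: int = 1,
    drop_fraction: float = 0.1,
) -> PowerSeries | list:
    """Simulate a K(P) series.

    ``path='analytic'`` evaluates the closed-form rate laws and applies
    noise; ``path='end-to-end'`` simulates a decay trace at each power and
    extracts K with the initial-rate method (slow but exercises the whole
    chain).  With ``n_replicates > 1`` a list of independent series (one RNG
    stream, so replicates differ) is returned.
    """
    powers = np.asarray(powers, dtype=float)
    if np.any(powers <= 0):
        raise InvalidParameterError("powers must be positive")
    rng = spec.rng()
    out = []
    for _ in range(n_replicates):
        if path == "analytic":
            K_true = analytic_rate(spec, powers)
            K = spec.noise.apply(K_true, rng)
            K_se = (
                spec.noise.sigma_rel * K
                if spec.noise.kind == "lognormal"
                else None
            )
        elif path == "end-to-end":
            from .kinetics import initial_rate, normalize_trace

            K = np.empty_like(powers)
            K_se = np.empty_like(powers)
            for i, P in enumerate(powers):
                # sub-seed per trace so traces are independent but reproducible
                sub = SimulationSpec(
                    molecule=spec.molecule,
                    laser=spec.laser,
                    geometry=spec.geometry,
                    scheme=spec.scheme,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    noise=spec.noise,
                    n_z=spec.n_z,
                    n_v=spec.n_v,
                )
                Ktrue_i = float(analytic_rate(spec, P))
                duration = min(10.0, 0.5 / max(Ktrue_i, 1e-2))
                trace = simulate_decay(sub, duration_s=duration, P=float(P))
                meas = initial_rate(
                    normalize_trace(trace), drop_fraction=drop_fraction
                )
                K[i], K_se[i] = meas.K, meas.K_se
        else:
            raise InvalidParameterError("path must be 'analytic' or 'end-to-end'")
        out.append(
            PowerSeries(
                P=powers,
                K=K,
                K_se=K_se,
                lambda_nm=spec.laser.lambda_nm,
                context=spec.context(),
            )
        )
    return out[0] if n_replicates == 1 else out


def simulate_scans(
    spec: SimulationSpec,
    z_positions_cm: Sequence[float] = (-0.02, -0.01, 0.0, 0.01, 0.02),
    n_x: int = 61,
    n_zprofile: int = 121,
    noise_rel: float = 0.0,
):
    """Simulate knife-edge scans at several z and a colony z-profile.

    Knife-edge: transmitted power follows the cumulative Gaussian with the
    local beam radius w(z).  Z-profile: rect(l) * Lorentzian(zR) convolution
    of the GL per-slice two-photon signal.  Gaussian relative noise
    ``noise_rel`` is applied from the spec's seed.
    """
    geometry = spec.geometry
    rng = spec.rng()
    P_total = max(spec.laser.P, 1e-3)
    scans = []
    for zpos in z_positions_cm:
        wz = float(geometry.w(zpos))
        x = np.linspace(-3.0 * wz, 3.0 * wz, n_x)
        P = P_total * 0.5 * (1.0 + erf(math.sqrt(2.0) * x / wz))
        if noise_rel > 0:
            P = P + noise_rel * P_total * rng.standard_normal(P.shape)
        scans.append(KnifeEdgeScan(x=x, Ptrans=P, z=float(zpos)))

    half_span = geometry.l / 2.0 + 5.0 * geometry.zR
    z = np.linspace(-half_span, half_span, n_zprofile)
    F = zprofile_shape(z, 0.0, geometry.l, geometry.zR)
    if noise_rel > 0:
        F = F * (1.0 + noise_rel * rng.standard_normal(F.shape))
    profile = ZProfile(z=z, F=F, stitched=True)
    return scans, profile
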