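"""Inference of molecular photophysics from K(P) power series.

Workflow mirroring the experimental analysis of bleaching-rate power
dependences:

1. ``power_exponent``      -- global log-log exponent alpha of K ~ P^alpha.
2. ``detect_threshold``    -- two-term fit K = a2 P^2 + a4 P^4; the threshold
   P* = sqrt(a2/a4) marks the switch from quadratic to super-quadratic
   bleaching (absent when a4 is consistent with zero).
3. Segment fits: ``fit_quadratic_segment`` (K vs P^2, slope a2 -> phi1 or
   phim), ``fit_quartic_excess`` (K - a2 P^2 vs P^4, slope a4 ->
   sigma_mn*sigma_nc), ``fit_cubic`` (K vs P^3, slope a3 -> sigma_mn*phin).
4. Saturated-branch fits (``fit_saturated_3photon``, ``fit_saturated_4photon``)
   that exploit the curvature of the slight/strong saturation laws to split
   products into individual cross sections / yields.
5. ``infer_pipeline``      -- regime diagnosis and orchestration.

All K-vs-P^n fits go through the origin (no bleaching at zero power).
Uncertainties of the nonlinear saturated fits are nonparametric bootstrap
over points (seeded); linear-fit uncertainties come from the weighted
least-squares covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .beam_optics import BeamGeometry, LaserConfig
from .exceptions import (
    ContaminationWarning,
    DomainWarning,
    InsufficientDataError,
    InvalidParameterError,
    NonIdentifiableError,
    RegimeMismatchError,
)
from .rate_models import (
    K3,
    K4,
    MolecularPhotophysics,
    phi_from_a2,
    product_mn_nc_from_a4,
    saturation_power,
    sigma_mn_phi_n_from_a3,
)

__all__ = [
    "SeriesContext",
    "PowerSeries",
    "ParameterEstimate",
    "InferenceResult",
    "power_exponent",
    "fit_quadratic_segment",
    "detect_threshold",
    "fit_quartic_excess",
    "fit_cubic",
    "fit_saturated_3photon",
    "fit_saturated_4photon",
    "infer_pipeline",
]


@dataclass(frozen=True)
class SeriesContext:
    """Laser, geometry and the 2PA cross section at the series wavelength."""

    laser: LaserConfig
    geometry: BeamGeometry
    sigma2_gm: float


@dataclass(frozen=True)
class PowerSeries:
    """Bleaching rates K (s^-1) measured at average powers P (W)."""

    P: np.ndarray
    K: np.ndarray
    K_se: Optional[np.ndarray] = None
    lambda_nm: Optional[float] = None
    context: Optional[SeriesContext] = None

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        K = np.asarray(self.K, dtype=float)
        if P.ndim != 1 or P.shape != K.shape:
            raise InvalidParameterError("P and K must be 1-D arrays of equal length")
        if np.any(P <= 0):
            raise InvalidParameterError("powers must be strictly positive")
        se = self.K_se
        if se is not None:
            se = np.asarray(se, dtype=float)
            if se.shape != P.shape:
                raise InvalidParameterError("K_se must match P in length")
        order = np.argsort(P, kind="stable")
        object.__setattr__(self, "P", P[order])
        object.__setattr__(self, "K", K[order])
        object.__setattr__(self, "K_se", None if se is None else se[order])

    def __len__(self) -> int:
        return int(self.P.size)

    def weights(self) -> np.ndarray:
        if self.K_se is None:
            return np.ones_like(self.K)
        se = np.clip(self.K_se, 1e-300, None)
        return 1.0 / se**2

    def subset(self, mask: np.ndarray) -> "PowerSeries":
        return PowerSeries(
            P=self.P[mask],
            K=self.K[mask],
            K_se=None if self.K_se is None else self.K_se[mask],
            lambda_nm=self.lambda_nm,
            context=self.context,
        )


@dataclass(frozen=True)
class ParameterEstimate:
    """A fitted quantity with its standard error and provenance tag."""

    value: float
    se: float
    model_tag: str
    ci95: Optional[tuple] = None


@dataclass
class InferenceResult:
    """Structured output of the inference pipeline."""

    alpha: Optional[ParameterEstimate] = None
    a2: Optional[ParameterEstimate] = None
    a3: Optional[ParameterEstimate] = None
    a4: Optional[ParameterEstimate] = None
    Pstar: Optional[ParameterEstimate] = None
    phi: Optional[ParameterEstimate] = None
    sigma_mn_phi_n: Optional[ParameterEstimate] = None
    product_mn_nc: Optional[ParameterEstimate] = None
    sigma_mn: Optional[ParameterEstimate] = None
    sigma_nc: Optional[ParameterEstimate] = None
    phin: Optional[ParameterEstimate] = None
    diagnostics: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"diagnostics": list(self.diagnostics)}
        for name in (
            "alpha",
            "a2",
            "a3",
            "a4",
            "Pstar",
            "phi",
            "sigma_mn_phi_n",
            "product_mn_nc",
            "sigma_mn",
            "sigma_nc",
            "phin",
        ):
            est = getattr(self, name)
            if est is not None:
                out[name] = {
                    "value": est.value,
                    "se": est.se,
                    "model_tag": est.model_tag,
                }
        return out


# ---------------------------------------------------------------------------
# linear building blocks
# ---------------------------------------------------------------------------


def _origin_fit(x, y, w):
    """Weighted least-squares slope of y = b x through the origin."""
    Sxx = np.sum(w * x * x)
    if Sxx <= 0:
        raise InsufficientDataError("degenerate design in origin fit")
    b = np.sum(w * x * y) / Sxx
    resid = y - b * x
    dof = max(x.size - 1, 1)
    se = math.sqrt(max(np.sum(w * resid**2) / dof, 0.0) / Sxx)
    return float(b), float(se)


def power_exponent(series: PowerSeries) -> ParameterEstimate:
    """Global exponent alpha of K ~ P^alpha from a weighted log-log fit."""
    usable = series.K > 0
    if np.any(~usable):
        warnings.warn(
            f"{int(np.sum(~usable))} nonpositive K value(s) excluded from the "
            "log-log exponent fit",
            UserWarning,
            stacklevel=2,
        )
    if int(np.sum(usable)) < 3:
        raise InsufficientDataError("power exponent needs >= 3 positive rates")
    P, K = series.P[usable], series.K[usable]
    if series.K_se is not None:
        w = (K / np.clip(series.K_se[usable], 1e-300, None)) ** 2
    else:
        w = np.ones_like(K)
    x, y = np.log(P), np.log(K)
    W = np.sum(w)
    xbar, ybar = np.sum(w * x) / W, np.sum(w * y) / W
    Sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / Sxx
    resid = y - (ybar + slope * (x - xbar))
    dof = max(x.size - 2, 1)
    se = math.sqrt(max(np.sum(w * resid**2) / dof, 0.0) / Sxx)
    return ParameterEstimate(float(slope), se, "loglog-exponent")


def fit_quadratic_segment(
    series: PowerSeries, p_max: Optional[float] = None
) -> InferenceResult:
    """Zero-intercept fit of K vs P^2 over the low-power segment.

    ``p_max`` restricts the segment (typically to powers below the detected
    threshold).  The slope a2 is inverted for the reaction quantum yield
    when the series carries a context.  A segment whose own log-log exponent
    is clearly super-quadratic triggers a contamination warning.
    """
    mask = np.ones(len(series), dtype=bool) if p_max is None else series.P <= p_max
    sub = series.subset(mask)
    if len(sub) < 3:
        raise InsufficientDataError("quadratic segment needs >= 3 points")
    try:
        alpha = power_exponent(sub)
        if alpha.value > 2.25 and (alpha.value - 2.0) > 3.0 * alpha.se:
            warnings.warn(
                f"quadratic segment looks super-quadratic "
                f"(alpha = {alpha.value:.2f} +/- {alpha.se:.2f})",
                ContaminationWarning,
                stacklevel=2,
            )
    except InsufficientDataError:
        pass
    a2, a2_se = _origin_fit(sub.P**2, sub.K, sub.weights())
    result = InferenceResult(
        a2=ParameterEstimate(a2, a2_se, "quadratic:K-vs-P2")
    )
    if series.context is not None:
        ctx = series.context
        phi = phi_from_a2(a2, ctx.sigma2_gm, ctx.laser, ctx.geometry)
        phi_se = phi * (a2_se / a2) if a2 > 0 else float("inf")
        result.phi = ParameterEstimate(phi, phi_se, "quadratic:K-vs-P2")
    return result


def detect_threshold(
    series: PowerSeries, cond_limit: float = 1e12
) -> Optional[InferenceResult]:
    """Two-term fit K = a2 P^2 + a4 P^4; threshold P* = sqrt(a2/a4).

    Returns ``None`` when the quartic coefficient is consistent with zero
    (95% CI includes 0) -- no quadratic-to-quartic transition in the probed
    power range -- or when the design is numerically non-identifiable.
    """
    if len(series) < 6:
        raise InsufficientDataError("threshold detection needs >= 6 points")
    if series.P.max() / series.P.min() < 10.0:
        raise InsufficientDataError(
            "threshold detection needs >= one decade of power"
        )
    w = series.weights()
    A = np.column_stack([series.P**2, series.P**4])
    Aw = A * np.sqrt(w)[:, None]
    yw = series.K * np.sqrt(w)
    if np.linalg.cond(Aw) > cond_limit:
        warnings.warn(
            "threshold fit non-identifiable (ill-conditioned design)",
            UserWarning,
            stacklevel=2,
        )
        return None
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    a2, a4 = float(coef[0]), float(coef[1])
    resid = yw - Aw @ coef
    dof = max(len(series) - 2, 1)
    s2 = float(np.sum(resid**2) / dof)
    cov = np.linalg.inv(Aw.T @ Aw) * s2
    a2_se, a4_se = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    if a4 <= 0 or a4 < 1.96 * a4_se:
        return None
    if a2 <= 0:
        return None
    Pstar = math.sqrt(a2 / a4)
    var = (Pstar**2 / 4.0) * (
        cov[0, 0] / a2**2 + cov[1, 1] / a4**2 - 2.0 * cov[0, 1] / (a2 * a4)
    )
    return InferenceResult(
        a2=ParameterEstimate(a2, a2_se, "two-term:K2+K4"),
        a4=ParameterEstimate(a4, a4_se, "two-term:K2+K4"),
        Pstar=ParameterEstimate(Pstar, math.sqrt(max(var, 0.0)), "two-term:K2+K4"),
    )


def fit_quartic_excess(
    series: PowerSeries, a2: float, p_min: Optional[float] = None
) -> InferenceResult:
    """Zero-intercept fit of the quartic excess K - a2 P^2 vs P^4.

    ``p_min`` restricts to powers above the threshold.  The slope a4 is
    inverted for sigma_mn*sigma_nc when a context is available.
    """
    mask = np.ones(len(series), dtype=bool) if p_min is None else series.P >= p_min
    sub = series.subset(mask)
    if len(sub) < 3:
        raise InsufficientDataError("quartic-excess fit needs >= 3 points")
    excess = sub.K - a2 * sub.P**2
    if np.sum(excess) <= 0 or np.mean(excess > 0) < 0.5:
        raise RegimeMismatchError(
            "quartic excess dominated by negative values; the segment is not "
            "in the super-quadratic regime"
        )
    a4, a4_se = _origin_fit(sub.P**4, excess, sub.weights())
    result = InferenceResult(a4=ParameterEstimate(a4, a4_se, "quartic-excess"))
    if series.context is not None:
        ctx = series.context
        prod = product_mn_nc_from_a4(a4, ctx.sigma2_gm, ctx.laser, ctx.geometry)
        prod_se = prod * (a4_se / a4) if a4 > 0 else float("inf")
        result.product_mn_nc = ParameterEstimate(prod, prod_se, "quartic-excess")
    return result


def fit_cubic(series: PowerSeries) -> InferenceResult:
    """Zero-intercept fit of K vs P^3; slope a3 -> sigma_mn * phin."""
    if len(series) < 3:
        raise InsufficientDataError("cubic fit needs >= 3 points")
    a3, a3_se = _origin_fit(series.P**3, series.K, series.weights())
    result = InferenceResult(a3=ParameterEstimate(a3, a3_se, "cubic:K-vs-P3"))
    if series.context is not None:
        ctx = series.context
        smp = sigma_mn_phi_n_from_a3(a3, ctx.sigma2_gm, ctx.laser, ctx.geometry)
        smp_se = smp * (a3_se / a3) if a3 > 0 else float("inf")
        result.sigma_mn_phi_n = ParameterEstimate(smp, smp_se, "cubic:K-vs-P3")
    return result


# ---------------------------------------------------------------------------
# saturated-branch fits (profile over sigma_mn; the second parameter enters
# linearly and is concentrated out analytically)
# ---------------------------------------------------------------------------

_SIGMA_MN_BOUNDS = (1e-18, 1e-15)  # cm^2, physically plausible 1PA range


def _profile_fit(series, unit_model, bounds=_SIGMA_MN_BOUNDS, n_grid=41):
    """Minimize over sigma_mn the weighted SSR of K = c * unit_model(sigma_mn).

    ``unit_model(sigma_mn)`` returns the model rates with the linear
    parameter set to 1; the linear parameter c is concentrated out exactly.
    Returns (sigma_mn, c, cost_grid) with a parabolic/bounded refinement.
    """
    w = series.weights()
    K = series.K

    def cost_and_c(sigma_mn):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DomainWarning)
            M = unit_model(sigma_mn)
        SMM = np.sum(w * M * M)
        if SMM <= 0 or not np.all(np.isfinite(M)):
            return np.inf, 0.0
        c = max(np.sum(w * M * K) / SMM, 0.0)
        return float(np.sum(w * (K - c * M) ** 2)), float(c)

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.logspace(lo, hi, n_grid)
    costs = np.array([cost_and_c(s)[0] for s in grid])
    i = int(np.argmin(costs))
    b_lo = grid[max(i - 1, 0)]
    b_hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda ls: cost_and_c(10.0**ls)[0],
        bounds=(math.log10(b_lo), math.log10(b_hi)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    sigma_mn = float(10.0**res.x)
    cost, c = cost_and_c(sigma_mn)
    return sigma_mn, c, grid, costs, cost


def _check_identifiable(series, unit_model, sigma_mn, best_cost, grid, costs):
    """Flat-profile and no-saturation-information guards."""
    finite = np.isfinite(costs)
    if not np.any(finite):
        raise NonIdentifiableError("saturated fit: model invalid on the grid")
    spread = (np.nanmax(costs[finite]) - best_cost) / max(best_cost, 1e-300)
    if spread < 1e-3:
        raise NonIdentifiableError(
            "flat likelihood in sigma_mn: the data carry no saturation "
            "information"
        )
    ctx = series.context
    mol = MolecularPhotophysics(sigma2_gm=ctx.sigma2_gm, sigma_mn=sigma_mn)
    x_max = series.P.max() / saturation_power(mol, ctx.laser, ctx.geometry)
    if x_max < 0.02:
        raise NonIdentifiableError(
            f"P/Ps <= {x_max:.3g} everywhere: data are unsaturated, sigma_mn "
            "not identifiable"
        )


def _bootstrap_profile(series, make_unit_model, sigma_mn0, rng, n_boot):
    """Nonparametric bootstrap over points of the profile fit."""
    sm, cs = [], []
    n = len(series)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        idx = np.unique(idx)
        if idx.size < 4:
            continue
        sub = series.subset(np.isin(np.arange(n), idx))
        try:
            s, c, *_ = _profile_fit(sub, make_unit_model(sub), n_grid=21)
        except (InsufficientDataError, NonIdentifiableError):
            continue
        sm.append(s)
        cs.append(c)
    return np.asarray(sm), np.asarray(cs)


def fit_saturated_3photon(
    series: PowerSeries, seed: int = 0, n_boot: int = 1000
) -> InferenceResult:
    """Fit the slightly saturated 2+1 law for sigma_mn and phin separately.

    Requires a context (the saturation power couples sigma_mn to the laser
    and geometry).  The reaction yield phin enters linearly and is profiled
    out; sigma_mn is scanned over the plausible 1PA range with a bounded
    refinement.  Uncertainties by seeded nonparametric bootstrap.
    """
    if series.context is None:
        raise InvalidParameterError("saturated fits require a series context")
    if len(series) < 5:
        raise InsufficientDataError("saturated 2+1 fit needs >= 5 points")
    ctx = series.context

    def make_unit_model(sub):
        def unit_model(sigma_mn):
            mol = MolecularPhotophysics(
                sigma2_gm=ctx.sigma2_gm, sigma_mn=sigma_mn, phin=1.0
            )
            return np.asarray(
                K3(sub.P, mol, ctx.laser, ctx.geometry, saturated=True)
            )

        return unit_model

    unit = make_unit_model(series)
    sigma_mn, phin, grid, costs, best = _profile_fit(series, unit)
    _check_identifiable(series, unit, sigma_mn, best, grid, costs)

    rng = np.random.default_rng(seed)
    sm, cs = _bootstrap_profile(series, make_unit_model, sigma_mn, rng, n_boot)
    sm_se = float(np.std(sm)) if sm.size else float("nan")
    ph_se = float(np.std(cs)) if cs.size else float("nan")
    ci = lambda a: (
        tuple(np.percentile(a, [2.5, 97.5])) if a.size else None
    )
    tag = "saturated-3photon"
    return InferenceResult(
        sigma_mn=ParameterEstimate(sigma_mn, sm_se, tag, ci95=ci(sm)),
        phin=ParameterEstimate(phin, ph_se, tag, ci95=ci(cs)),
        sigma_mn_phi_n=ParameterEstimate(
            sigma_mn * phin,
            sigma_mn * phin * math.hypot(
                sm_se / sigma_mn if sigma_mn else 0.0,
                ph_se / phin if phin else 0.0,
            ),
            tag,
        ),
    )


def fit_saturated_4photon(
    series: PowerSeries, seed: int = 0, n_boot: int = 1000
) -> InferenceResult:
    """Fit the strongly saturated 2+1+1 law for sigma_mn and sigma_nc.

    The ionization cross section enters linearly and is profiled out.  The
    product sigma_mn*sigma_nc is reported for cross-validation against the
    quartic-excess route.
    """
    if series.context is None:
        raise InvalidParameterError("saturated fits require a series context")
    if len(series) < 5:
        raise InsufficientDataError("saturated 2+1+1 fit needs >= 5 points")
    ctx = series.context

    def make_unit_model(sub):
        def unit_model(sigma_mn):
            mol = MolecularPhotophysics(
                sigma2_gm=ctx.sigma2_gm, sigma_mn=sigma_mn, sigma_nc=1.0
            )
            return np.asarray(
                K4(sub.P, mol, ctx.laser, ctx.geometry, saturated=True)
            )

        return unit_model

    unit = make_unit_model(series)
    sigma_mn, sigma_nc, grid, costs, best = _profile_fit(series, unit)
    _check_identifiable(series, unit, sigma_mn, best, grid, costs)

    rng = np.random.default_rng(seed)
    sm, cs = _bootstrap_profile(series, make_unit_model, sigma_mn, rng, n_boot)
    sm_se = float(np.std(sm)) if sm.size else float("nan")
    nc_se = float(np.std(cs)) if cs.size else float("nan")
    prods = sm * cs if sm.size else np.array([])
    prod = sigma_mn * sigma_nc
    prod_se = float(np.std(prods)) if prods.size else float("nan")
    ci = lambda a: (
        tuple(np.percentile(a, [2.5, 97.5])) if a.size else None
    )
    tag = "saturated-4photon"
    return InferenceResult(
        sigma_mn=ParameterEstimate(sigma_mn, sm_se, tag, ci95=ci(sm)),
        sigma_nc=ParameterEstimate(sigma_nc, nc_se, tag, ci95=ci(cs)),
        product_mn_nc=ParameterEstimate(prod, prod_se, tag, ci95=ci(prods)),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def infer_pipeline(
    series: PowerSeries,
    seed: int = 0,
    n_boot: int = 1000,
    integer_tol: float = 0.2,
) -> InferenceResult:
    """Regime diagnosis and staged fitting of a power series.

    Exponent scan -> threshold detection -> segment fits appropriate to the
    diagnosed regime.  Exponents within ``integer_tol`` of 2, 3 or 4 select
    the unsaturated branch of that order; intermediate exponents trigger the
    saturated-branch fits; exponents above ~4.5 (e.g. the alpha ~ 8 regime)
    are reported without mechanistic parameter extraction, since no rate law
    of order 2-4 applies there.
    """
    result = InferenceResult()
    result.alpha = power_exponent(series)
    alpha = result.alpha.value

    if alpha > 4.5:
        result.diagnostics.append(
            f"power exponent alpha = {alpha:.2f} exceeds the mechanistic "
            "range of the order 2-4 rate laws; reporting the exponent only"
        )
        return result

    thr = None
    try:
        thr = detect_threshold(series)
    except InsufficientDataError as exc:
        result.diagnostics.append(f"threshold detection skipped: {exc}")

    if thr is not None:
        result.Pstar = thr.Pstar
        quad = fit_quadratic_segment(series, p_max=thr.Pstar.value)
        result.a2, result.phi = quad.a2, quad.phi
        try:
            quart = fit_quartic_excess(
                series, a2=quad.a2.value, p_min=thr.Pstar.value
            )
            result.a4 = quart.a4
            result.product_mn_nc = quart.product_mn_nc
        except (InsufficientDataError, RegimeMismatchError) as exc:
            result.diagnostics.append(f"quartic-excess fit skipped: {exc}")
        if series.context is not None and 3.0 + integer_tol < alpha <= 4.5:
            try:
                sat = fit_saturated_4photon(series, seed=seed, n_boot=n_boot)
                result.sigma_mn, result.sigma_nc = sat.sigma_mn, sat.sigma_nc
                if result.product_mn_nc is None:
                    result.product_mn_nc = sat.product_mn_nc
            except (NonIdentifiableError, InsufficientDataError) as exc:
                result.diagnostics.append(f"saturated 2+1+1 fit skipped: {exc}")
        return result

    result.diagnostics.append("no threshold detected")
    if abs(alpha - 2.0) <= integer_tol:
        quad = fit_quadratic_segment(series)
        result.a2, result.phi = quad.a2, quad.phi
    elif abs(alpha - 3.0) <= integer_tol:
        cub = fit_cubic(series)
        result.a3 = cub.a3
        result.sigma_mn_phi_n = cub.sigma_mn_phi_n
    elif 2.0 + integer_tol < alpha < 3.0 - integer_tol and series.context is not None:
        try:
            sat = fit_saturated_3photon(series, seed=seed, n_boot=n_boot)
            result.sigma_mn, result.phin = sat.sigma_mn, sat.phin
            result.sigma_mn_phi_n = sat.sigma_mn_phi_n
        except (NonIdentifiableError, InsufficientDataError) as exc:
            result.diagnostics.append(f"saturated 2+1 fit skipped: {exc}")
            cub = fit_cubic(series)
            result.a3 = cub.a3
            result.sigma_mn_phi_n = cub.sigma_mn_phi_n
    elif 3.0 + integer_tol < alpha <= 4.5 and series.context is not None:
        try:
            sat = fit_saturated_4photon(series, seed=seed, n_boot=n_boot)
            result.sigma_mn, result.sigma_nc = sat.sigma_mn, sat.sigma_nc
            result.product_mn_nc = sat.product_mn_nc
        except (NonIdentifiableError, InsufficientDataError) as exc:
            result.diagnostics.append(f"saturated 2+1+1 fit skipped: {exc}")
    else:
        result.diagnostics.append(
            f"alpha = {alpha:.2f} between integer regimes and no context for "
            "saturated fits; only the exponent is reported"
        )
    return result
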