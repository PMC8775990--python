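"""File formats, reference tables, and structured reports.

CSV dialects use explicit unit-suffixed headers (``P_mW``, ``K_per_s``,
``time_s`` ...) because the domain mixes mW, W, GM and cm^2 and silent unit
mistakes are the dominant failure mode.  Reports are JSON with units
embedded per field, a schema version, and the hash of the resolved
configuration for reproducibility.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .beam_optics import BeamGeometry, LaserConfig
from .exceptions import ValidationError
from .inference import InferenceResult, PowerSeries, SeriesContext
from .kinetics import DecayTrace
from .rate_models import MolecularPhotophysics

__all__ = [
    "SCHEMA_VERSION",
    "config_hash",
    "read_power_series",
    "write_power_series",
    "read_decay_trace",
    "write_decay_trace",
    "load_context",
    "write_report",
    "load_photophysics",
    "load_threshold_table",
    "load_reference_dye_2pa",
    "get_protein_params",
]

SCHEMA_VERSION = "1"

_PACKAGE_VERSION = "0.1.0"


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("mpbleach.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_photophysics() -> pd.DataFrame:
    """Per-(protein, wavelength) photobleaching parameter table."""
    return _read_packaged_csv("photophysics.csv")


def load_threshold_table() -> pd.DataFrame:
    """mCherry threshold operating points (predicted and observed)."""
    return _read_packaged_csv("threshold_table.csv")


def load_reference_dye_2pa() -> pd.DataFrame:
    """Synthetic stand-in reference-dye 2PA spectrum (see file header)."""
    return _read_packaged_csv("reference_dye_2pa_synthetic.csv")


def get_protein_params(protein: str, lambda_nm: float) -> MolecularPhotophysics:
    """Molecular parameters for one protein at one wavelength from the
    packaged table.

    The tabulated cross-section product (quartic-regime fit) and the
    individual sigma_mn / sigma_nc (saturated-regime fit) come from
    different fits and need not multiply out exactly.  The product is the
    quantity entering threshold and FOM arithmetic, so when both a product
    and sigma_mn are tabulated, sigma_nc is re-derived as product/sigma_mn
    (the same convention the tables use where only the product was
    measured), keeping the returned object internally consistent.
    """
    df = load_photophysics()
    row = df[(df["protein"] == protein) & (df["lambda_nm"] == lambda_nm)]
    if row.empty:
        raise ValidationError(
            f"no packaged parameters for {protein} at {lambda_nm} nm"
        )
    r = row.iloc[0]

    def opt(col):
        v = r.get(col)
        return None if pd.isna(v) else float(v)

    prod = opt("sigma_mn_sigma_nc_cm4")
    sigma_mn = opt("sigma_mn_cm2")
    sigma_nc = opt("sigma_nc_cm2")
    if prod is not None and sigma_mn is not None:
        sigma_nc = prod / sigma_mn
    return MolecularPhotophysics(
        sigma2_gm=opt("sigma2_GM"),
        phim=opt("phi_12"),
        phin=opt("phi_n"),
        sigma_mn=sigma_mn,
        sigma_nc=sigma_nc,
        product_mn_nc_explicit=prod,
        vde_ev=opt("vde_eV"),
        phiF=opt("phi_F"),
    )


# ---------------------------------------------------------------------------
# power series and decay traces
# ---------------------------------------------------------------------------


def read_power_series(path: Union[str, Path]) -> PowerSeries:
    """Read a power-series CSV with columns P_mW, K_per_s[, K_se_per_s].

    Rows with missing, non-numeric or nonpositive powers / non-finite rates
    are rejected with their line numbers.  Powers are converted to W and the
    series is returned sorted ascending (stable reorder).
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"P_mW", "K_per_s"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing required columns {sorted(required - set(df.columns))}"
        )
    bad_lines = []
    P = pd.to_numeric(df["P_mW"], errors="coerce")
    K = pd.to_numeric(df["K_per_s"], errors="coerce")
    for i in df.index:
        if not np.isfinite(P[i]) or P[i] <= 0 or not np.isfinite(K[i]):
            bad_lines.append(int(i) + 2)  # 1-based + header line
    if bad_lines:
        raise ValidationError(
            f"{path}: malformed rows at line(s) {bad_lines} "
            "(powers must be positive numbers, rates finite)"
        )
    se = None
    if "K_se_per_s" in df.columns:
        se = pd.to_numeric(df["K_se_per_s"], errors="coerce").to_numpy()
    return PowerSeries(
        P=P.to_numpy() * 1e-3, K=K.to_numpy(), K_se=se
    )


def write_power_series(series: PowerSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"P_mW": series.P * 1e3, "K_per_s": series.K})
    if series.K_se is not None:
        df["K_se_per_s"] = series.K_se
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_decay_trace(path: Union[str, Path]) -> DecayTrace:
    """Read a decay-trace CSV with columns time_s, F; '# meta: {...}' header
    comments carry acquisition metadata as JSON."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# meta:"):
                meta = json.loads(line[len("# meta:") :])
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "F"}.issubset(df.columns):
        raise ValidationError(f"{path}: trace CSV needs columns time_s, F")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
    F = pd.to_numeric(df["F"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(F)):
        raise ValidationError(f"{path}: non-numeric values in trace")
    return DecayTrace(t=t, F=F, meta=meta)


def write_decay_trace(trace: DecayTrace, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# meta: " + json.dumps(trace.meta, default=float) + "\n")
        fh.write("time_s,F\n")
        for ti, Fi in zip(trace.t, trace.F):
            fh.write(f"{float(ti)!r},{float(Fi)!r}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONTEXT_KEYS = {
    "lambda_nm",
    "f_Hz",
    "dtau_fs",
    "w0_um",
    "l_um",
    "z0_um",
    "n0",
    "sigma2_GM",
    "P_mW",
}


def load_context(path: Union[str, Path]) -> SeriesContext:
    """Read a laser/geometry context from YAML or JSON.

    Keys carry explicit unit suffixes: lambda_nm, f_Hz, dtau_fs, w0_um,
    l_um, [z0_um], n0, sigma2_GM, [P_mW].  Unknown keys are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: context must be a mapping")
    unknown = set(raw) - _CONTEXT_KEYS
    if unknown:
        raise ValidationError(f"{path}: unknown keys {sorted(unknown)}")
    missing = {"lambda_nm", "f_Hz", "dtau_fs", "w0_um", "l_um", "n0", "sigma2_GM"} - set(
        raw
    )
    if missing:
        raise ValidationError(f"{path}: missing keys {sorted(missing)}")
    laser = LaserConfig(
        lambda_nm=float(raw["lambda_nm"]),
        f=float(raw["f_Hz"]),
        dtau=float(raw["dtau_fs"]) * 1e-15,
        P=float(raw.get("P_mW", 0.0)) * 1e-3,
    )
    geometry = BeamGeometry.from_units(
        w0_um=float(raw["w0_um"]),
        lambda_nm=float(raw["lambda_nm"]),
        n0=float(raw["n0"]),
        z0_um=float(raw.get("z0_um", 0.0)),
        l_um=float(raw["l_um"]),
    )
    return SeriesContext(laser=laser, geometry=geometry, sigma2_gm=float(raw["sigma2_GM"]))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_UNITS = {
    "alpha": "dimensionless",
    "a2": "s^-1 W^-2",
    "a3": "s^-1 W^-3",
    "a4": "s^-1 W^-4",
    "Pstar": "W",
    "phi": "dimensionless",
    "phin": "dimensionless",
    "sigma_mn_phi_n": "cm^2",
    "product_mn_nc": "cm^4",
    "sigma_mn": "cm^2",
    "sigma_nc": "cm^2",
    "w0": "cm",
    "z0": "cm",
    "zR": "cm",
    "l": "cm",
}


def _payload(result) -> dict:
    if isinstance(result, InferenceResult):
        body = result.to_dict()
        for key, val in body.items():
            if isinstance(val, dict) and key in _UNITS:
                val["units"] = _UNITS[key]
        return {"kind": "inference", "result": body}
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        body = dataclasses.asdict(result)
        return {"kind": type(result).__name__, "result": body}
    if isinstance(result, pd.DataFrame):
        return {"kind": "table", "result": result.to_dict(orient="records")}
    if isinstance(result, dict):
        return {"kind": "mapping", "result": result}
    raise ValidationError(f"cannot serialize result of type {type(result)!r}")


def write_report(
    result,
    path: Union[str, Path],
    config: Optional[dict] = None,
    csv_mirror: bool = False,
) -> dict:
    """Write a structured JSON report (and optionally a CSV mirror of
    tabular content).  Every report embeds the schema version, package
    version, resolved-config hash and a UTC timestamp."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _payload(result)
    payload["schema_version"] = SCHEMA_VERSION
    payload["provenance"] = {
        "package": f"mpbleach {_PACKAGE_VERSION}",
        "config_hash": config_hash(config or {}),
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    if csv_mirror and isinstance(result, pd.DataFrame):
        result.to_csv(path.with_suffix(".csv"), index=False)
    return payload
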