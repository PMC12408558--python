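"""File round-tripping: datasets (CSV), parameters and designs (YAML), logs.

The dataset format is the long NONMEM-style layout: one row per dose event
or observation, columns ID, TIME, EVID, CMT, AMT (mg), RATE (mg/h),
DV (ng/mL), DVID (1 total irinotecan, 2 total SN-38, 3 SN-38G), MDV, COHORT.
Dose events appear as four simultaneous infusion rows (compartments 1, 3, 6,
8) carrying the NP/S split amounts.

Parameter files use the field's conventional symbols (CL1..V10, K13, K68,
PROP1-3, a BSV block) plus the formulation constants (fnp_iri, fnp_sn38,
fmet, mw_iri, mw_sn38).
"""

from __future__ import annotations

import json
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import FixedEffects
from .population import DATASET_COLUMNS, VariabilitySpec
from .trial import Cohort, TrialDesign

__all__ = [
    "read_dataset",
    "write_dataset",
    "load_parameters",
    "save_parameters",
    "load_design",
    "save_design",
    "write_run_log",
]

_INT_COLUMNS = ("ID", "EVID", "CMT", "DVID", "MDV", "COHORT")

#: YAML symbol <-> FixedEffects attribute
_SYMBOLS = {
    "CL1": "cl1", "V1": "v1", "V2": "v2", "Q1": "q1", "K13": "k13",
    "V3": "v3", "V4": "v4", "V5": "v5", "Q2": "q2", "Q3": "q3",
    "K68": "k68", "V8": "v8", "V9": "v9", "Q5": "q5", "CL2": "cl2",
    "CL3": "cl3", "Q6": "q6", "V10": "v10",
    "fnp_iri": "fnp_iri", "fnp_sn38": "fnp_sn38", "fmet": "fmet",
    "mw_iri": "mw_iri", "mw_sn38": "mw_sn38",
}
_PROP_SYMBOLS = {"PROP1": "irinotecan", "PROP2": "sn38", "PROP3": "sn38g"}


def validate_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Schema and sanity checks; errors name the offending row and column."""
    missing = [c for c in DATASET_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s) {missing}")
    bad_amt = data.index[data["AMT"] < 0]
    if len(bad_amt):
        raise ValueError(f"negative AMT at row {bad_amt[0]} (column AMT)")
    obs = data[(data["EVID"] == 0) & (data["MDV"] == 0)]
    if obs.empty:
        warnings.warn("dataset contains zero usable observations")
    for (sid, dvid), sub in obs.groupby(["ID", "DVID"]):
        t = sub["TIME"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            row = sub.index[int(np.argmax(np.diff(t) <= 0)) + 1]
            raise ValueError(
                f"non-monotone TIME within subject {sid}, DVID {dvid} at row {row} (column TIME)"
            )
    return data


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial dataset CSV."""
    data = pd.read_csv(path)
    validate_dataset(data)
    for col in _INT_COLUMNS:
        data[col] = data[col].astype(np.int64)
    for col in ("TIME", "AMT", "RATE", "DV"):
        data[col] = data[col].astype(float)
    return data[list(DATASET_COLUMNS)]


def write_dataset(path: str | Path, data: pd.DataFrame) -> None:
    """Validate and write a trial dataset CSV (comma, UTF-8, header, no index)."""
    validate_dataset(data)
    data.to_csv(path, index=False, encoding="utf-8")


def load_parameters(path: str | Path) -> tuple[FixedEffects, VariabilitySpec]:
    """Read a parameter YAML into (typical values, variability)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    unknown = set(raw) - set(_SYMBOLS) - set(_PROP_SYMBOLS) - {"BSV"}
    if unknown:
        raise ValueError(f"unknown parameter key(s) {sorted(unknown)}")
    values = {attr: float(raw[sym]) for sym, attr in _SYMBOLS.items() if sym in raw}
    theta = FixedEffects(**values)
    omega = {}
    for sym, value in (raw.get("BSV") or {}).items():
        if sym not in _SYMBOLS:
            raise ValueError(f"unknown BSV key {sym!r}")
        omega[_SYMBOLS[sym]] = float(value)
    sigma = {
        analyte: float(raw[sym]) for sym, analyte in _PROP_SYMBOLS.items() if sym in raw
    }
    return theta, VariabilitySpec(omega=omega, sigma_prop=sigma)


def save_parameters(path: str | Path, theta: FixedEffects, spec: VariabilitySpec) -> None:
    attr_to_sym = {attr: sym for sym, attr in _SYMBOLS.items()}
    out: dict = {sym: getattr(theta, attr) for sym, attr in _SYMBOLS.items()}
    out["BSV"] = {attr_to_sym[name]: value for name, value in spec.omega.items()}
    for sym, analyte in _PROP_SYMBOLS.items():
        out[sym] = spec.sigma_for(analyte)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def load_design(path: str | Path) -> TrialDesign:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    cohorts = tuple(
        Cohort(
            n=int(c["n"]),
            dose_iri_per_m2=float(c["dose_iri_mg_m2"]),
            dose_sn38_per_m2=float(c["dose_sn38_mg_m2"]),
        )
        for c in raw["cohorts"]
    )
    kwargs = {}
    if "sampling_times" in raw:
        kwargs["sampling_times"] = tuple(float(t) for t in raw["sampling_times"])
    if "bsa" in raw:
        kwargs["bsa"] = float(raw["bsa"])
    if "infusion_duration" in raw:
        kwargs["infusion_duration"] = float(raw["infusion_duration"])
    return TrialDesign(cohorts=cohorts, **kwargs)


def save_design(path: str | Path, design: TrialDesign) -> None:
    out = {
        "cohorts": [
            {
                "n": c.n,
                "dose_iri_mg_m2": c.dose_iri_per_m2,
                "dose_sn38_mg_m2": c.dose_sn38_per_m2,
            }
            for c in design.cohorts
        ],
        "sampling_times": list(design.sampling_times),
        "bsa": design.bsa,
        "infusion_duration": design.infusion_duration,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def write_run_log(outdir: str | Path, command: str, seed: int | None, **details) -> Path:
    """Provenance record for a CLI run: command, seed, package version, inputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {
        "command": command,
        "seed": seed,
        "nanopk_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        **details,
    }
    path = outdir / f"{command}_run_log.json"
    path.write_text(json.dumps(log, indent=2, default=str), encoding="utf-8")
    return path
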