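"""Between-subject variability and residual error on top of the structural model.

Individual parameters are log-normal around the typical values,
``p_i = theta_p * exp(eta_p)`` with ``eta_p ~ N(0, omega_p^2)`` independent
across parameters.  Structurally shared parameters (V6=V1, V7=V2, Q4=Q1,
V11=V9) are stored once, so a single eta automatically applies to both roles.
Observations carry a proportional residual, ``obs = pred * (1 + eps)`` with a
separate eps SD per analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import (
    ANALYTES,
    DoseRegimen,
    FixedEffects,
    observe_totals,
    simulate_profile,
)

__all__ = [
    "ETA_PARAMETERS",
    "DVID_CODES",
    "VariabilitySpec",
    "IndividualParameters",
    "sample_individual",
    "apply_residual_error",
    "simulate_trial",
    "DATASET_COLUMNS",
]

#: parameters carrying between-subject variability in the final model;
#: the dissolved-irinotecan entries are literature values held fixed during
#: estimation but still sampled when simulating subjects.
ETA_PARAMETERS: tuple[str, ...] = (
    "cl1", "v1", "v2", "v3", "v4", "v5", "q2", "q3", "k68", "cl2", "cl3", "v10",
)

#: DV identifier codes in the long-format dataset
DVID_CODES: Mapping[str, int] = {"irinotecan": 1, "sn38": 2, "sn38g": 3}

#: dosed compartments (1-based, NONMEM-style) in dose-event rows
DOSE_CMTS = (1, 3, 6, 8)

DATASET_COLUMNS = ("ID", "TIME", "EVID", "CMT", "AMT", "RATE", "DV", "DVID", "MDV", "COHORT")

_DEFAULT_OMEGA = {
    "cl1": 0.347, "v1": 0.409, "v2": 0.945, "v3": 0.154, "v4": 0.162,
    "v5": 0.291, "q2": 0.861, "q3": 0.495, "k68": 0.396, "cl2": 0.449,
    "cl3": 1.159, "v10": 1.221,
}
_DEFAULT_SIGMA = {"irinotecan": 0.21, "sn38": 0.416, "sn38g": 0.308}


@dataclass(frozen=True)
class VariabilitySpec:
    """Log-normal BSV SDs (omega) and per-analyte proportional error SDs.

    Defaults are the final population estimates; omegas are the SD of
    log-parameter (reported as percentages, e.g. 34.7% -> 0.347).  Parameters
    without an entry have no between-subject variability.
    """

    omega: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_OMEGA))
    sigma_prop: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGMA))

    def __post_init__(self) -> None:
        for name, value in self.omega.items():
            if name not in ETA_PARAMETERS:
                raise ValueError(f"parameter {name!r} does not carry between-subject variability")
            if value < 0:
                raise ValueError(f"omega[{name!r}] must be non-negative, got {value!r}")
        for analyte, value in self.sigma_prop.items():
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {analyte!r}")
            if value < 0:
                raise ValueError(f"sigma_prop[{analyte!r}] must be non-negative, got {value!r}")

    def omega_for(self, name: str) -> float:
        return float(self.omega.get(name, 0.0))

    def sigma_for(self, analyte: str) -> float:
        if analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {analyte!r}")
        return float(self.sigma_prop.get(analyte, 0.0))

    @classmethod
    def none(cls) -> "VariabilitySpec":
        """No variability at all (typical-subject simulation)."""
        return cls(omega={}, sigma_prop={})


@dataclass(frozen=True)
class IndividualParameters:
    """One subject's random effects and the realised parameter set."""

    subject_id: int
    eta: Mapping[str, float]
    params: FixedEffects


def sample_individual(
    theta: FixedEffects,
    spec: VariabilitySpec,
    rng: np.random.Generator,
    subject_id: int = 1,
) -> IndividualParameters:
    """Draw one subject: eta_p ~ N(0, omega_p^2), parameter = theta_p * exp(eta_p).

    Draws are made for every BSV-carrying parameter in a fixed order so the
    stream of random numbers (and thus reproducibility) does not depend on
    which omegas happen to be zero.
    """
    eta = {}
    values = {}
    for name in ETA_PARAMETERS:
        omega = spec.omega_for(name)
        draw = rng.normal(0.0, 1.0)
        eta[name] = omega * draw
        if eta[name] != 0.0:
            values[name] = getattr(theta, name) * float(np.exp(eta[name]))
    return IndividualParameters(
        subject_id=subject_id, eta=eta, params=theta.with_values(**values)
    )


def apply_residual_error(
    true_conc: np.ndarray | float,
    analyte: str,
    spec: VariabilitySpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Proportional residual: obs = true * (1 + eps), eps ~ N(0, sigma^2).

    Negative draws (possible when sigma is large) are floored at zero, the
    convention for a concentration scale.  A true concentration of zero stays
    zero exactly.
    """
    sigma = spec.sigma_for(analyte)
    true_conc = np.asarray(true_conc, dtype=float)
    if np.any(true_conc < 0):
        raise ValueError("true concentrations must be non-negative")
    eps = rng.normal(0.0, 1.0, size=true_conc.shape) * sigma
    return np.maximum(true_conc * (1.0 + eps), 0.0)


def _dose_rows(subject_id: int, cohort: int, params: FixedEffects, regimen: DoseRegimen) -> list[dict]:
    splits = {
        1: params.fnp_iri * regimen.dose_iri,
        3: (1.0 - params.fnp_iri) * regimen.dose_iri,
        6: params.fnp_sn38 * regimen.dose_sn38,
        8: (1.0 - params.fnp_sn38) * regimen.dose_sn38,
    }
    return [
        {
            "ID": subject_id, "TIME": regimen.start_time, "EVID": 1, "CMT": cmt,
            "AMT": amt, "RATE": amt / regimen.infusion_duration,
            "DV": np.nan, "DVID": 0, "MDV": 1, "COHORT": cohort,
        }
        for cmt, amt in splits.items()
    ]


def simulate_trial(
    design,
    theta: FixedEffects,
    spec: VariabilitySpec,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a full trial into a long-format (NONMEM-style) dataset.

    One subject at a time: draw individual parameters, solve the model at the
    design's sampling times, form the three observed totals, and apply the
    per-analyte proportional error.  The pre-dose sample (t = 0) is emitted
    with MDV=1 and DV=0 (nothing on board before the infusion).

    `design` must provide `cohorts` (each with `n`, `dose_iri_per_m2`,
    `dose_sn38_per_m2`), `sampling_times`, `bsa` and `infusion_duration`
    (see :func:`nanopk.trial.default_design`).
    """
    if not design.cohorts:
        raise ValueError("trial design has no cohorts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.asarray(design.sampling_times, dtype=float)

    rows: list[dict] = []
    subject_id = 0
    for cohort_no, cohort in enumerate(design.cohorts, start=1):
        regimen = DoseRegimen(
            dose_iri_per_m2=cohort.dose_iri_per_m2,
            dose_sn38_per_m2=cohort.dose_sn38_per_m2,
            bsa=design.bsa,
            infusion_duration=design.infusion_duration,
        )
        for _ in range(cohort.n):
            subject_id += 1
            indiv = sample_individual(theta, spec, rng, subject_id=subject_id)
            rows.extend(_dose_rows(subject_id, cohort_no, indiv.params, regimen))
            obs_times = times[times > regimen.start_time]
            profile = simulate_profile(indiv.params, regimen, obs_times)
            totals = observe_totals(profile)
            for analyte, dvid in DVID_CODES.items():
                noisy = apply_residual_error(totals[analyte], analyte, spec, rng)
                if np.any(times <= regimen.start_time):
                    rows.append({
                        "ID": subject_id, "TIME": float(times[0]), "EVID": 0, "CMT": 0,
                        "AMT": 0.0, "RATE": 0.0, "DV": 0.0, "DVID": dvid, "MDV": 1,
                        "COHORT": cohort_no,
                    })
                for t, dv in zip(obs_times, noisy):
                    rows.append({
                        "ID": subject_id, "TIME": float(t), "EVID": 0, "CMT": 0,
                        "AMT": 0.0, "RATE": 0.0, "DV": float(dv), "DVID": dvid,
                        "MDV": 0, "COHORT": cohort_no,
                    })

    data = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    data = data.sort_values(["ID", "TIME", "EVID", "DVID"], kind="stable").reset_index(drop=True)
    return data
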