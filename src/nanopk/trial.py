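"""Synthetic Phase-I trial generator.

The dose-escalation study behind the model enrolled 21 adults with advanced
solid tumours in seven cohorts, SN-38 doses 5-50 mg/m^2 with irinotecan at
the fixed product ratio (~1:1 molar), and a rich single-dose sampling
schedule out to 169.5 h.  The clinical dataset is not public, so this module
generates datasets with the same design and the statistical structure the
analysis assumes (log-normal BSV, proportional error).  Demographics are
carried as metadata only — the final model contains no covariate effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FixedEffects
from .population import VariabilitySpec, simulate_trial

__all__ = ["Cohort", "TrialDesign", "default_design", "generate", "SAMPLING_TIMES"]

#: single-dose sampling schedule (h): pre-dose plus 16 post-dose samples
SAMPLING_TIMES: tuple[float, ...] = (
    0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0,
    24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, 169.5,
)


@dataclass(frozen=True)
class Cohort:
    """One dose-escalation cohort (doses body-surface-area normalised)."""

    n: int
    dose_iri_per_m2: float
    dose_sn38_per_m2: float
    sex_m: int = 0
    sex_f: int = 0
    age_yr: float = float("nan")
    weight_kg: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort must enrol at least one subject")
        if self.dose_iri_per_m2 < 0 or self.dose_sn38_per_m2 < 0:
            raise ValueError("doses must be non-negative")


@dataclass(frozen=True)
class TrialDesign:
    """Cohorts plus the shared sampling schedule and infusion settings."""

    cohorts: tuple[Cohort, ...]
    sampling_times: tuple[float, ...] = SAMPLING_TIMES
    bsa: float = 1.6              # m^2, fixed for all simulated subjects
    infusion_duration: float = 1.5  # h

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("design needs at least one cohort")
        times = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(times) <= 0) or np.any(times < 0):
            raise ValueError("sampling times must be non-negative and strictly increasing")

    @property
    def n_subjects(self) -> int:
        return sum(c.n for c in self.cohorts)


def default_design() -> TrialDesign:
    """The seven-cohort, 21-subject first-in-human dose-escalation design.

    Dose pairs keep irinotecan:SN-38 close to 1:1 molar (the product's fixed
    composition); demographics are cohort-level metadata.
    """
    cohorts = (
        Cohort(n=1, dose_iri_per_m2=8.0, dose_sn38_per_m2=5.0, sex_m=1, age_yr=60, weight_kg=70),
        Cohort(n=1, dose_iri_per_m2=16.0, dose_sn38_per_m2=10.0, sex_m=1, age_yr=62, weight_kg=72),
        Cohort(n=1, dose_iri_per_m2=32.0, dose_sn38_per_m2=20.0, sex_m=1, age_yr=58, weight_kg=68),
        Cohort(n=5, dose_iri_per_m2=48.0, dose_sn38_per_m2=30.0, sex_m=3, sex_f=2, age_yr=65.0, weight_kg=75.0),
        Cohort(n=7, dose_iri_per_m2=64.0, dose_sn38_per_m2=40.0, sex_m=4, sex_f=3, age_yr=63.0, weight_kg=73.0),
        Cohort(n=3, dose_iri_per_m2=72.0, dose_sn38_per_m2=45.0, sex_m=2, sex_f=1, age_yr=59.0, weight_kg=70.0),
        Cohort(n=3, dose_iri_per_m2=80.0, dose_sn38_per_m2=50.0, sex_m=2, sex_f=1, age_yr=62.0, weight_kg=73.0),
    )
    return TrialDesign(cohorts=cohorts)


def generate(
    design: TrialDesign,
    theta: FixedEffects | None = None,
    spec: VariabilitySpec | None = None,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a trial dataset under the given design (long NONMEM format)."""
    theta = theta if theta is not None else FixedEffects()
    spec = spec if spec is not None else VariabilitySpec()
    return simulate_trial(design, theta, spec, seed=seed)
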