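"""Visual predictive check: percentile bands of replicate trial simulations.

For each dose cohort, analyte and nominal sampling time, many full trials
are simulated under the population model and the 5th/50th/95th percentiles
of the simulated observations form the median and 90% prediction interval.
Simulated times coincide with the nominal schedule, so no time-binning is
needed; percentiles use the standard linear-interpolation quantile
estimator.  Cohorts of one subject still get bands (the spread then reflects
prediction uncertainty for a single subject).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import _totals_matrix
from .model import DoseRegimen, FixedEffects, infusion_rates
from .population import DVID_CODES, VariabilitySpec, apply_residual_error, sample_individual

__all__ = ["VpcResult", "run_vpc", "fraction_within_band", "plot_vpc"]

_ANALYTE_ORDER = tuple(DVID_CODES)


@dataclass(frozen=True)
class VpcResult:
    """Tidy percentile table: one row per (cohort, analyte, time)."""

    table: pd.DataFrame  # cohort, dose_iri_mg_m2, dose_sn38_mg_m2, analyte, time, p5, p50, p95
    n_rep: int

    def band(self, cohort: int, analyte: str) -> pd.DataFrame:
        t = self.table
        return t[(t["cohort"] == cohort) & (t["analyte"] == analyte)].reset_index(drop=True)


def run_vpc(
    design,
    theta: FixedEffects | None = None,
    spec: VariabilitySpec | None = None,
    n_rep: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> VpcResult:
    """Simulate `n_rep` trials and summarise per-bin percentiles.

    Draws follow the same per-subject order as
    :func:`nanopk.population.simulate_trial` (etas first, then residuals per
    analyte), so a single replicate reproduces that function's observations
    for the same seed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be at least 1")
    if not design.cohorts:
        raise ValueError("trial design has no cohorts")
    theta = theta if theta is not None else FixedEffects()
    spec = spec if spec is not None else VariabilitySpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    times = np.asarray(design.sampling_times, dtype=float)
    obs_times = times[times > 0]
    n_t = obs_times.size

    regimens = [
        DoseRegimen(
            dose_iri_per_m2=c.dose_iri_per_m2,
            dose_sn38_per_m2=c.dose_sn38_per_m2,
            bsa=design.bsa,
            infusion_duration=design.infusion_duration,
        )
        for c in design.cohorts
    ]

    # sims[cohort] has shape (n_rep * n_subjects, n_analytes, n_times)
    sims = [np.empty((n_rep * c.n, 3, n_t)) for c in design.cohorts]
    for rep in range(n_rep):
        for ci, (cohort, regimen) in enumerate(zip(design.cohorts, regimens)):
            for s in range(cohort.n):
                indiv = sample_individual(theta, spec, rng)
                u = infusion_rates(indiv.params, regimen)
                totals = _totals_matrix(
                    indiv.params, u, regimen.start_time, regimen.infusion_duration, obs_times
                ).T  # (3, n_times)
                row = rep * cohort.n + s
                for ai, analyte in enumerate(_ANALYTE_ORDER):
                    sims[ci][row, ai] = apply_residual_error(totals[ai], analyte, spec, rng)

    records = []
    for ci, cohort in enumerate(design.cohorts):
        p5, p50, p95 = np.percentile(sims[ci], [5.0, 50.0, 95.0], axis=0)
        for ai, analyte in enumerate(_ANALYTE_ORDER):
            for ti, t in enumerate(obs_times):
                records.append({
                    "cohort": ci + 1,
                    "dose_iri_mg_m2": cohort.dose_iri_per_m2,
                    "dose_sn38_mg_m2": cohort.dose_sn38_per_m2,
                    "analyte": analyte,
                    "time": float(t),
                    "p5": p5[ai, ti],
                    "p50": p50[ai, ti],
                    "p95": p95[ai, ti],
                })
    return VpcResult(table=pd.DataFrame(records), n_rep=n_rep)


def fraction_within_band(result: VpcResult, dataset: pd.DataFrame) -> float:
    """Fraction of observed DVs inside their bin's 90% prediction interval."""
    obs = dataset[(dataset["EVID"] == 0) & (dataset["MDV"] == 0)]
    if obs.empty:
        raise ValueError("dataset contains no usable observations")
    code_to_name = {code: name for name, code in DVID_CODES.items()}
    lookup = result.table.set_index(["cohort", "analyte", "time"])
    inside = 0
    for _, row in obs.iterrows():
        band = lookup.loc[(int(row["COHORT"]), code_to_name[int(row["DVID"])], float(row["TIME"]))]
        inside += bool(band["p5"] <= row["DV"] <= band["p95"])
    return inside / len(obs)


def plot_vpc(result: VpcResult, dataset: pd.DataFrame | None = None, path: str | None = None):
    """Per-analyte VPC panels (median solid, 90% PI dashed, observations dots)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cohorts = sorted(result.table["cohort"].unique())
    analytes = list(_ANALYTE_ORDER)
    fig, axes = plt.subplots(
        len(analytes), len(cohorts),
        figsize=(3.2 * len(cohorts), 2.6 * len(analytes)),
        squeeze=False, sharex=True,
    )
    code_by_name = DVID_CODES
    for ai, analyte in enumerate(analytes):
        for ci, cohort in enumerate(cohorts):
            ax = axes[ai][ci]
            band = result.band(cohort, analyte)
            ax.plot(band["time"], band["p50"], "r-", lw=1.2)
            ax.plot(band["time"], band["p5"], "b--", lw=0.9)
            ax.plot(band["time"], band["p95"], "b--", lw=0.9)
            if dataset is not None:
                obs = dataset[
                    (dataset["EVID"] == 0) & (dataset["MDV"] == 0)
                    & (dataset["COHORT"] == cohort)
                    & (dataset["DVID"] == code_by_name[analyte])
                ]
                ax.plot(obs["TIME"], obs["DV"], "k.", ms=3, alpha=0.6)
            ax.set_yscale("log")
            if ai == 0:
                ax.set_title(f"cohort {cohort}", fontsize=9)
            if ci == 0:
                ax.set_ylabel(f"{analyte}\n(ng/mL)", fontsize=8)
    fig.supxlabel("time (h)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
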