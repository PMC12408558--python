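"""Structural 11-compartment model for SNB-101 pharmacokinetics.

SNB-101 is a polymeric nanoparticle that co-encapsulates irinotecan and its
active metabolite SN-38 at roughly a 1:1 molar ratio.  After an intravenous
infusion, each drug circulates in two conceptual forms: still bound inside
the nanoparticle (NP form) and dissolved in plasma (S form).  Only the S
form is metabolised; only total (NP + S) concentrations are measured in
early-phase trials, so the model's job is to account for both forms with
separate compartments and let the NP/S split be inferred from totals.

Compartment map (amounts in mg)::

    1  NP-irinotecan central        (V1)
    2  NP-irinotecan peripheral     (V2)
    3  S-irinotecan central         (V3)
    4  S-irinotecan rapid periph.   (V4)
    5  S-irinotecan slow periph.    (V5)
    6  NP-SN-38 central             (V6 = V1, shared NP disposition)
    7  NP-SN-38 peripheral          (V7 = V2)
    8  S-SN-38 central              (V8)
    9  S-SN-38 peripheral           (V9)
    10 SN-38G central               (V10)
    11 SN-38G peripheral            (V11 = V9)

All transfer is first order.  The only exit from each NP pool is release
into the matching dissolved pool (K13, K68).  S-irinotecan is cleared by
CL1, of which a fixed 3% (molar) appears as S-SN-38; S-SN-38 is eliminated
exclusively by glucuronidation to SN-38G (CL2); SN-38G is cleared by CL3.

Units: amounts mg, volumes L, time h; concentrations are reported in ng/mL
(mg/L x 1000).  The system is linear, so profiles are computed exactly with
piecewise matrix exponentials (the release constant K13 = 64.4 /h makes the
system stiff, ruling out naive explicit stepping).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

import numpy as np
from scipy.linalg import expm

__all__ = [
    "N_COMPARTMENTS",
    "FORMS",
    "ANALYTES",
    "FixedEffects",
    "DoseRegimen",
    "CompartmentLayout",
    "ConcentrationProfile",
    "build_rate_matrix",
    "infusion_rates",
    "simulate_profile",
    "observe_totals",
    "propagate",
    "integrate_amounts",
]

N_COMPARTMENTS = 11

# 0-based compartment indices
NP_IRI_CENTRAL = 0
NP_IRI_PERIPH = 1
S_IRI_CENTRAL = 2
S_IRI_RAPID = 3
S_IRI_SLOW = 4
NP_SN38_CENTRAL = 5
NP_SN38_PERIPH = 6
S_SN38_CENTRAL = 7
S_SN38_PERIPH = 8
SN38G_CENTRAL = 9
SN38G_PERIPH = 10

#: analyte-form -> (central compartment index, volume attribute)
FORMS: Mapping[str, tuple[int, str]] = {
    "np_iri": (NP_IRI_CENTRAL, "v1"),
    "s_iri": (S_IRI_CENTRAL, "v3"),
    "np_sn38": (NP_SN38_CENTRAL, "v1"),
    "s_sn38": (S_SN38_CENTRAL, "v8"),
    "sn38g": (SN38G_CENTRAL, "v10"),
}

#: observed analytes (totals) -> constituent forms
ANALYTES: Mapping[str, tuple[str, ...]] = {
    "irinotecan": ("np_iri", "s_iri"),
    "sn38": ("np_sn38", "s_sn38"),
    "sn38g": ("sn38g",),
}

#: dosed compartments and the dose-split attribute driving each
DOSING_SPLIT = (
    (NP_IRI_CENTRAL, "iri", True),
    (S_IRI_CENTRAL, "iri", False),
    (NP_SN38_CENTRAL, "sn38", True),
    (S_SN38_CENTRAL, "sn38", False),
)


@dataclass(frozen=True)
class FixedEffects:
    """Population (typical-subject) structural parameters.

    Defaults are the final population estimates for SNB-101; the dissolved
    irinotecan disposition (V3, V4, V5, Q2, Q3 and CL1's structure) follows
    the literature three-compartment model and is conventionally held fixed
    during estimation.  V6/V7/Q4 and V11 are not stored: NP-SN-38 shares the
    NP-irinotecan disposition (v1, v2, q1) and SN-38G shares the S-SN-38
    peripheral volume (v9), exposed as read-only aliases.
    """

    cl1: float = 29.7     # L/h, S-irinotecan clearance
    v1: float = 54.4      # L, NP central (irinotecan and SN-38)
    v2: float = 287.0     # L, NP peripheral
    q1: float = 6.45      # L/h, NP intercompartmental clearance
    k13: float = 64.4     # 1/h, NP-irinotecan -> S-irinotecan release
    v3: float = 68.6      # L, S-irinotecan central
    v4: float = 67.2      # L, S-irinotecan rapid peripheral
    v5: float = 127.0     # L, S-irinotecan slow peripheral
    q2: float = 114.0     # L/h, cpt 3 <-> 4
    q3: float = 9.89      # L/h, cpt 3 <-> 5
    k68: float = 0.712    # 1/h, NP-SN-38 -> S-SN-38 release
    v8: float = 40.3      # L, S-SN-38 central
    v9: float = 491.0     # L, S-SN-38 peripheral (shared with SN-38G)
    q5: float = 121.0     # L/h, S-SN-38 intercompartmental
    cl2: float = 167.0    # L/h, S-SN-38 -> SN-38G clearance
    cl3: float = 16.9     # L/h, SN-38G clearance
    q6: float = 11.3      # L/h, SN-38G intercompartmental
    v10: float = 7.84     # L, SN-38G central
    fnp_iri: float = 0.15    # NP fraction of the irinotecan dose
    fnp_sn38: float = 0.98   # NP fraction of the SN-38 dose
    fmet: float = 0.03       # molar fraction of CL1 converted to SN-38
    mw_iri: float = 586.68   # g/mol
    mw_sn38: float = 392.40  # g/mol

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {value!r}")
        for name in ("fnp_iri", "fnp_sn38", "fmet"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"fraction {name!r} must lie in (0, 1), got {value!r}")

    # structurally shared parameters
    @property
    def v6(self) -> float:
        return self.v1

    @property
    def v7(self) -> float:
        return self.v2

    @property
    def q4(self) -> float:
        return self.q1

    @property
    def v11(self) -> float:
        return self.v9

    @property
    def conversion_factor(self) -> float:
        """Mass-flux factor for irinotecan -> SN-38 conversion (molar 3%)."""
        return self.fmet * self.mw_sn38 / self.mw_iri

    def with_values(self, **values: float) -> "FixedEffects":
        return replace(self, **values)


@dataclass(frozen=True)
class DoseRegimen:
    """A single intravenous SNB-101 infusion.

    Doses are body-surface-area normalised (mg/m^2), as in the dose-escalation
    cohorts; absolute amounts are dose x BSA.  The product splits each dose
    between NP and dissolved pools (0.15/0.85 for irinotecan, 0.98/0.02 for
    SN-38), delivered simultaneously as zero-order infusions.
    """

    dose_iri_per_m2: float
    dose_sn38_per_m2: float
    bsa: float = 1.6             # m^2, typical subject
    infusion_duration: float = 1.5  # h
    start_time: float = 0.0      # h

    def __post_init__(self) -> None:
        if self.dose_iri_per_m2 < 0 or self.dose_sn38_per_m2 < 0:
            raise ValueError("doses must be non-negative")
        if self.bsa <= 0:
            raise ValueError("bsa must be positive")
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be positive")
        if self.start_time < 0:
            raise ValueError("start_time must be non-negative")

    @property
    def dose_iri(self) -> float:
        """Absolute irinotecan dose (mg)."""
        return self.dose_iri_per_m2 * self.bsa

    @property
    def dose_sn38(self) -> float:
        """Absolute SN-38 dose (mg)."""
        return self.dose_sn38_per_m2 * self.bsa

    @property
    def end_time(self) -> float:
        return self.start_time + self.infusion_duration

    def scaled(self, factor: float) -> "DoseRegimen":
        return replace(
            self,
            dose_iri_per_m2=self.dose_iri_per_m2 * factor,
            dose_sn38_per_m2=self.dose_sn38_per_m2 * factor,
        )


@dataclass(frozen=True)
class CompartmentLayout:
    """Descriptive view of the compartment scheme for a parameter set."""

    params: FixedEffects

    names: tuple = (
        "NP-irinotecan central",
        "NP-irinotecan peripheral",
        "S-irinotecan central",
        "S-irinotecan rapid peripheral",
        "S-irinotecan slow peripheral",
        "NP-SN-38 central",
        "NP-SN-38 peripheral",
        "S-SN-38 central",
        "S-SN-38 peripheral",
        "SN-38G central",
        "SN-38G peripheral",
    )
    analyte_tags: tuple = (
        "NP-iri", "NP-iri", "S-iri", "S-iri", "S-iri",
        "NP-SN38", "NP-SN38", "S-SN38", "S-SN38", "SN38G", "SN38G",
    )

    @property
    def volumes(self) -> np.ndarray:
        p = self.params
        return np.array([
            p.v1, p.v2, p.v3, p.v4, p.v5,
            p.v6, p.v7, p.v8, p.v9, p.v10, p.v11,
        ])


def build_rate_matrix(params: FixedEffects) -> np.ndarray:
    """First-order rate matrix M such that dA/dt = M A + u(t) (A in mg).

    Release is the sole exit from each NP pool.  Of the S-irinotecan mass
    cleared at rate CL1/V3, a 3% molar fraction re-appears as S-SN-38 (hence
    the MW ratio on the mass flux); the remainder leaves the system.
    S-SN-38 is eliminated only into SN-38G (1:1 mass transfer).
    """
    p = params
    M = np.zeros((N_COMPARTMENTS, N_COMPARTMENTS))

    def exchange(a: int, b: int, q: float, va: float, vb: float) -> None:
        M[a, a] -= q / va
        M[b, a] += q / va
        M[b, b] -= q / vb
        M[a, b] += q / vb

    # NP-irinotecan: release + distribution
    M[NP_IRI_CENTRAL, NP_IRI_CENTRAL] -= p.k13
    M[S_IRI_CENTRAL, NP_IRI_CENTRAL] += p.k13
    exchange(NP_IRI_CENTRAL, NP_IRI_PERIPH, p.q1, p.v1, p.v2)

    # S-irinotecan: three-compartment disposition, CL1 elimination with
    # partial conversion to S-SN-38
    M[S_IRI_CENTRAL, S_IRI_CENTRAL] -= p.cl1 / p.v3
    M[S_SN38_CENTRAL, S_IRI_CENTRAL] += p.conversion_factor * p.cl1 / p.v3
    exchange(S_IRI_CENTRAL, S_IRI_RAPID, p.q2, p.v3, p.v4)
    exchange(S_IRI_CENTRAL, S_IRI_SLOW, p.q3, p.v3, p.v5)

    # NP-SN-38: shared NP disposition, release into S-SN-38
    M[NP_SN38_CENTRAL, NP_SN38_CENTRAL] -= p.k68
    M[S_SN38_CENTRAL, NP_SN38_CENTRAL] += p.k68
    exchange(NP_SN38_CENTRAL, NP_SN38_PERIPH, p.q4, p.v6, p.v7)

    # S-SN-38: glucuronidation is the only elimination
    M[S_SN38_CENTRAL, S_SN38_CENTRAL] -= p.cl2 / p.v8
    M[SN38G_CENTRAL, S_SN38_CENTRAL] += p.cl2 / p.v8
    exchange(S_SN38_CENTRAL, S_SN38_PERIPH, p.q5, p.v8, p.v9)

    # SN-38G
    M[SN38G_CENTRAL, SN38G_CENTRAL] -= p.cl3 / p.v10
    exchange(SN38G_CENTRAL, SN38G_PERIPH, p.q6, p.v10, p.v11)

    return M


def infusion_rates(params: FixedEffects, regimen: DoseRegimen) -> np.ndarray:
    """Zero-order input rates (mg/h) during the infusion, split NP/S."""
    u = np.zeros(N_COMPARTMENTS)
    doses = {"iri": regimen.dose_iri, "sn38": regimen.dose_sn38}
    fracs = {"iri": params.fnp_iri, "sn38": params.fnp_sn38}
    for cpt, drug, is_np in DOSING_SPLIT:
        frac = fracs[drug] if is_np else 1.0 - fracs[drug]
        u[cpt] = frac * doses[drug] / regimen.infusion_duration
    return u


def propagate(M: np.ndarray, u: np.ndarray, a0: np.ndarray, dt: float) -> np.ndarray:
    """Exact state advance over dt under constant forcing u.

    Uses the augmented-matrix construction [[M, u], [0, 0]]: its exponential
    carries both the homogeneous propagator and the particular response, so
    stiffness is handled without stepping.
    """
    n = M.shape[0]
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = M
    aug[:n, n] = u
    phi = expm(aug * dt)
    return phi[:n, :n] @ a0 + phi[:n, n]


def integrate_amounts(
    M: np.ndarray, u: np.ndarray, a0: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (A(dt), integral of A over [0, dt]) under constant forcing.

    The state is augmented with running integrals dI/dt = A and a constant,
    giving areas in closed form (no quadrature grid).
    """
    n = M.shape[0]
    m = 2 * n + 1
    aug = np.zeros((m, m))
    aug[:n, :n] = M
    aug[:n, m - 1] = u
    aug[n : 2 * n, :n] = np.eye(n)
    phi = expm(aug * dt)
    state = np.zeros(m)
    state[:n] = a0
    state[m - 1] = 1.0
    out = phi @ state
    return out[:n], out[n : 2 * n]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Solved amounts on a time grid with NP/S/total concentration views."""

    times: np.ndarray          # h, strictly increasing
    amounts: np.ndarray        # (n_times, 11) mg
    params: FixedEffects
    regimen: DoseRegimen

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("time grid must be one-dimensional and strictly increasing")
        if self.amounts.shape != (times.size, N_COMPARTMENTS):
            raise ValueError("amounts must be (n_times, 11)")

    def concentration(self, form: str) -> np.ndarray:
        """Central-compartment concentration of an analyte form, ng/mL."""
        try:
            cpt, vol_attr = FORMS[form]
        except KeyError:
            raise KeyError(f"unknown analyte form {form!r}; expected one of {sorted(FORMS)}") from None
        volume = getattr(self.params, vol_attr)
        return self.amounts[:, cpt] / volume * 1000.0

    def total(self, analyte: str) -> np.ndarray:
        """Total (NP + S) concentration of an observed analyte, ng/mL."""
        try:
            parts = ANALYTES[analyte]
        except KeyError:
            raise KeyError(f"unknown analyte {analyte!r}; expected one of {sorted(ANALYTES)}") from None
        return sum(self.concentration(form) for form in parts)


def _segment_knots(regimen: DoseRegimen, times: np.ndarray) -> np.ndarray:
    knots = np.union1d(times, [regimen.start_time, regimen.end_time])
    return knots[knots <= times[-1] + 1e-12] if times.size else knots


def simulate_profile(
    params: FixedEffects, regimen: DoseRegimen, times: np.ndarray
) -> ConcentrationProfile:
    """Exact profile for one infusion regimen on an arbitrary sorted grid.

    The linear system is solved piecewise: matrix exponential with constant
    forcing while the infusion runs, homogeneous decay afterwards.  Matrix
    exponentials are cached per step length, so uniform grids cost one expm.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if times[0] < 0:
        raise ValueError("negative time in grid")

    M = build_rate_matrix(params)
    u_on = infusion_rates(params, regimen)
    n = N_COMPARTMENTS

    # augmented propagators, cached by (rounded dt, infusing flag)
    aug_on = np.zeros((n + 1, n + 1))
    aug_on[:n, :n] = M
    aug_on[:n, n] = u_on
    aug_off = aug_on.copy()
    aug_off[:n, n] = 0.0
    cache: dict[tuple[float, bool], np.ndarray] = {}

    def step(a: np.ndarray, dt: float, infusing: bool) -> np.ndarray:
        if dt == 0.0:
            return a
        key = (round(dt, 12), infusing)
        phi = cache.get(key)
        if phi is None:
            phi = expm((aug_on if infusing else aug_off) * dt)
            cache[key] = phi
        return phi[:n, :n] @ a + phi[:n, n]

    knots = _segment_knots(regimen, times)
    if knots[0] > 0.0:
        knots = np.concatenate([[0.0], knots])
    amounts_at: dict[float, np.ndarray] = {}
    a = np.zeros(n)
    amounts_at[knots[0]] = a
    for t0, t1 in zip(knots[:-1], knots[1:]):
        infusing = regimen.start_time <= t0 < regimen.end_time
        a = step(a, t1 - t0, infusing)
        amounts_at[t1] = a

    amounts = np.vstack([amounts_at[t] for t in times])
    # clip tiny negative round-off
    amounts[(amounts < 0) & (amounts > -1e-9)] = 0.0
    return ConcentrationProfile(times=times, amounts=amounts, params=params, regimen=regimen)


def observe_totals(profile: ConcentrationProfile) -> dict[str, np.ndarray]:
    """Total concentrations per observed analyte (ng/mL), keyed by analyte.

    Totals are what the bioanalytical assay reports: NP + S concentration for
    irinotecan and SN-38, and the (dissolved-only) SN-38G concentration.
    """
    return {analyte: profile.total(analyte) for analyte in ANALYTES}
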