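# Methods

## The deconvolution problem

SNB-101 delivers irinotecan and SN-38 inside one polymeric nanoparticle.
Bioanalysis in the first-in-human trial measured total plasma concentrations
only, so the nanoparticle-bound (NP) and dissolved (S) forms must be
separated by modelling. The identifying assumptions are: (i) the dissolved
irinotecan disposition is known from the literature and fixed (three
compartments, CL1 = 29.7 L/h, V3/V4/V5 = 68.6/67.2/127 L, Q2/Q3 = 114/9.89
L/h); (ii) each NP pool's only elimination is first-order release into its
dissolved counterpart; (iii) 3% of cleared irinotecan becomes SN-38;
(iv) S-SN-38 is eliminated only by glucuronidation, so the (dissolved-only)
SN-38G signal pins down CL2. Whatever the fixed S-irinotecan model cannot
explain in total irinotecan is attributed to NP-irinotecan, and the early
total-SN-38 signal, which metabolism alone cannot produce that fast, to
NP-SN-38.

## Structural model

Eleven compartments, all transfer first order, amounts in mg, volumes in L,
time in h; concentrations reported in ng/mL (mg/L × 1000):

| # | pool | volume |
|---|------|--------|
| 1/2 | NP-irinotecan central/peripheral | V1 = 54.4 L, V2 = 287 L |
| 3/4/5 | S-irinotecan central/rapid/slow | V3/V4/V5 (fixed) |
| 6/7 | NP-SN-38 central/peripheral | shares V1, V2, Q1 |
| 8/9 | S-SN-38 central/peripheral | V8 = 40.3 L, V9 = 491 L |
| 10/11 | SN-38G central/peripheral | V10 = 7.84 L, V11 = V9 |

NP-irinotecan and NP-SN-38 ride in the same particle, so their disposition
parameters are shared structurally (single stored value; one eta applies to
both). Release constants: K13 = 64.4 h⁻¹ (irinotecan leaves the particle in
minutes), K68 = 0.712 h⁻¹ (SN-38 over hours) — the asymmetry that makes
NP-SN-38 dominate SN-38 exposure.

Dosing: one intravenous zero-order infusion, split 0.15/0.85
(irinotecan NP/S) and 0.98/0.02 (SN-38 NP/S) per the product's measured
composition, delivered simultaneously into compartments 1, 3, 6, 8.

### Choices where the source design left gaps

- **Infusion duration 1.5 h.** Not reported with the design; calibrated once
  against the published end-of-infusion peaks of the fast-eliminating NP
  pools (3.65 and 824.79 ng/mL at the 50:80 mg/m² level), which pin the rate
  because those pools are near pseudo-steady-state at the end of infusion.
- **BSA 1.6 m².** Follows from the exact identity AUC(S-iri) = BSA ×
  dose_per_m² / CL1 against the published 4,309.93 ng·h/mL at 80 mg/m².
- **3% conversion on a molar basis**, implemented as a mass flux scaled by
  MW(SN-38)/MW(irinotecan) = 392.40/586.68. The mass-basis variant
  overpredicts the published S-SN-38 AUC by ~1.5%; the molar variant
  reproduces it.
- **SN-38 → SN-38G as 1:1 mass transfer.** The true stoichiometric factor is
  unidentifiable (absorbed into CL3/V10, both estimated).

## Simulation

The system is linear with piecewise-constant forcing, so profiles are
computed exactly: the augmented matrix [[M, u], [0, 0]] is exponentiated per
step (constant forcing during the infusion, homogeneous decay after), with
propagators cached per step length. K13 = 64.4 h⁻¹ gives a stiffness ratio
of ~3,000 against the slowest phase (~36 h half-life of NP peripheral
return); explicit stepping is not used anywhere. AUCs are exact too: running
integrals are part of a larger augmented exponential, so no quadrature grid
enters AUC₀₋₃₃₆. AUC₀₋∞ adds the closed-form tail −M⁻¹A(T). Cmax is taken on
a 0.02-h grid over 0–48 h with the exact end-of-infusion point appended (NP
forms peak exactly there; dissolved forms peak within a few hours). The
estimation hot path evaluates the same exact solution through an
eigendecomposition of M (vectorised over observation times) and falls back
to the matrix-exponential route if the eigenbasis is ill-conditioned; both
routes are verified against an implicit (Radau) integration at tight
tolerance.

## Population model

Between-subject variability is log-normal, `p_i = θ_p·exp(η_p)`,
independent across parameters, on exactly the twelve parameters with
reported BSV (CL1, V1, V2, V3, V4, V5, Q2, Q3, K68, CL2, CL3, V10); reported
"BSV %" is interpreted as 100×ω (SD of log), the standard pharmacometric
convention. The dissolved-irinotecan etas are sampled when simulating but
never estimated. Residual error is proportional with a separate SD per
analyte (0.21 irinotecan, 0.416 SN-38, 0.308 SN-38G); negative draws are
floored at zero. No eta correlations, no inter-occasion variability, no
covariate effects (none were retained in the final model), no BQL handling.

## Estimation

Per-subject marginal likelihoods are approximated by Laplace's method around
the posterior mode of the etas. The reported OFV is the full −2 log marginal
likelihood including 2π constants (differences between nested models are
unaffected). Observation variance uses the individual prediction,
(σ_analyte·f_i)², the conventional Laplace/interaction pairing. Pre-dose
records (MDV = 1) are excluded; zero-variance etas are omitted from the
integral.

Numerical choices:

- **Inner problem** (eta mode): damped Newton with Levenberg–Marquardt
  damping on the expected (Fisher) information built from a
  finite-difference prediction Jacobian; forward differences far from the
  mode, central differences close to it. Target gradient tolerance 1e−8 for
  standalone OFV evaluation; during outer optimisation the tolerance is
  relaxed (default 1e−2, 1e−3 for the recovery experiments) because the
  induced OFV error, ~g²/2H, is orders of magnitude below what the outer
  finite differences resolve. Modes are warm-started across outer
  iterations; a stale warm start is discarded when η = 0 scores better.
- **Laplace curvature**: either the exact central-difference Hessian of the
  joint −2 log density (default for `neg2ll`; matches a 64-point
  Gauss–Hermite oracle on a one-eta problem to ~2×10⁻⁴) or the expected
  information (`hessian="expected"`, much cheaper, used for replicate
  fitting experiments).
- **Multimodality**: with the large BSVs on CL3 and V10 (ω > 1), a few
  subjects' joint eta densities are genuinely multimodal. The modes tracked
  across the outer search can dominate a cold restart from η = 0, so the
  final OFV reuses them. Cold evaluations are deterministic but may sit on a
  secondary mode for such subjects.
- **Outer problem**: L-BFGS-B on log-transformed free parameters
  (positivity by construction), finite-difference gradients. The
  literature-fixed dissolved-irinotecan parameters cannot be freed.
- The ΔOFV ≥ 3.84 (χ², 1 df) likelihood-ratio gate is exposed as a utility;
  no covariate search machinery is provided.

## Synthetic trials and what they can show

The generator reproduces the Phase-I design: cohorts of 1/1/1/5/7/3/3
subjects at 5–50 mg/m² SN-38 (irinotecan fixed at 1.6× per m²), sampling at
0, 0.5, 1, 2, 4, 6, 8, 10, 12, 24, 36, 48, 72, 96, 120, 144, 169.5 h, BSA
fixed at 1.6 m² (reported weights are near-constant and the final model has
no covariates; demographics are carried as metadata only). It emulates the
statistical structure the analysis assumes — log-normal BSV, proportional
error, no dropout, no BQL censoring, exact nominal sampling times. Passing
recovery and coverage tests therefore shows the estimator and the VPC are
correct under the model's own assumptions; they cannot show robustness to
model misspecification, assay censoring or irregular sampling in real data.

## Validation scales

Replicate experiments are sized to run on one CPU in minutes: parameter
recovery uses 20 replicate trials of the full 21-subject design with
{K68, CL2, V1} free (each within ±20% of truth in ≥80% of replicates); the
VPC calibration check uses 500 replicates (observed coverage of the 90%
interval within 0.90 ± 0.03). The deterministic exposure grid reproduces the
published table to <0.5% per cell, with closed-form AUC identities checked
to 0.1% and solver equivalence to an implicit ODE oracle to 1e−6.

## Known limitations

- Kinetics are strictly linear; saturable release, protein-corona effects,
  enterohepatic recirculation and lactone/carboxylate interconversion are
  out of scope.
- The estimator is per-subject Laplace, not FOCE-I or SAEM; no
  standard-error or bootstrap machinery is provided.
- A single infusion per subject is supported (the Phase-I setting); no
  multi-cycle accumulation.
- Cold-started OFV evaluations can land on secondary eta modes for subjects
  with very large random effects (see Estimation).
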