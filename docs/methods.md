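# Methods

## Scope and model structure

`pbpkit` simulates the whole-body disposition of AT-RvD1 (aspirin-triggered
resolvin D1, a lipid specialized pro-resolving mediator investigated for
Sjögren's-syndrome hyposalivation) after intravenous bolus dosing, in a
NOD/ShiLtJ mouse and an adult human reference, and derives the standard PK
parameter set by non-compartmental analysis.

The body is a closed circulatory loop of 15 perfused organs — lung, heart,
brain, kidney, liver, spleen, gut, muscle, skin, adipose, bone, gonads,
pancreas, salivary gland and a rest-of-body balance compartment — connected
through arterial and venous plasma pools, plus a small saliva compartment
coupled to the salivary gland. Systemic organs are perfused in parallel
(arterial → organ → venous); the lung bridges the venous pool back to the
arterial pool. The state vector holds drug *amounts* (ng); one extra state
accumulates eliminated mass so the right-hand side sums to zero and total
mass is conserved identically.

Distribution is perfusion-limited (well-stirred): blood leaving an organ is
in equilibrium with its tissue at the tissue-to-plasma partition coefficient
K_organ, so

    dA_o/dt = Q_p,o (C_art − A_o/(V_o K_o)) − elimination_o,

with organ plasma flow `Q_p = Q_blood (1 − hematocrit)`. An optional
permeability-limited mode replaces the exchange conductance by the series
combination `(1/Q_p + 1/PS_p)⁻¹`, with the permeability–surface-area product
built from the organ-vascularization surface-area rule `SA = k·f_vas·V`.
It is off by default because no measured permeability exists for AT-RvD1.

## Partition coefficients

K_organ follows the composition-based rule

    K_organ = F_water + K_lipid·F_lipid + K_protein·F_protein·fu_plasma,

with the free fraction scaling only the protein term (the rule as printed; a
switch exposes the whole-sum alternative). `K_lipid = 10^LogP` (octanol/water,
LogP = 3.22) and `K_protein = (1/fu − 1)/F_protein_plasma` with
F_protein_plasma = 0.06, chosen so the plasma compartment's own protein
binding is self-consistent with the supplied fu. Both rules are
config-overridable; they are package conventions, since only the K_organ
equation itself is published.

Per-organ water/lipid/protein fractions and vascular fractions are package
defaults in the fixture JSONs — no organ compositions are published for
these references — and every such value is flagged in the fixtures'
`assumed_parameters` metadata, which propagates into run manifests.

`fu_plasma` for AT-RvD1 has never been measured. It is a **required** input
with no silent default; the shipped example configs use 0.05 (a typical
order of magnitude for an albumin-bound lipid mediator), always flagged as
assumed.

## Elimination

Two clearance modes:

* **calibrated_total** (default): a whole-body plasma clearance CL
  (ml/min/kg, referenced to venous plasma) split over liver, kidney and lung
  in proportion to blood flow. Each organ's intrinsic clearance is obtained
  by inverting the well-stirred extraction `CL_o = Q_p·CL_int/(Q_p+CL_int)`;
  because lung elimination happens before the arterial pool, the systemic
  shares are additionally scaled by the lung transmission factor
  `g = 1 − E_lung`. With this construction the venous-plasma AUC₀₋∞ after an
  IV bolus equals dose/CL *analytically*, for any partition-coefficient set.
  The lung is included among eliminating organs for two reasons: eicosanoid
  oxidoreductase (15-prostaglandin dehydrogenase), the enzyme that degrades
  resolvins, is classically pulmonary — the lung is the canonical
  single-pass inactivation site for circulating eicosanoids — and the
  reference human hepatic + renal plasma flows (57.4 L/hr) are smaller than
  the reported human total plasma clearance (14.02 ml/min/kg ≈ 67.6 L/hr),
  so no liver+kidney well-stirred split can deliver it.
* **enzymatic**: Michaelis–Menten degradation `ab·Vmax·Cu/(Km+Cu)` in every
  organ with positive EOR abundance, driven by the unbound outflow
  concentration. Vmax/Km values are user-supplied placeholders (the
  literature Km is cited but not printed); this mode exists for mechanistic
  studies and is not used by the calibrated study pipeline.

## Saliva

Saliva is a first-order equilibration compartment:
`dA_sal/dt = k_sal (k_saliva·C_gland,plasma·V_sal − A_sal)`, mass-exchanged
with the salivary gland. Defaults: `k_sal = 10 hr⁻¹` (a few-minute lag) and
`k_saliva = fu_plasma`, i.e. saliva tracks the *unbound* plasma
concentration, the standard expectation for passive salivary transfer of a
protein-bound lipophilic drug. This reproduces the qualitative observation
that salivary kinetics parallel plasma kinetics; it does not model secretion
flow or pH trapping.

## Dosing, integration, reporting

The IV bolus (`0.1 mg/kg × BW`) is placed in the venous pool at t = 0.
Integration uses `scipy.integrate.solve_ivp` (LSODA by default) with the
analytic Jacobian of the constant-coefficient linear system (rtol 1e-9,
atol = 1e-13 × dose), and reports concentrations on a fixed grid — by
default 0–24 hr in 0.05-hr (3-min) steps, the grid on which Tmax is
resolved. Venous concentrations are amounts over venous *plasma* volume;
organ concentrations are per total organ volume.

The t = 0 venous value (dose over venous plasma volume) is a pre-mixing
artifact: Cmax/Tmax are reported from the first strictly positive grid time
onward, earliest time winning ties. For AUC work the
`quadrature_grid` helper prepends a geometric sub-grid (default from 1e-5 hr)
that resolves the sub-minute mixing transient, whose area is otherwise
overestimated on a 3-min grid, and appends a coarse segment through the
terminal phase.

## Non-compartmental analysis

Linear-up/log-down trapezoid for AUC and AUMC, exponential tail
`C_last/ke` and `C_last·t_last/ke + C_last/ke²`, and the identities
t½ = ln2/ke, MRT = AUMC/AUC, CL = dose/AUC₀₋∞, Vd = CL/ke (these hold on
every result by construction). CL is reported in ml/min/kg and Vd in L/kg;
internal units are ml, hr, ng. Zero concentrations are excluded from log
fits; no below-quantification model is applied. `extrapolated_fraction` is
always reported so that heavy extrapolation (a 100-hr half-life estimated
from a 24-hr window) is visible rather than silent.

The terminal slope maximizes adjusted R² over trailing windows of the
positive post-Tmax points, near-ties (1e-4) resolved toward more points, and
only negative-slope windows qualify. One guard was added after the
conventional rule failed in testing: on densely sampled profiles an
unrestricted scan degenerates into 3-point noise windows whose R² is high by
chance — measured ke RMSE *rose* from 0.018 to 0.40 as sampling grew from 12
to 481 points at 10 % noise. Candidate windows must therefore cover at least
10 % of the post-Tmax points (never fewer than 3, so sparse designs keep the
standard rule exactly). With the guard, ke RMSE decreases monotonically with
sampling density and the median ke bias at CV 10 % is ≈ 0.05 %.

## Virtual populations

Mouse: body weight uniform on 12–30 g (the strain's reported range; a
truncated-Gaussian option exists), each weight mapped to a physiology by
allometric rescaling (volumes ∝ BW, flows ∝ BW^0.75) of the 27.5-g
reference. Human: age uniform on 20–80 y, exactly equal sex split, (age,
sex) mapped to weight through a shipped piecewise-linear table anchored so
the population mean is the 80.35-kg reference adult. Human per-kg clearance
is additionally scaled by a senescence factor (−0.5 %/year beyond 35,
floor 0.70), a deliberate design choice: per-kg dosing with per-kg
clearance makes AUC weight-invariant, so without an age effect the human
population would show essentially no PK variability, contrary to the
age-driven spread survey-based virtual populations exhibit. Mouse
variability remains weight-only; organ-level age ontogeny is not modelled
(a documented limitation). All sampling is seed-deterministic end to end.

## Sensitivity analysis

For parameter p and output y, each variation factor f yields
`S_f = (y(f·p)/y(p) − 1)/(f − 1)`; the reported sensitivity is the mean over
the factor set (default {0.1, 0.5, 2, 10} — a ten-fold change in both
directions — plus {0.9, 1.1}, whose mean approaches d ln y/d ln p). Outputs
are AUC₀₋∞ and total body clearance (dose/AUC of the perturbed run), per
compartment (venous plasma, saliva) and per dose (0.1/0.25/0.5 mg/kg), each
evaluated by a full simulation + NCA on the 0–24-hr window. Factors multiply
the parameter value itself (LogP 3.22 → 32.2 at f = 10 — physically
aggressive but exactly what the variation-factor definition prescribes).
Infeasible factors (hematocrit × 10, clearance beyond organ flow) are
recorded per result, not fatal. In the one-compartment reduction
S(CL → AUC) → −1 analytically, which the acceptance suite checks to 0.02.

Because calibrated-mode AUC₀₋∞ is structurally dose/CL, true
infinite-window AUC is insensitive to distribution parameters; on the
study's finite 0–24-hr window, however, lipophilicity governs how much AUC
lies beyond the window and therefore ranks among the top influences, with
fraction unbound dominating the saliva outputs. The screen is emitted as a
report; only the structural fu → saliva relationship is asserted.

## Synthetic data

Mono-/bi-exponential generators evaluate their closed forms exactly
(noiseless output is bit-reproducible); noise is multiplicative lognormal
with unit mean (σ² = ln(1+CV²)), so noisy profiles are unbiased on the
concentration scale. `recovery_suite` reports bias, median relative bias
and RMSE of the NCA estimators over seeded replicates. These profiles
emulate smooth single-subject curves on a regular grid; they contain no
assay quantification limit, censoring, sparse sampling or model
misspecification, so passing recovery tests demonstrates estimator
correctness, not robustness to real bioanalytical data. The
`one_compartment_inputs` reduction (single all-water organ, pools shrunk to
1e-5 of its volume, perfusion at 1e4 × CL so extraction bias is ~1e-4)
provides the closed-form oracle used throughout.

## Problem sizes and numerical choices

The shipped analyses use: the 0.05-hr reporting grid over 0–24 hr (481
points) for Tmax and population work; `quadrature_grid(2000 hr)` (~2,700
points) for mouse AUC₀₋∞, long enough that the slowest distribution mode
(adipose, with K ≈ 1.3e3 under the default compositions) has decayed and the
extrapolated fraction is a few percent; six half-lives for one-compartment
estimates; n = 100 per species in the study pipeline (n is a parameter);
200 replicates in recovery checks. Solver tolerances leave mass-balance
errors near 1e-15; the conservation gate is 1e-6.

## Known limitations

* Organ compositions, f_vas, blood-pool volumes and the non-printed organ
  set are assumptions (flagged in metadata); absolute tissue concentrations
  therefore carry that uncertainty, and published tissue Cmax values are not
  reproduced, only the clearance-anchored plasma identities.
* Perfusion-limited transport and flow-proportional clearance splitting are
  idealizations; no transporters, metabolites, ionization (pKa is carried
  but unused by the default rules), or blood-cell partitioning.
* Saliva coupling is phenomenological (no secretion-flow physiology).
* Human aging enters only through body weight and the clearance factor; no
  organ-level ontogeny, disease-state (Sjögren's) physiology, pregnancy or
  pediatrics.
* Single IV bolus only; no oral/topical absorption or multiple dosing.
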