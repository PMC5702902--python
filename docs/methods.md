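# Methods

This note documents the models implemented in hepaflux, the assumptions
behind them, the defaults and why they were chosen, and what the bundled
synthetic networks do and do not show about real data.

## Constraint-based kernel

The network is a list of metabolites (internal or external) and reactions
with signed stoichiometry, flux bounds and optional Boolean GPR rules.
External metabolites are unbalanced sources/sinks and never appear as rows
of the stoichiometric matrix S; exchange reactions are identified
structurally as reactions whose internal stoichiometry is one-sided
(all-negative = sink, all-positive = source).

FBA solves `max a·v  s.t.  S·v = 0, l ≤ v ≤ u` with HiGHS. Bounds are
closed intervals `l ≤ v ≤ u`: strict inequalities are not representable in
LP, and the closed form is the universal convention in constraint-based
modelling. Reversibility is encoded purely through the sign of the lower
bound; reactions are never split into forward/backward halves.

Numerical choices:

* balance/feasibility tolerance 1e-6 (model flux units) on `max|S·v|` and
  on bound feasibility of returned solutions;
* LP duality/optimality tolerances are the HiGHS defaults;
* essentiality `influence_threshold` defaults to 1e-6 relative — knockout
  objectives are reported to ~3 decimals in practice, and this threshold
  cleanly separates genuine influence from solver round-off;
* the knockout objective is normalised to wild type (`z_relative`), with
  infeasible knockouts recorded as `z_knockout = 0`; the scan refuses a
  wild type that is infeasible or has z ≤ 0, since the normalisation would
  be meaningless;
* IEEE −0.0 from the solver is normalised to 0.0;
* degenerate optima: `fba` returns one solver vertex. Uniqueness is the
  caller's concern; `flux_variability` (per-reaction min/max LP with
  `a·v ≥ fraction·z_max` added as a constraint) and `uniqueness_guard`
  report the width of each flux range at the optimum. Only the objective
  *value* is ever coupled to the ODE layers, because the value is unique
  even when the flux vector is not.

Flux-space sampling is hit-and-run on `{S·v = 0, l ≤ v ≤ u}`: a strictly
feasible start point is found by maximising a uniform slack LP, random
directions are drawn in the null space of S restricted to non-fixed
reactions, and a uniform point is taken on each feasible chord, with
thinning (every 5th point) and per-step re-projection onto the null-space
slice to suppress floating-point drift. The walk is exactly reproducible
for a fixed seed. No claim of a mixing rate is made; the tests check
feasibility invariants and a symmetry property, not distributional
accuracy.

## Model I/O

The tabular dialect (`id, formula, lower_bound, upper_bound, gpr` TSV) uses
formulas such as `2 A(c) + B(c) -> C(m)`; `<=>` marks reversibility, the
token grammar is `coefficient? name [ "(" compartment ")" ]`, and a
metabolite whose name ends in `xt` (or is named in an explicit externals
list) is external. Exchange reactions are written in the export direction
(internal → external); import is negative flux. A bounds CSV of
per-observation consumption/release magnitudes therefore reduces, under
`max_over_observations`, to `lb = −max(consumption), ub = +max(release)` —
the "no tissue exceeds the fastest cell-line flux" argument for using
cell-line panel maxima as physiological envelopes.

SBML L3-FBC files are read via libsbml: boundary-condition species become
external, FBC parameters give the bounds (missing bounds fall back to the
conventional effectively-unbounded defaults, (0, 1000) irreversible and
(−1000, 1000) reversible, with a logged warning), gene-product
associations are rendered to GPR strings using gene *labels* (the names
knockouts are phrased in), and the active objective is returned when
declared. SBML writing is out of scope.

## PBPK

A standard 13-compartment flow-limited adult (≈70 kg, cardiac output
390 L/h) with textbook volumes and regional flows; the gut drains through
the portal vein into the liver, so liver outflow carries hepatic-artery
plus portal flow. Amounts (mg) are states; tissue outflow blood
concentration is `A/(V·Kp/BP)`. Dosing supports iv bolus (state impulse),
zero-order infusion and oral first-order absorption into the gut via a
depot. Integration is LSODA with rtol 1e-8/atol 1e-10, split at dose
events and coupling-grid boundaries; piecewise-constant
(cyp3a4_scale, gsh_scale) series are honoured exactly at grid boundaries.

The liver phase-I rate is `cyp3a4_scale · CL_phaseI · Cu`, with Cu the
unbound concentration in liver outflow blood (`fup·C_out/BP`, well-stirred
convention). The GSH conjugation rate is
`SF · CLmet · (Atox/Vli) · fup`: the printed form of this rate law is
typographically ambiguous about the placement of fup, and the adopted
reading — clearance × unbound concentration, with Atox/Vli the *total*
liver concentration of the metabolite — is the standard well-stirred form;
the alternative `Atox/(Vli·fup)` was rejected as pharmacologically
non-standard. This remains a documented open choice, as does the use of
total rather than unbound liver concentration in the feedforward
inhibition link.

The metabolite is tracked in parent-mass equivalents (1:1 conversion), so
`dose = body + metabolite + cumulative eliminated` holds to integrator
precision at all times; the test suite enforces 0.5% and observes ~1e-14.
Example-drug parameters (fup 0.3, CL_phaseI 30 L/h, CLmet 12 L/h, renal CL
6 L/h, generic Kp ≈ 0.6–2) are deliberately generic placeholders within
physiological ranges; the package models the *approach*, not a specific
compound, and all values are config-overridable.

## Gene regulation

States: total GR, total PXR and CYP3A4 (nM). Ligand binding is rapid
equilibrium, so activated pools are `total × L/(L+Kd)` with the affinity
ladder Kd(MR) = 1 nM, Kd(GR) = 10 nM, Kd(PXR) = 10 μM. MR is carried for
occupancy readouts only — no downstream edge is wired to it. The ODEs
implement: GR synthesis repressed by activated GR
(`1/(1 + GRa/K_fb)`), PXR synthesis induced by activated GR (saturating,
max 4-fold), CYP3A4 synthesis driven by `PXRa + 0.05·GRa` through a
saturating function, and first-order degradation of all three pools
(receptors t½ ≈ 3.5 h; CYP3A4 t½ ≈ 11.6 h, hour-scale gene regulation).

The published source model for this pathway is not reproduced
equation-for-equation (its full parameterisation is not available in the
open literature in reusable form); instead the minimal motif set above is
implemented with synthesis constants *back-calculated* from the
degradation rates so that the homeostatic state (baseline free cortisol
30 nM, CYP3A4 = 705 nM) is an exact fixed point. Consequences that are
guaranteed by construction rather than fitted: homeostatic simulations
hold CYP3A4 at its reference indefinitely (drug metabolism untouched), and
a return of cortisol to baseline relaxes CYP3A4 back to 705 nM. Chronic
stress is modelled as a sustained 5× baseline (optionally with
exponentially decaying boluses) and yields ≈ +12% CYP3A4 at 96 h with the
defaults — the direction and order of magnitude, not the exact published
trajectory, are the claim. Free (not total plasma) cortisol is used
because receptor binding sees the free fraction; cortisol is an exogenous
forcing function, not a PBPK species.

## Coupling

The quasi-steady-state loop treats intracellular metabolism as
instantaneously at steady state within each Δt (default 5 min = 0.0833 h,
short against PK and gene-regulation timescales; halving it changes the
24-h metabolite Cmax by ≪1%). Within a step the order is fixed:
feedforward bounds → FBA → feedback scaling → ODE advance, with the GRN
advanced in the same integrator call as the PBPK (both are the "dynamic
layer").

Feedforward links scale the *wild-type* bounds each step (never the
previous step's bounds — stateless scaling cannot compound), using the
competitive-inhibition activity `1/(1 + I/(2·Ki))`, which is the
normalised rate of a Michaelis–Menten reaction at S = Km under competitive
inhibition; concentrations are converted mg/L → mM via the example drug's
molar mass (151.2 g/mol by default). The default Ki of 50 mM means
inhibition only bites at toxicological (mM) concentrations; tests that
exercise the feedforward path therefore use smaller Ki values or tighter
wild-type bounds, which probes the mechanism rather than re-tuning the
scenario. Feedback maps z through a `ScalingTable`: proportional mode
(`SF = z/z_ref`, z_ref the unperturbed wild-type optimum) is the default;
monotone lookup tables (step or piecewise-linear) can be configured when a
calibrated SF(GSHmax) table is available. In `feedback_only` mode bounds
never change, so the LP is evaluated once and reused.

## Synthetic fixtures — what they show and what they do not

All fixtures are generated in code, deterministically.

* `fig1_like` reproduces the *stated properties* of the classic FBA
  teaching network — exactly three alternative optimal vertices at z_max,
  exactly one essential reaction (the import R1), one reversible reaction,
  all bounds of magnitude 1 — with a stoichiometry of this package's own
  construction. It is not a redrawing of any published figure.
* `make_mini_liver` is an ~18-reaction synthetic GSH-synthesis network
  (γ-glutamyl pathway fed by a serine/folate one-carbon cycle with a
  capacity-limited transformylase shunt and redundant amino-acid supplies)
  designed so that one designated step (MTHFD-like) is essential, one
  (FTHLDH-like) is partially limiting (z_rel = 0.3), and the remaining
  knockouts are buffered. Its ground truth is frozen in tests and verified
  by an independent brute-force vertex-enumeration oracle and by cobrapy.
* `make_random_network` builds feasible-by-construction networks (a
  spanning path plus random shortcuts) for property tests; bounds tables
  come with known column-wise maxima.

Passing tests on these fixtures demonstrates the *mechanisms* (LP
correctness against enumeration, GPR logic, scan/variability/sampling
invariants, coupling directions) at toy scale. They do not demonstrate
genome-scale numerical behaviour, realistic flux magnitudes, or the
specific essentiality spectrum of a curated liver reconstruction; for
that, a user-supplied SBML model is loaded through the same interfaces
(`tests/data/external/` paths in the test suite, `pipelines.
gsh_essentiality_screen` in code).

## Problem sizes used in the shipped analyses

The default test-and-example workload uses toy networks (≤ 18 reactions),
24–96 h simulations, coupling steps of 2.5–30 min, and 10²–2·10³ flux
samples. These sizes were chosen so every mechanism is exercised and every
invariant checked while the whole suite remains quick to run; all of them
scale up transparently (the LP, FVA and scan costs grow with network size,
the loop cost linearly with duration/Δt).

## Known limitations

* Perfusion-limited PBPK only: no permeability-limited tissues, no
  mechanistic gut-transit absorption model, no enterohepatic
  recirculation, no population variability.
* The GRN is a motif-level stand-in with designed (not fitted) constants;
  quantitative induction trajectories should not be read off it.
* Drug-as-PXR-ligand interactions (the drug inducing its own metabolism)
  are an extension point, not implemented.
* Flux-level feedback (coupling individual solver fluxes into PBPK rates)
  is deliberately out of scope; only objective values are coupled.
* No gap filling, thermodynamic annotation, elementary flux modes or
  SBML writing.
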