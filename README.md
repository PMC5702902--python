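# hepaflux

Multiscale simulation of drug metabolism in which a constraint-based
genome-scale metabolic network (GSMN) acts as the mechanistic intracellular
liver compartment of a whole-body physiologically based pharmacokinetic
(PBPK) model, with an ODE model of cortisol/nuclear-receptor gene
regulation setting the CYP3A4-driven phase-I metabolism rate.

The package is aimed at quantitative systems pharmacology and systems
toxicology modellers who want to connect molecular-level liver metabolism
(thousands of enzyme-associated reactions, gene–protein–reaction rules,
genetic polymorphism) to whole-body pharmacokinetic readouts such as the
peak concentration of a reactive, glutathione-detoxified metabolite.

## The models

**Flux balance analysis (FBA).** A metabolic network of N reactions over M
internal metabolites is encoded by its stoichiometric matrix S. At steady
state the flux vector v satisfies S·v = 0, and a metabolic capability is
quantified by the linear program

```
maximise  z = Σᵢ aᵢ vᵢ   subject to   S·v = 0,   l ≤ v ≤ u
```

solved here with HiGHS (`scipy.optimize.linprog`). External metabolites are
unbalanced sources/sinks and are excluded from the rows of S; bounds encode
reversibility, measured exchange fluxes and perturbations — setting a
reaction's bounds to (0, 0) removes it, which is the basis of the
essentiality screen. z is guaranteed globally maximal, but the optimal flux
vector need not be unique; `flux_variability` diagnoses alternative optima.
Gene knockouts act through Boolean gene–protein–reaction (GPR) rules
(AND = subunits, OR = isoenzymes). Hit-and-run sampling of the flux
polytope is provided for objective-free exploration.

**PBPK.** A 13-compartment flow-limited human (lung, arterial/venous
blood, liver, kidney, gut, muscle, adipose, skin, brain, heart, bone,
rest; gut drains portally into the liver) tracks a parent drug and its
toxic metabolite in mg. The liver converts parent to metabolite at rate
`cyp3a4_scale · CL_phaseI · Cu_liver`, and clears the metabolite by
glutathione conjugation at

```
GSH conjugation rate = SF(GSHmax) · CLmet · (Atox / Vli) · fup
```

where SF is a scaling factor proportional to the maximal GSH production
computed by the liver network. Drug parameters are example values within
physiological ranges.

**Gene regulation.** Cortisol occupies MR, GR and PXR with Kd values of
1 nM, 10 nM and 10 μM (occupancy L/(L+Kd)); activated GR represses GR
synthesis and induces PXR, activated PXR (mainly) drives CYP3A4 synthesis.
Synthesis rates are back-calculated so the homeostatic state holds liver
CYP3A4 exactly at 705 nM. The enzyme→metabolism coupling is linear:
`scale = CYP3A4 / 705 nM`, so a 10% rise in enzyme gives a 10% faster
phase-I metabolism.

**Quasi-steady-state coupling.** Per time-step (default 5 min): (1) set
network bounds from current tissue concentrations, e.g. competitive
inhibition at S = Km, `activity = 1 / (1 + I/(2·Ki))`, scaling wild-type
bounds; (2) solve the FBA; (3) map the objective value through a scaling
table to PBPK parameters (only the unique objective *value* is fed back,
never solver-chosen fluxes); (4) advance the PBPK+GRN ODEs one step.
`feedforward_only` and `feedback_only` modes skip step 3 or step 1.

## Worked example

`examples/05_multiscale_simulation.py` couples all three layers for an
oral 500 mg dose over 24 h and prints:

```
wild-type maximal GSH production z_ref = 1.000

wild type      : liver metabolite Cmax =  4.556 mg/L  (final z = 1.000, SF = 1.000, CYP3A4 scale = 1.000)
MTHFD knockout : liver metabolite Cmax = 10.904 mg/L  (final z = 0.000, SF = 0.000, CYP3A4 scale = 1.000)
chronic stress : liver metabolite Cmax =  4.627 mg/L  (final z = 1.000, SF = 1.000, CYP3A4 scale = 1.092)
```

Knocking out the essential MTHFD step abolishes GSH production (z = 0, so
SF = 0): conjugation stops and the toxic-metabolite peak more than
doubles. Chronic stress leaves the network intact but induces CYP3A4
(scale 1.09 after 24 h), speeding metabolite formation and raising the
peak. The other examples cover FBA with alternative optima (`01`), the
essentiality screen (`02`), plain PBPK dosing (`03`) and the cortisol/GRN
layer alone (`04`).

A thin CLI mirrors the library: `hepaflux fba|fva|essentiality|sample|
fixture|simulate` (see `hepaflux --help`); `simulate` takes a YAML config
and writes a trajectory CSV plus a provenance record (config hash,
version, seed).

Users with a genome-scale liver reconstruction in SBML L3-FBC (e.g.
HepatoNet1) can load it with `hepaflux.read_sbml_fbc`, constrain exchanges
with a consumption/release bounds CSV
(`hepaflux.pipelines.gsh_essentiality_screen`), and run the same analyses
at genome scale; nothing is downloaded by the package itself.

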