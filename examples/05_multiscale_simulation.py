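"""Full multiscale run: PBPK + liver network + CYP3A4 regulation.

Couples the three layers with the quasi-steady-state loop (5-minute steps):
the liver metabolite concentration competitively inhibits the FTHLDH step
of the folate cycle (feedforward), FBA recomputes maximal GSH production,
the proportional scaling factor SF(GSHmax) sets the conjugation capacity
(feedback), and the PBPK/GRN ODEs advance one step. Three scenarios show
the perturbation logic: wild type, a metabolic knockout that abolishes GSH
production, and chronic stress that induces CYP3A4.
"""

from hepaflux import (
    CompetitiveInhibition,
    CouplingConfig,
    Dose,
    FeedbackLink,
    FeedforwardLink,
    GRNParameters,
    MultiscaleModel,
    PBPKParameters,
    ScalingTable,
    cortisol_schedule,
    fba,
    knockout_reactions,
)
from hepaflux.fixtures import make_mini_liver

net, objective = make_mini_liver()
z_wt = fba(net, objective).z
grn = GRNParameters()
pbpk = PBPKParameters(doses=[Dose("oral", 500.0, ka_per_h=1.0)])
feedforward = [FeedforwardLink(reaction_id="FTHLDH",
                               transform=CompetitiveInhibition(ki_mm=50.0))]
feedback = FeedbackLink(table=ScalingTable(mode="proportional", z_ref=z_wt))
config = CouplingConfig(mode="full", dt_h=5.0 / 60.0)

scenarios = {
    "wild type": dict(network=net),
    "MTHFD knockout": dict(network=knockout_reactions(net, ["MTHFD"])),
    "chronic stress": dict(network=net,
                           cortisol=cortisol_schedule("chronic_stress", grn)),
}
print(f"wild-type maximal GSH production z_ref = {z_wt:.3f}\n")
for name, kw in scenarios.items():
    model = MultiscaleModel(objective=objective, pbpk_params=pbpk,
                            grn_params=grn, feedforward=feedforward,
                            feedback=feedback, config=config, **kw)
    traj = model.simulate(24.0)
    print(f"{name:15s}: liver metabolite Cmax = {traj.liver_metabolite_cmax():6.3f} mg/L"
          f"  (final z = {traj.z[-1]:.3f}, SF = {traj.sf[-1]:.3f},"
          f" CYP3A4 scale = {traj.cyp_scale[-1]:.3f})")
print("\nabolishing GSH production (SF = 0) or inducing CYP3A4 under stress "
      "both raise the toxic-metabolite peak above the wild-type run.")
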