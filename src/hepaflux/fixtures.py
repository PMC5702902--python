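"""Deterministic generators of toy metabolic networks and bounds tables.

These make every analysis in the package testable and demonstrable without
downloading a genome-scale reconstruction. Two of them carry designed-in
ground truth:

* :func:`make_fig1_like` — a small network with four external metabolites,
  one reversible reaction, all flux bounds of magnitude 1, exactly three
  alternative optimal flux distributions at the maximal objective value and
  exactly one essential reaction (the import R1). It reproduces these
  *stated properties* of the classic FBA textbook example; the exact
  stoichiometry is this package's own construction, not a redrawing of any
  published figure.

* :func:`make_mini_liver` — an ~18-reaction glutathione (GSH) synthesis
  network with a folate/serine one-carbon cycle, built so that a designated
  dehydrogenase ("FTHLDH-like") knockout only partially reduces maximal GSH
  production while a designated cyclohydrolase-branch reaction
  ("MTHFD-like") is strictly essential. It is a synthetic stand-in for a
  liver genome-scale model, shaped after the qualitative structure of a GSH
  essentiality screen.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .network import Metabolite, MetabolicNetwork, Objective, Reaction

__all__ = [
    "make_linear_chain",
    "make_parallel_paths",
    "make_fig1_like",
    "make_mini_liver",
    "make_random_network",
    "make_bounds_table",
    "FIXTURES",
]


def _met(mid: str, external: bool = False) -> Metabolite:
    # fixture ids carry no compartment tag so that tabular round-trips are
    # the identity (the writer emits "name(comp)" tokens)
    return Metabolite(id=mid, name=mid, compartment="", is_external=external)


def make_linear_chain(n: int = 3, bound: float = 1.0) -> Tuple[MetabolicNetwork, Objective]:
    """Sxt -> A1 -> ... -> A(n-1) -> Pxt; every reaction is essential."""
    if n < 2:
        raise ValueError("chain needs at least 2 reactions")
    mets = [_met("Sxt", external=True), _met("Pxt", external=True)]
    mets += [_met(f"A{i}") for i in range(1, n)]
    rxns = []
    names = ["Sxt"] + [f"A{i}" for i in range(1, n)] + ["Pxt"]
    for i in range(n):
        rxns.append(
            Reaction(
                id=f"R{i + 1}",
                stoichiometry={names[i]: -1.0, names[i + 1]: 1.0},
                lower_bound=0.0,
                upper_bound=bound,
            )
        )
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    return net, Objective({f"R{n}": 1.0}, name="export_P")


def make_parallel_paths(bound: float = 1.0) -> Tuple[MetabolicNetwork, Objective]:
    """Two equivalent A->B routes; no single internal knockout changes z."""
    mets = [_met("Sxt", external=True), _met("Pxt", external=True), _met("A"), _met("B")]
    rxns = [
        Reaction(id="Rin", stoichiometry={"Sxt": -1.0, "A": 1.0}, upper_bound=bound),
        Reaction(id="Rpath1", stoichiometry={"A": -1.0, "B": 1.0}, upper_bound=bound),
        Reaction(id="Rpath2", stoichiometry={"A": -1.0, "B": 1.0}, upper_bound=bound),
        Reaction(id="Rout", stoichiometry={"B": -1.0, "Pxt": 1.0}, upper_bound=bound),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    return net, Objective({"Rout": 1.0}, name="export_P")


def make_fig1_like() -> Tuple[MetabolicNetwork, Objective]:
    """Toy network: three alternative optima, one essential import.

    Metabolite A (from the sole import R1) can reach the product sink Xxt by
    three routes: directly (R4), via B (R5, R6) or via C (R7 reversible,
    R8). All bounds have magnitude 1. The objective is total production of
    X. z_max = 1 with exactly three optimal vertices — one per route — and
    R1 is the only essential reaction.
    """
    mets = [
        _met("M1xt", external=True),
        _met("M2xt", external=True),
        _met("M4xt", external=True),
        _met("Xxt", external=True),
        _met("A"),
        _met("B"),
        _met("C"),
    ]
    rxns = [
        Reaction(id="R1", stoichiometry={"M1xt": -1.0, "A": 1.0}, upper_bound=1.0),
        Reaction(id="R4", stoichiometry={"A": -1.0, "Xxt": 1.0}, upper_bound=1.0),
        Reaction(id="R5", stoichiometry={"A": -1.0, "M2xt": -1.0, "B": 1.0}, upper_bound=1.0),
        Reaction(id="R6", stoichiometry={"B": -1.0, "Xxt": 1.0}, upper_bound=1.0),
        Reaction(
            id="R7",
            stoichiometry={"A": -1.0, "C": 1.0, "M4xt": 1.0},
            lower_bound=-1.0,
            upper_bound=1.0,
        ),
        Reaction(id="R8", stoichiometry={"C": -1.0, "Xxt": 1.0}, upper_bound=1.0),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    obj = Objective({"R4": 1.0, "R6": 1.0, "R8": 1.0}, name="production_of_X")
    return net, obj


def make_mini_liver() -> Tuple[MetabolicNetwork, Objective]:
    """Mini liver GSH network with designed partial and essential knockouts.

    Pathway sketch (names ending in ``xt`` are external; everything else
    is cytosolic):

    * GSH synthesis: Glu + Cys → γGluCys; γGluCys + Gly → GSH → export
      (the export flux is the objective, maximal GSH production).
    * Glycine comes exclusively from serine via SHMT, which consumes THF and
      produces 5,10-methylene-THF; sustaining it requires THF regeneration
      through the one-carbon cycle: MTHFD (methylene→methenyl, the
      *essential* step), MTHFC (methenyl→10-formyl) and then either FTHLDH
      (10-formyl-THF dehydrogenase, the *partial* step) or a
      capacity-limited transformylase shunt (AICART, fed by a small AICAR
      import).
    * Serine: direct import plus a capacity-limited 3PG branch; glutamate:
      direct import plus a proline route — both give non-influential
      redundant knockouts.
    * NADP+/NADPH is a conserved internal pool closed by a lumped oxidase.

    Designed ground truth at wild-type z = 1 (GSH export):
    FTHLDH knockout → z = 0.3; EX_Ser knockout → z = 0.5; MTHFD, MTHFC,
    SHMT, EX_Cys, GCL, GSS, EX_GSH, NADPH_ox knockouts → z = 0; all other
    single knockouts leave z = 1.
    """
    ext = ["Gluxt", "Cysxt", "Serxt", "GSHxt", "AICARxt", "FAICARxt",
           "Proxt", "3PGxt", "H2Oxt", "CO2xt"]
    internal = ["Glu", "Cys", "Ser", "Gly", "gGluCys", "GSH", "THF",
                "CH2THF", "CHTHF", "CHOTHF", "AICAR", "FAICAR", "Pro",
                "3PG", "NADP", "NADPH"]
    mets = [_met(m, external=True) for m in ext] + [_met(m) for m in internal]
    R = Reaction
    rxns = [
        # amino-acid supply
        R(id="EX_Glu", stoichiometry={"Gluxt": -1.0, "Glu": 1.0}, upper_bound=1.0),
        R(id="EX_Cys", stoichiometry={"Cysxt": -1.0, "Cys": 1.0}, upper_bound=1.0,
          gpr="slc7a11"),
        R(id="EX_Ser", stoichiometry={"Serxt": -1.0, "Ser": 1.0}, upper_bound=1.0),
        R(id="EX_Pro", stoichiometry={"Proxt": -1.0, "Pro": 1.0}, upper_bound=1.0),
        R(id="PRO2GLU", stoichiometry={"Pro": -1.0, "Glu": 1.0}, upper_bound=10.0,
          gpr="prodh AND aldh4a1"),
        R(id="EX_3PG", stoichiometry={"3PGxt": -1.0, "3PG": 1.0}, upper_bound=0.5),
        R(id="SERSYN", stoichiometry={"3PG": -1.0, "Ser": 1.0}, upper_bound=10.0,
          gpr="phgdh AND psat1 AND psph"),
        # GSH synthesis and export
        R(id="GCL", stoichiometry={"Glu": -1.0, "Cys": -1.0, "gGluCys": 1.0},
          upper_bound=10.0, gpr="gclc AND gclm"),
        R(id="GSS", stoichiometry={"gGluCys": -1.0, "Gly": -1.0, "GSH": 1.0},
          upper_bound=10.0, gpr="gss"),
        R(id="EX_GSH", stoichiometry={"GSH": -1.0, "GSHxt": 1.0}, upper_bound=10.0),
        # serine → glycine via SHMT, coupled to the folate cycle
        R(id="SHMT", stoichiometry={"Ser": -1.0, "THF": -1.0, "Gly": 1.0,
                                    "CH2THF": 1.0, "H2Oxt": 1.0},
          lower_bound=-10.0, upper_bound=10.0, gpr="shmt1 OR shmt2"),
        R(id="MTHFD", stoichiometry={"CH2THF": -1.0, "NADP": -1.0,
                                     "CHTHF": 1.0, "NADPH": 1.0},
          upper_bound=10.0, gpr="mthfd1"),
        R(id="MTHFC", stoichiometry={"CHTHF": -1.0, "H2Oxt": -1.0, "CHOTHF": 1.0},
          lower_bound=-10.0, upper_bound=10.0, gpr="mthfd1"),
        R(id="FTHLDH", stoichiometry={"CHOTHF": -1.0, "NADP": -1.0, "THF": 1.0,
                                      "CO2xt": 1.0, "NADPH": 1.0},
          upper_bound=10.0, gpr="aldh1l1"),
        # capacity-limited alternative THF regeneration
        R(id="AICART", stoichiometry={"CHOTHF": -1.0, "AICAR": -1.0,
                                      "THF": 1.0, "FAICAR": 1.0},
          upper_bound=10.0, gpr="atic"),
        R(id="EX_AICAR", stoichiometry={"AICARxt": -1.0, "AICAR": 1.0},
          upper_bound=0.3),
        R(id="EX_FAICAR", stoichiometry={"FAICAR": -1.0, "FAICARxt": 1.0},
          upper_bound=10.0),
        # conserved NADP pool closed by a lumped NADPH oxidation
        R(id="NADPH_ox", stoichiometry={"NADPH": -1.0, "NADP": 1.0},
          upper_bound=100.0),
    ]
    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    return net, Objective({"EX_GSH": 1.0}, name="GSH_production")


#: designed ground truth of make_mini_liver (z_relative per influential knockout)
MINI_LIVER_ESSENTIAL = frozenset(
    {"EX_Cys", "GCL", "GSS", "EX_GSH", "SHMT", "MTHFD", "MTHFC", "NADPH_ox"}
)
MINI_LIVER_PARTIAL: Dict[str, float] = {"FTHLDH": 0.3, "EX_Ser": 0.5}


def make_random_network(
    n_reactions: int, seed: int, bound: float = 1.0
) -> Tuple[MetabolicNetwork, Objective]:
    """A feasible-by-construction random network.

    A spanning linear path Sxt → A1 → … → Pxt guarantees a nonzero optimum;
    random shortcut reactions between path metabolites add redundancy and
    alternative optima. Deterministic for a fixed seed.
    """
    if n_reactions < 2:
        raise ValueError("need at least 2 reactions")
    rng = np.random.default_rng(seed)
    n_path = max(2, n_reactions - rng.integers(0, max(1, n_reactions - 2), endpoint=True))
    net, obj = make_linear_chain(int(n_path), bound=bound)
    mets = list(net.metabolites)
    rxns = [r.copy() for r in net.reactions]
    names = ["Sxt"] + [f"A{i}" for i in range(1, int(n_path))] + ["Pxt"]
    k = 0
    while len(rxns) < n_reactions:
        i, j = sorted(rng.choice(len(names), size=2, replace=False))
        if i == j:
            continue
        k += 1
        reversible = bool(rng.random() < 0.3)
        rxns.append(
            Reaction(
                id=f"Rs{k}",
                stoichiometry={names[int(i)]: -1.0, names[int(j)]: 1.0},
                lower_bound=-bound if reversible else 0.0,
                upper_bound=bound,
            )
        )
    return MetabolicNetwork(metabolites=mets, reactions=rxns), obj


def make_bounds_table(n_metabolites: int, n_observations: int, seed: int):
    """Synthetic per-observation consumption/release flux table.

    Returns a pandas DataFrame with one row per exchange reaction id and
    paired ``consumption_k`` / ``release_k`` columns (all magnitudes, ≥ 0),
    mimicking a cell-line flux screen whose column-wise maxima become
    exchange bounds.
    """
    import pandas as pd

    if n_metabolites < 1 or n_observations < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    data = {"reaction_id": [f"EX_met{i}" for i in range(n_metabolites)]}
    for k in range(n_observations):
        data[f"consumption_{k}"] = np.round(rng.uniform(0, 5, n_metabolites), 3)
        data[f"release_{k}"] = np.round(rng.uniform(0, 5, n_metabolites), 3)
    return pd.DataFrame(data)


FIXTURES = {
    "linear_chain": make_linear_chain,
    "parallel_paths": make_parallel_paths,
    "fig1_like": make_fig1_like,
    "mini_liver": make_mini_liver,
}
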