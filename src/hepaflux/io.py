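"""Read/write metabolic models and exchange-bounds tables.

Two model formats are supported:

* A plain tabular TSV dialect with one reaction per row
  (``id``, ``formula``, ``lower_bound``, ``upper_bound``, ``gpr``), where a
  formula looks like ``2 A(c) + B(c) -> C(m)`` (``<=>`` marks a reversible
  reaction). A metabolite token ending in ``xt``, or named in an explicit
  externals list, is an unbalanced external species.
* SBML Level 3 with the FBC package (the distribution format of published
  genome-scale reconstructions such as HepatoNet1/Recon2), read via libsbml.

Sign convention for exchanges: reactions are written in the export
direction (internal → external), so consumption (import) is a *negative*
flux. A bounds table reporting per-observation consumption/release flux
magnitudes therefore reduces to ``lb = -max(consumption)``,
``ub = +max(release)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

import pandas as pd

from .network import Metabolite, MetabolicNetwork, Objective, Reaction

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFormatError",
    "BoundsTable",
    "read_tabular",
    "write_tabular",
    "read_sbml_fbc",
    "read_bounds_csv",
    "load_model",
]

TABULAR_COLUMNS = ["id", "formula", "lower_bound", "upper_bound", "gpr"]

_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?([^\s()]+)(?:\(([^)]*)\))?$")
_ARROWS = {"<=>": True, "<->": True, "->": False, "-->": False}


class ModelFormatError(ValueError):
    """A model file that cannot be parsed; message carries the location."""


def _parse_side(side: str, lineno: int) -> Dict[Tuple[str, str], float]:
    out: Dict[Tuple[str, str], float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ModelFormatError(f"line {lineno}: empty term in formula")
        m = _TERM.match(term)
        if m is None:
            raise ModelFormatError(f"line {lineno}: cannot parse term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        name, comp = m.group(2), m.group(3) or ""
        key = (name, comp)
        out[key] = out.get(key, 0.0) + coef
    return out


def _parse_formula(formula: str, lineno: int):
    arrow = None
    for a in ("<=>", "<->", "-->", "->"):
        if a in formula:
            arrow = a
            break
    if arrow is None:
        raise ModelFormatError(f"line {lineno}: no reaction arrow in {formula!r}")
    lhs, rhs = formula.split(arrow, 1)
    reversible = _ARROWS[arrow]
    stoich: Dict[Tuple[str, str], float] = {}
    for key, coef in _parse_side(lhs, lineno).items():
        stoich[key] = stoich.get(key, 0.0) - coef
    for key, coef in _parse_side(rhs, lineno).items():
        stoich[key] = stoich.get(key, 0.0) + coef
    return stoich, reversible


def _met_id(name: str, comp: str) -> str:
    return f"{name}({comp})" if comp else name


def read_tabular(path, externals: Iterable[str] = ()) -> MetabolicNetwork:
    """Read the tabular TSV reaction dialect into a network.

    ``externals`` lists extra metabolite names (without compartment suffix)
    to treat as unbalanced, in addition to the ``…xt`` naming convention.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TABULAR_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ModelFormatError(f"{path}: missing columns {missing}")
    externals = set(externals)
    mets: Dict[str, Metabolite] = {}
    rxns = []
    seen = set()
    for k, row in df.iterrows():
        lineno = k + 2  # header is line 1
        rid = row["id"].strip()
        if not rid:
            raise ModelFormatError(f"line {lineno}: empty reaction id")
        if rid in seen:
            raise ModelFormatError(f"line {lineno}: duplicate reaction id {rid!r}")
        seen.add(rid)
        stoich_keys, reversible = _parse_formula(row["formula"], lineno)
        stoich = {}
        for (name, comp), coef in stoich_keys.items():
            mid = _met_id(name, comp)
            is_ext = name.endswith("xt") or name in externals
            if mid not in mets:
                mets[mid] = Metabolite(id=mid, name=name, compartment=comp,
                                       is_external=is_ext)
            stoich[mid] = coef
        try:
            lo = float(row["lower_bound"])
            hi = float(row["upper_bound"])
        except ValueError as exc:
            raise ModelFormatError(f"line {lineno}: non-numeric bound ({exc})") from None
        if not reversible and lo < 0:
            raise ModelFormatError(
                f"line {lineno}: irreversible reaction {rid!r} has negative lower bound"
            )
        rxns.append(
            Reaction(id=rid, stoichiometry=stoich, lower_bound=lo, upper_bound=hi,
                     gpr=str(row.get("gpr", "")).strip())
        )
    net = MetabolicNetwork(metabolites=list(mets.values()), reactions=rxns)
    logger.info("read %d reactions / %d metabolites from %s",
                len(rxns), len(mets), path)
    return net


def _format_formula(network: MetabolicNetwork, rxn: Reaction) -> str:
    subs, prods = [], []
    for mid, coef in rxn.stoichiometry.items():
        met = network.metabolite(mid)
        token = f"{met.name}({met.compartment})" if met.compartment else met.name
        mag = abs(coef)
        text = token if mag == 1 else f"{mag:g} {token}"
        (subs if coef < 0 else prods).append(text)
    arrow = "<=>" if rxn.reversible else "->"
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


def write_tabular(network: MetabolicNetwork, path) -> None:
    rows = [
        {
            "id": r.id,
            "formula": _format_formula(network, r),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gpr": r.gpr,
        }
        for r in network.reactions
    ]
    pd.DataFrame(rows, columns=TABULAR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML L3 + FBC
# ---------------------------------------------------------------------------

_DEFAULT_IRREV = (0.0, 1000.0)
_DEFAULT_REV = (-1000.0, 1000.0)


def _gpr_from_association(assoc, gene_names: Dict[str, str]) -> str:
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return gene_names.get(gid, gid)
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_gpr_from_association(assoc.getAssociation(i), gene_names)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " AND ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_gpr_from_association(assoc.getAssociation(i), gene_names)
                 for i in range(assoc.getNumAssociations())]
        return "(" + " OR ".join(parts) + ")"
    raise ModelFormatError(f"unsupported GPR association node: {assoc}")


def read_sbml_fbc(path) -> Tuple[MetabolicNetwork, Optional[Objective]]:
    """Read an SBML Level-3 FBC model.

    Returns the network and the model's active objective (or ``None`` if
    the file declares no objective, in which case the caller supplies one).
    Species with ``boundaryCondition=true`` become external metabolites.
    Reactions without FBC bound parameters get the conventional
    "effectively unbounded" defaults with a logged warning.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path}: SBML error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ModelFormatError(f"{path}: file contains no model")
    fbc = model.getPlugin("fbc")

    # gene products are referenced by id; expose them by their label (gene
    # name) when one is declared, which is what knockouts are phrased in
    gene_names: Dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    mets = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment(),
                is_external=bool(sp.getBoundaryCondition()),
            )
        )

    def _bound_value(rxn_fbc, getter, default, rid, which):
        if rxn_fbc is not None:
            pid = getter()
            if pid:
                param = model.getParameter(pid)
                if param is not None:
                    return param.getValue()
        logger.warning("reaction %s: missing FBC %s bound; default %s used",
                       rid, which, default)
        return default

    rxns = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rx_fbc = rx.getPlugin("fbc")
        defaults = _DEFAULT_REV if rx.getReversible() else _DEFAULT_IRREV
        lo = _bound_value(rx_fbc, rx_fbc.getLowerFluxBound if rx_fbc else (lambda: ""),
                          defaults[0], rx.getId(), "lower")
        hi = _bound_value(rx_fbc, rx_fbc.getUpperFluxBound if rx_fbc else (lambda: ""),
                          defaults[1], rx.getId(), "upper")
        gpr = ""
        if rx_fbc is not None:
            gpa = rx_fbc.getGeneProductAssociation()
            if gpa is not None:
                gpr = _gpr_from_association(gpa.getAssociation(), gene_names)
        rxns.append(Reaction(id=rx.getId(), stoichiometry=stoich,
                             lower_bound=lo, upper_bound=hi, gpr=gpr))

    objective = None
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        coeffs = {}
        for j in range(active.getNumFluxObjectives()):
            fo = active.getFluxObjective(j)
            coeffs[fo.getReaction()] = fo.getCoefficient()
        if active.getType() == "minimize":
            coeffs = {k: -c for k, c in coeffs.items()}
        if coeffs:
            objective = Objective(coeffs, name=active.getId() or "objective")

    net = MetabolicNetwork(metabolites=mets, reactions=rxns)
    logger.info("read %d reactions / %d metabolites from %s",
                len(rxns), len(mets), path)
    return net, objective


def load_model(path, externals: Iterable[str] = ()):
    """Dispatch on extension: .xml/.sbml → SBML-FBC, otherwise tabular.

    Always returns ``(network, objective_or_None)``.
    """
    p = Path(path)
    if p.suffix.lower() in (".xml", ".sbml"):
        return read_sbml_fbc(p)
    return read_tabular(p, externals=externals), None


# ---------------------------------------------------------------------------
# exchange-bounds tables
# ---------------------------------------------------------------------------

@dataclass
class BoundsTable:
    """Per-exchange-reaction flux bounds, export-oriented sign convention."""

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __len__(self):
        return len(self.bounds)

    def items(self):
        return self.bounds.items()


def read_bounds_csv(path, reduction: str = "none") -> BoundsTable:
    """Read an exchange-bounds CSV.

    Accepted layouts (detected from the header):

    * pre-reduced: columns ``reaction_id, lower_bound, upper_bound``;
    * per-observation: ``reaction_id`` plus paired ``consumption_*`` /
      ``release_*`` magnitude columns; with
      ``reduction="max_over_observations"`` each row collapses to
      ``(-max consumption, +max release)``.
    """
    if reduction not in ("none", "max_over_observations"):
        raise ValueError(f"unknown reduction {reduction!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return BoundsTable({})
    if df.empty and "reaction_id" not in df.columns:
        return BoundsTable({})
    if "reaction_id" not in df.columns:
        raise ModelFormatError(f"{path}: missing 'reaction_id' column")

    out: Dict[str, Tuple[float, float]] = {}
    if {"lower_bound", "upper_bound"}.issubset(df.columns):
        for _, row in df.iterrows():
            rid = str(row["reaction_id"])
            try:
                out[rid] = (float(row["lower_bound"]), float(row["upper_bound"]))
            except (TypeError, ValueError):
                raise ModelFormatError(f"{path}: non-numeric bound in row {rid!r}") from None
        return BoundsTable(out)

    cons = [c for c in df.columns if c.startswith("consumption")]
    rel = [c for c in df.columns if c.startswith("release")]
    if not cons and not rel:
        raise ModelFormatError(
            f"{path}: expected lower/upper_bound or consumption_*/release_* columns"
        )
    if reduction == "none" and (len(cons) > 1 or len(rel) > 1):
        raise ModelFormatError(
            f"{path}: multiple observation columns require reduction='max_over_observations'"
        )
    for _, row in df.iterrows():
        rid = str(row["reaction_id"])
        try:
            cmax = max((float(row[c]) for c in cons), default=0.0)
            rmax = max((float(row[c]) for c in rel), default=0.0)
        except (TypeError, ValueError):
            raise ModelFormatError(f"{path}: non-numeric flux in row {rid!r}") from None
        if cmax < 0 or rmax < 0:
            raise ModelFormatError(
                f"{path}: row {rid!r} has negative flux magnitude"
            )
        out[rid] = (-cmax, rmax)
    return BoundsTable(out)
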