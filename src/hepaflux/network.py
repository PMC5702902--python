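"""Constraint-based metabolic network kernel.

A genome-scale metabolic network (GSMN) is a system of N coupled chemical
reactions over M metabolites, represented by the M×N stoichiometric matrix S
(S[i, j] = coefficient of metabolite i in reaction j). At steady state the
flux vector v satisfies S·v = 0; flux balance analysis (FBA) maximises a
linear objective z = a·v over this null space intersected with the box
l ≤ v ≤ u, which is a linear program with a guaranteed global optimum
(though possibly many alternative optimal flux vectors).

External metabolites (sources/sinks of the cellular microenvironment) are
unbalanced and excluded from the rows of S. An exchange reaction is one
whose internal stoichiometry is one-sided: it consumes internal metabolites
without producing any (a sink/export) or vice versa (a source/import).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .gpr import GPRRule, parse_gpr

logger = logging.getLogger(__name__)

#: componentwise tolerance on S·v = 0 and on bound feasibility of solutions
BALANCE_TOL = 1e-6

__all__ = [
    "BALANCE_TOL",
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "Objective",
    "FBASolution",
    "EssentialityRecord",
    "NetworkStructureError",
    "build_stoichiometric_matrix",
    "fba",
    "knockout_reactions",
    "gene_knockout",
    "essentiality_scan",
    "flux_variability",
    "sample_flux_space",
    "apply_exchange_bounds",
    "is_exchange",
]


class NetworkStructureError(ValueError):
    """A structural inconsistency in a network definition."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    is_external: bool = False


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative for
    substrates, positive for products). Reversibility is encoded purely via
    the bounds: an irreversible reaction has ``lower_bound >= 0``.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise NetworkStructureError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkStructureError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def gpr_rule(self) -> GPRRule:
        return parse_gpr(self.gpr)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicNetwork:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- lookups -------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> frozenset:
        out = set()
        for r in self.reactions:
            out |= r.gpr_rule.genes
        return frozenset(out)

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return self._met_index[mid]
        except KeyError:
            raise KeyError(f"unknown metabolite {mid!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_external]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
        )

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            dup = sorted({x for x in mids if mids.count(x) > 1})
            raise NetworkStructureError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({x for x in rids if rids.count(x) > 1})
            raise NetworkStructureError(f"duplicate reaction ids: {dup}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self._met_index:
                    raise NetworkStructureError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )


@dataclass(frozen=True)
class Objective:
    """Linear objective z = Σ aᵢ·vᵢ, maximised."""

    coefficients: Mapping[str, float]
    name: str = "objective"

    def __post_init__(self):
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("objective has no nonzero coefficient")

    def vector(self, reaction_ids: Sequence[str]) -> np.ndarray:
        unknown = set(self.coefficients) - set(reaction_ids)
        if unknown:
            raise KeyError(f"objective references unknown reactions: {sorted(unknown)}")
        return np.array([self.coefficients.get(rid, 0.0) for rid in reaction_ids])

    def value(self, fluxes: Mapping[str, float]) -> float:
        return float(sum(a * fluxes[rid] for rid, a in self.coefficients.items()))


@dataclass(frozen=True)
class FBASolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    z: float
    v: Dict[str, float]
    residual: float

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class EssentialityRecord:
    reaction_id: str
    z_knockout: float
    z_relative: float
    influences_objective: bool


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def build_stoichiometric_matrix(network: MetabolicNetwork) -> np.ndarray:
    """Dense S over *internal* metabolites (rows) × reactions (columns).

    External metabolites are unbalanced sources/sinks and do not appear.
    """
    internal = network.internal_metabolites()
    row = {m.id: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for mid, coef in rxn.stoichiometry.items():
            met = network.metabolite(mid)  # raises for unresolved ids
            if not met.is_external:
                S[row[mid], j] += coef
    return S


def is_exchange(network: MetabolicNetwork, reaction: Reaction) -> bool:
    """Structural exchange test: one-sided internal stoichiometry.

    A source has no balanced substrate, a sink no balanced product; either
    connects the network to its environment.
    """
    coeffs = [
        c
        for mid, c in reaction.stoichiometry.items()
        if not network.metabolite(mid).is_external and c != 0
    ]
    if not coeffs:
        return True
    return all(c > 0 for c in coeffs) or all(c < 0 for c in coeffs)


def _bounds_arrays(network: MetabolicNetwork) -> Tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in network.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in network.reactions], dtype=float)
    return lb, ub


_LP_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def fba(
    network: MetabolicNetwork,
    objective: Objective,
    tolerance: float = BALANCE_TOL,
) -> FBASolution:
    """Maximise z = a·v subject to S·v = 0 and l ≤ v ≤ u (HiGHS LP).

    Returns one optimal vertex; uniqueness of the flux vector is the
    caller's concern (see :func:`flux_variability`). ``z = 0`` with optimal
    status means the metabolic function carries no flux, i.e. is infeasible
    in the stoichiometric sense.
    """
    S = build_stoichiometric_matrix(network)
    lb, ub = _bounds_arrays(network)
    a = objective.vector(network.reaction_ids)
    res = linprog(
        -a,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = _LP_STATUS.get(res.status, "numerical")
    if status != "optimal":
        if status not in ("infeasible", "unbounded"):
            raise RuntimeError(f"LP solver failure: {res.message}")
        return FBASolution(status=status, z=float("nan"), v={}, residual=float("nan"))
    v = np.asarray(res.x, dtype=float)
    residual = float(np.max(np.abs(S @ v))) if S.size else 0.0
    if residual > tolerance:
        logger.warning("FBA balance residual %.3g exceeds tolerance %.3g", residual, tolerance)
    return FBASolution(
        status="optimal",
        z=float(-res.fun) + 0.0,  # normalise IEEE -0.0 from the solver
        v=dict(zip(network.reaction_ids, v.tolist())),
        residual=residual,
    )


def knockout_reactions(
    network: MetabolicNetwork, reaction_ids: Iterable[str]
) -> MetabolicNetwork:
    """Return a copy with bounds (0, 0) on the listed reactions.

    Setting flux bounds to (0, 0) is equivalent to removing the reaction
    from the model. The input network is unmodified.
    """
    ids = list(reaction_ids)
    out = network.copy()
    for rid in ids:
        rxn = out.reaction(rid)  # raises for unknown ids
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


def gene_knockout(network: MetabolicNetwork, gene_ids: Iterable[str]) -> MetabolicNetwork:
    """Disable every reaction whose GPR rule evaluates False with the given
    genes knocked out (knocked genes False, all others True).

    Reactions with an empty GPR are untouched.
    """
    knocked = set(gene_ids)
    disabled = [
        r.id
        for r in network.reactions
        if r.gpr and not r.gpr_rule.evaluate(knocked_out=knocked)
    ]
    return knockout_reactions(network, disabled)


def essentiality_scan(
    network: MetabolicNetwork,
    objective: Objective,
    influence_threshold: float = 1e-6,
    reaction_ids: Optional[Sequence[str]] = None,
) -> List[EssentialityRecord]:
    """Single-reaction knockout screen against a metabolic objective.

    Each reaction in turn is inactivated by setting its flux bounds to
    (0, 0) and the objective is re-evaluated. ``z_relative`` is the knockout
    optimum normalised to wild type; a reaction influences the objective iff
    |z_relative − 1| > influence_threshold. Knockouts that make the LP
    infeasible are recorded with ``z_knockout = 0``.
    """
    wild = fba(network, objective)
    if not wild.optimal:
        raise RuntimeError(f"wild-type FBA is {wild.status}; essentiality scan refused")
    if wild.z <= 0:
        raise RuntimeError(
            "wild-type objective is not positive; z_relative is undefined"
        )
    rids = list(reaction_ids) if reaction_ids is not None else network.reaction_ids
    records = []
    for rid in rids:
        sol = fba(knockout_reactions(network, [rid]), objective)
        z_ko = sol.z if sol.optimal else 0.0
        # tiny negative LP round-off is clamped; the invariant is 0 <= z_rel
        z_ko = max(z_ko, 0.0)
        z_rel = z_ko / wild.z
        records.append(
            EssentialityRecord(
                reaction_id=rid,
                z_knockout=z_ko,
                z_relative=z_rel,
                influences_objective=abs(z_rel - 1.0) > influence_threshold,
            )
        )
    return records


def flux_variability(
    network: MetabolicNetwork,
    objective: Objective,
    optimality_fraction: float = 1.0,
    reaction_ids: Optional[Sequence[str]] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux subject to z ≥ fraction·z_max.

    A range wider than tolerance on a coupled flux flags alternative optima
    (the LP solver may "flip" between them between time-steps).
    """
    base = fba(network, objective)
    if not base.optimal:
        raise RuntimeError(f"FBA is {base.status}; flux variability undefined")
    S = build_stoichiometric_matrix(network)
    lb, ub = _bounds_arrays(network)
    a = objective.vector(network.reaction_ids)
    # a·v >= f·z_max  encoded as  -a·v <= -f·z_max
    A_ub = -a.reshape(1, -1)
    b_ub = np.array([-optimality_fraction * base.z])
    rids = list(reaction_ids) if reaction_ids is not None else network.reaction_ids
    index = {rid: i for i, rid in enumerate(network.reaction_ids)}
    ranges: Dict[str, Tuple[float, float]] = {}
    for rid in rids:
        j = index[rid]
        c = np.zeros(len(network.reactions))
        c[j] = 1.0
        lo_hi = []
        for sign in (1.0, -1.0):
            res = linprog(
                sign * c,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=list(zip(lb, ub)),
                method="highs",
            )
            if res.status != 0:
                raise RuntimeError(
                    f"FVA sub-problem for {rid!r} ({'min' if sign > 0 else 'max'}) "
                    f"failed: {_LP_STATUS.get(res.status, res.message)}"
                )
            lo_hi.append(sign * res.fun)
        ranges[rid] = (float(lo_hi[0]), float(lo_hi[1]))
    return ranges


def apply_exchange_bounds(
    network: MetabolicNetwork,
    bounds: Mapping[str, Tuple[float, float]],
    restrict_to_listed: bool = False,
) -> MetabolicNetwork:
    """Set exchange-reaction bounds from a table of (lb, ub) per reaction id.

    Rows naming reactions that are not structural exchanges are skipped with
    a logged warning. With ``restrict_to_listed``, every unlisted exchange is
    closed to (0, 0) — the "physiological import/export set" restriction.
    """
    out = network.copy()
    listed = set()
    for rid, (lo, hi) in bounds.items():
        try:
            rxn = out.reaction(rid)
        except KeyError:
            logger.warning("bounds table names unknown reaction %r; skipped", rid)
            continue
        if not is_exchange(out, rxn):
            logger.warning("bounds table names non-exchange reaction %r; skipped", rid)
            continue
        rxn.lower_bound = float(lo)
        rxn.upper_bound = float(hi)
        listed.add(rid)
    if restrict_to_listed:
        for rxn in out.reactions:
            if rxn.id not in listed and is_exchange(out, rxn):
                rxn.lower_bound = 0.0
                rxn.upper_bound = 0.0
    return out


# ---------------------------------------------------------------------------
# flux-space sampling
# ---------------------------------------------------------------------------

def _strictly_feasible_point(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray
) -> np.ndarray:
    """A point of {S v = 0, l ≤ v ≤ u}, pushed toward the interior.

    Maximises the uniform slack t with l + t ≤ v ≤ u − t (t capped at half
    the smallest bound width so the LP stays bounded). Falls back to any
    feasible point when the region has empty interior.
    """
    n = S.shape[1]
    widths = ub - lb
    cap = 0.5 * float(np.min(widths)) if n else 0.0
    # variables: (v, t); maximise t
    c = np.zeros(n + 1)
    c[-1] = -1.0
    A_eq = np.hstack([S, np.zeros((S.shape[0], 1))])
    # v - t >= l  ->  -v + t <= -l ; v + t <= u
    A_ub = np.vstack(
        [
            np.hstack([-np.eye(n), np.ones((n, 1))]),
            np.hstack([np.eye(n), np.ones((n, 1))]),
        ]
    )
    b_ub = np.concatenate([-lb, ub])
    var_bounds = [(None, None)] * n + [(0.0, max(cap, 0.0))]
    res = linprog(
        c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), A_ub=A_ub, b_ub=b_ub,
        bounds=var_bounds, method="highs",
    )
    if res.status != 0:
        raise RuntimeError("flux space is empty: no feasible point exists")
    return np.asarray(res.x[:n], dtype=float)


def sample_flux_space(
    network: MetabolicNetwork,
    n_samples: int,
    seed: int,
    extra_inequalities: Optional[Sequence[Tuple[Mapping[str, float], float, float]]] = None,
    tolerance: float = BALANCE_TOL,
    thin: int = 5,
) -> np.ndarray:
    """Hit-and-run sampling of the steady-state flux polytope.

    Random directions are drawn in the null space of S (restricted to
    reactions whose bounds are not fixed), the feasible chord through the
    current point is computed against the box and any extra linear
    inequalities ``(coefficients, lo, hi)``, and a uniform point on the
    chord is taken. Every ``thin``-th point is recorded. The walk is exactly
    reproducible for a fixed seed.

    Returns an ``(n_samples, N)`` array in the network's reaction order.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    S = build_stoichiometric_matrix(network)
    lb, ub = _bounds_arrays(network)
    n = len(network.reactions)
    rid_index = {rid: i for i, rid in enumerate(network.reaction_ids)}

    ineq_rows = []
    ineq_lo = []
    ineq_hi = []
    for coeffs, lo, hi in extra_inequalities or ():
        row = np.zeros(n)
        for rid, c in coeffs.items():
            row[rid_index[rid]] = c
        ineq_rows.append(row)
        ineq_lo.append(lo)
        ineq_hi.append(hi)
    A = np.array(ineq_rows) if ineq_rows else np.zeros((0, n))
    A_lo = np.array(ineq_lo)
    A_hi = np.array(ineq_hi)

    v = _strictly_feasible_point(S, lb, ub)

    free = lb < ub
    from scipy.linalg import null_space

    basis_free = null_space(S[:, free]) if free.any() else np.zeros((0, 0))
    if basis_free.size == 0:
        # Flux vector fully determined; the "sample" is the single point.
        return np.tile(v, (n_samples, 1))
    basis = np.zeros((n, basis_free.shape[1]))
    basis[free, :] = basis_free

    samples = np.empty((n_samples, n))
    collected = 0
    step = 0
    v_anchor = v.copy()
    while collected < n_samples:
        d = basis @ rng.standard_normal(basis.shape[1])
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            continue
        d /= norm
        t_lo, t_hi = -np.inf, np.inf
        for i in np.nonzero(np.abs(d) > 1e-12)[0]:
            a_, b_ = (lb[i] - v[i]) / d[i], (ub[i] - v[i]) / d[i]
            lo_i, hi_i = min(a_, b_), max(a_, b_)
            t_lo, t_hi = max(t_lo, lo_i), min(t_hi, hi_i)
        if A.shape[0]:
            Ad = A @ d
            Av = A @ v
            for k in np.nonzero(np.abs(Ad) > 1e-12)[0]:
                a_, b_ = (A_lo[k] - Av[k]) / Ad[k], (A_hi[k] - Av[k]) / Ad[k]
                lo_k, hi_k = min(a_, b_), max(a_, b_)
                t_lo, t_hi = max(t_lo, lo_k), min(t_hi, hi_k)
        if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi < t_lo:
            continue
        v = v + rng.uniform(t_lo, t_hi) * d
        # re-project onto the null-space slice to suppress float drift
        v = v_anchor + basis @ (basis.T @ (v - v_anchor))
        np.clip(v, lb, ub, out=v)
        step += 1
        if step % thin == 0:
            resid = float(np.max(np.abs(S @ v))) if S.size else 0.0
            if resid > tolerance:
                raise RuntimeError(f"sampler drifted off the balance manifold ({resid:.2e})")
            samples[collected] = v
            collected += 1
    return samples
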