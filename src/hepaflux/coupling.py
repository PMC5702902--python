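"""Quasi-steady-state coupling of the metabolic network, PBPK and gene
regulation layers.

Intracellular metabolism is far faster than drug distribution and gene
regulation, so within each coupling time-step (a few minutes) the network
is assumed to sit at steady state while the PBPK/GRN ODEs evolve. Each
iteration runs up to four steps:

1. *feedforward* — selected network flux bounds are set from current
   tissue concentrations (e.g. competitive inhibition of a dehydrogenase
   by the toxic metabolite scales its wild-type upper bound);
2. *FBA* — the metabolic objective (e.g. maximal GSH production) is
   re-optimised;
3. *feedback* — the objective value is mapped through a scaling table to a
   PBPK parameter (e.g. the GSH-conjugation scaling factor SF(GSHmax));
4. the PBPK and GRN ODEs are advanced together by one time-step, with the
   enzyme level read out of the GRN as the linear phase-I scale.

Only the objective *value* is fed back: the LP optimum value is unique even
when the optimal flux vector is not, which avoids the discontinuities an
under-constrained model would inject if individual solver-chosen fluxes
were coupled. ``feedforward_only`` and ``feedback_only`` modes skip step 3
or step 1 respectively; in feedback-only mode the bounds never change, so
the LP is evaluated once and reused.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from . import pbpk as _pbpk
from .grn import GRNParameters, cortisol_schedule, cyp3a4_scale, grn_derivatives, grn_steady_state
from .network import (
    FBASolution,
    MetabolicNetwork,
    Objective,
    fba,
    flux_variability,
)
from .pbpk import PBPKParameters, PBPKTrajectory, N_STATE

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingConfigError",
    "CompetitiveInhibition",
    "FeedforwardLink",
    "ScalingTable",
    "FeedbackLink",
    "CouplingConfig",
    "MultiscaleModel",
    "MultiscaleTrajectory",
    "competitive_inhibition_activity",
    "apply_feedforward",
    "uniqueness_guard",
    "simulate_multiscale",
]

MODES = ("full", "feedforward_only", "feedback_only")


class CouplingConfigError(ValueError):
    """Invalid link or configuration detected at load time."""


def competitive_inhibition_activity(inhibitor: float, ki: float) -> float:
    """Relative rate 1/(1 + I/(2·Ki)) of a competitively inhibited
    Michaelis–Menten reaction operating at S = Km, normalised to the
    uninhibited rate. Maps any I ≥ 0 into (0, 1]; I and Ki share units.
    """
    if ki <= 0:
        raise ValueError("Ki must be > 0")
    if inhibitor < 0:
        raise ValueError("inhibitor concentration must be >= 0")
    return 1.0 / (1.0 + inhibitor / (2.0 * ki))


@dataclass(frozen=True)
class CompetitiveInhibition:
    """Concentration→activity transform with Ki in mM (substrate at Km)."""

    ki_mm: float

    def __call__(self, concentration_mm: float) -> float:
        return competitive_inhibition_activity(concentration_mm, self.ki_mm)


@dataclass
class FeedforwardLink:
    """PBPK concentration → network reaction bound.

    The source tissue concentration (mg/L) is converted to the transform's
    units (mM by default, via the molar mass in g/mol) and mapped through
    ``transform`` to an activity in (0, 1] that scales the reaction's
    *wild-type* bounds each step (never the previous step's bounds, so
    repeated application cannot compound).
    """

    reaction_id: str
    transform: Callable[[float], float]
    species: str = "metabolite"
    compartment: str = "liver"
    molar_mass_g_per_mol: float = 151.2  # example-drug value, config-overridable

    def concentration_mm(self, conc_mg_per_l: float) -> float:
        return conc_mg_per_l / self.molar_mass_g_per_mol

    def activity(self, conc_mg_per_l: float) -> float:
        a = float(self.transform(self.concentration_mm(conc_mg_per_l)))
        if not (0.0 < a <= 1.0):
            raise CouplingConfigError(
                f"link to {self.reaction_id!r}: transform produced activity {a}, "
                "outside (0, 1]"
            )
        return a


@dataclass
class ScalingTable:
    """Objective value → scaling factor SF.

    ``proportional`` mode: SF = z / z_ref (proportional to maximal
    availability). ``lookup`` mode: monotone non-decreasing breakpoints
    (z, SF) interpolated stepwise ("step", previous breakpoint holds) or
    piecewise-linearly ("linear").
    """

    mode: str = "proportional"
    z_ref: Optional[float] = None
    breakpoints: Sequence[Tuple[float, float]] = ()
    interpolation: str = "linear"

    def __post_init__(self):
        if self.mode not in ("proportional", "lookup"):
            raise CouplingConfigError(f"unknown scaling mode {self.mode!r}")
        if self.mode == "proportional":
            if self.z_ref is None or self.z_ref <= 0:
                raise CouplingConfigError("proportional scaling requires z_ref > 0")
        else:
            bp = sorted(self.breakpoints)
            if not bp:
                raise CouplingConfigError("lookup scaling requires breakpoints")
            sfs = [s for _, s in bp]
            if any(s < 0 for s in sfs):
                raise CouplingConfigError("scaling factors must be >= 0")
            if any(b > a for a, b in zip(sfs[1:], sfs[:-1])):
                raise CouplingConfigError("scaling table must be monotone non-decreasing")
            if self.interpolation not in ("step", "linear"):
                raise CouplingConfigError(f"unknown interpolation {self.interpolation!r}")
            self.breakpoints = bp

    def __call__(self, z: float) -> float:
        if self.mode == "proportional":
            return max(z, 0.0) / self.z_ref
        zs = np.array([b[0] for b in self.breakpoints])
        sfs = np.array([b[1] for b in self.breakpoints])
        if z <= zs[0]:
            return float(sfs[0])
        if z >= zs[-1]:
            return float(sfs[-1])
        if self.interpolation == "linear":
            return float(np.interp(z, zs, sfs))
        return float(sfs[np.searchsorted(zs, z, side="right") - 1])


@dataclass
class FeedbackLink:
    """Network objective value → PBPK parameter (the GSH-conjugation scale)."""

    table: ScalingTable
    target: str = "gsh_scale"

    def __post_init__(self):
        if self.target != "gsh_scale":
            raise CouplingConfigError(f"unsupported feedback target {self.target!r}")


@dataclass
class CouplingConfig:
    dt_h: float = 5.0 / 60.0  # a few minutes, short vs. PK timescales
    mode: str = "full"
    uniqueness_check: bool = False
    uniqueness_tol: float = 1e-6

    def __post_init__(self):
        if self.dt_h <= 0:
            raise CouplingConfigError("dt_h must be > 0")
        if self.mode not in MODES:
            raise CouplingConfigError(f"mode must be one of {MODES}")


def apply_feedforward(
    network: MetabolicNetwork,
    links: Sequence[FeedforwardLink],
    concentrations_mg_per_l: Dict[Tuple[str, str], float],
) -> MetabolicNetwork:
    """Scale linked reactions' wild-type bounds by their current activity.

    ``network`` carries the wild-type (reference) bounds; the returned copy
    has, for each link, upper bound ``activity × wild-type upper`` (and the
    lower bound scaled symmetrically when negative, preserving declared
    reversibility). Scaling is stateless: calling twice with the same
    concentrations yields the same bounds, not their square.
    """
    out = network.copy()
    for link in links:
        try:
            rxn = out.reaction(link.reaction_id)
        except KeyError:
            raise CouplingConfigError(
                f"feedforward link targets unknown reaction {link.reaction_id!r}"
            ) from None
        conc = concentrations_mg_per_l.get((link.species, link.compartment), 0.0)
        a = link.activity(conc)
        rxn.upper_bound = a * network.reaction(link.reaction_id).upper_bound
        wt_lo = network.reaction(link.reaction_id).lower_bound
        rxn.lower_bound = a * wt_lo if wt_lo < 0 else wt_lo
    return out


def uniqueness_guard(
    network: MetabolicNetwork,
    objective: Objective,
    coupled_reaction_ids: Sequence[str],
    tolerance: float = 1e-6,
    strict: bool = False,
) -> Dict[str, Tuple[float, float]]:
    """Flag coupled fluxes whose range at the optimum exceeds tolerance.

    The LP optimum *value* is always unique, but individual fluxes need not
    be; a solver flipping between alternative optima would make flux-level
    feedback discontinuous. Returns the offending {rid: (min, max)} ranges;
    warns by default, raises in strict mode.
    """
    ranges = flux_variability(network, objective, optimality_fraction=1.0,
                              reaction_ids=coupled_reaction_ids)
    wide = {rid: r for rid, r in ranges.items() if (r[1] - r[0]) > tolerance}
    for rid, (lo, hi) in wide.items():
        msg = (f"coupled flux {rid!r} is non-unique at the optimum "
               f"(range [{lo:.6g}, {hi:.6g}])")
        if strict:
            raise RuntimeError(msg)
        logger.warning(msg)
    return wide


@dataclass
class MultiscaleTrajectory:
    """Time-stamped multiscale output: PBPK states, GRN states, z, SF."""

    pbpk: PBPKTrajectory
    grn_states: Optional[np.ndarray]     # (n_times, 3) or None
    z: np.ndarray                        # objective value per step boundary
    sf: np.ndarray                       # SF applied on each interval (+ final)
    cyp_scale: np.ndarray
    activities: Dict[str, np.ndarray]    # per feedforward link

    @property
    def times_h(self) -> np.ndarray:
        return self.pbpk.times_h

    def liver_metabolite_cmax(self) -> float:
        return float(self.pbpk.concentration("metabolite", "liver").max())

    def to_frame(self):
        import pandas as pd

        df = self.pbpk.to_frame()
        df["z"] = self.z
        df["sf"] = self.sf
        df["cyp3a4_scale"] = self.cyp_scale
        if self.grn_states is not None:
            df["grn_gr_total_nm"] = self.grn_states[:, 0]
            df["grn_pxr_total_nm"] = self.grn_states[:, 1]
            df["grn_cyp3a4_nm"] = self.grn_states[:, 2]
        for rid, act in self.activities.items():
            df[f"activity_{rid}"] = act
        return df


@dataclass
class MultiscaleModel:
    """Bundle of the three layers plus their coupling links.

    ``network`` holds the reference (wild-type, or deliberately perturbed,
    e.g. knocked-out) bounds that feedforward scaling always starts from.
    ``grn_params`` may be None to run without the regulatory layer
    (cyp3a4_scale fixed at 1).
    """

    network: MetabolicNetwork
    objective: Objective
    pbpk_params: PBPKParameters
    grn_params: Optional[GRNParameters] = None
    feedforward: Sequence[FeedforwardLink] = ()
    feedback: Optional[FeedbackLink] = None
    config: CouplingConfig = field(default_factory=CouplingConfig)
    cortisol: Optional[Callable[[float], float]] = None

    def __post_init__(self):
        for link in self.feedforward:
            if link.reaction_id not in self.network.reaction_ids:
                raise CouplingConfigError(
                    f"feedforward link targets unknown reaction {link.reaction_id!r}"
                )

    # -- helpers -------------------------------------------------------
    def _concentrations(self, y: np.ndarray) -> Dict[Tuple[str, str], float]:
        out = {}
        for link in self.feedforward:
            comp = link.compartment
            off = 1 if link.species == "parent" else 1 + _pbpk._NC
            amt = max(float(y[off + _pbpk._IDX[comp]]), 0.0)
            out[(link.species, comp)] = amt / self.pbpk_params.volumes_l[comp]
        return out

    def _combined_rhs(self, cyp_scale_of, gsh_scale, infusion, ka, cortisol):
        p = self.pbpk_params
        gp = self.grn_params

        def rhs(t, y):
            y_pb = y[:N_STATE]
            if gp is not None:
                y_gr = y[N_STATE:]
                cyp_scale = cyp3a4_scale(max(float(y_gr[2]), 0.0), gp.cyp3a4_ref_nm)
                d_gr = grn_derivatives(y_gr, t, gp, cortisol)
            else:
                cyp_scale = 1.0
                d_gr = np.zeros(0)
            d_pb = _pbpk.derivatives(y_pb, t, p, cyp_scale, gsh_scale, infusion, ka)
            return np.concatenate([d_pb, d_gr])

        return rhs

    # -- the quasi-steady-state loop -----------------------------------
    def simulate(
        self,
        duration_h: float,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ) -> MultiscaleTrajectory:
        """Run the four-step loop for ``duration_h`` hours.

        Deterministic for a fixed model and configuration. Aborts with the
        step index and the offending bounds if the LP turns infeasible
        mid-run.
        """
        cfg = self.config
        n_steps = int(round(duration_h / cfg.dt_h))
        if n_steps < 1:
            raise ValueError("duration shorter than one coupling step")
        t_grid = np.linspace(0.0, n_steps * cfg.dt_h, n_steps + 1)

        grn_on = self.grn_params is not None
        cortisol = self.cortisol
        if grn_on and cortisol is None:
            cortisol = cortisol_schedule("homeostatic", self.grn_params)

        y = np.zeros(N_STATE + (3 if grn_on else 0))
        if grn_on:
            y[N_STATE:] = grn_steady_state(self.grn_params)
        # initial boluses / oral depot at t = 0
        for d in self.pbpk_params.doses:
            if abs(d.time_h - t_grid[0]) < 1e-12:
                if d.route == "iv_bolus":
                    y[1 + _pbpk._IDX["venous"]] += d.amount_mg
                elif d.route == "oral":
                    y[0] += d.amount_mg

        n_t = n_steps + 1
        states = np.empty((n_t, N_STATE))
        grn_states = np.empty((n_t, 3)) if grn_on else None
        z_series = np.empty(n_t)
        sf_series = np.empty(n_t)
        cyp_series = np.empty(n_t)
        act_series = {l.reaction_id: np.empty(n_t) for l in self.feedforward}

        cached_solution: Optional[FBASolution] = None
        for k in range(n_steps + 1):
            t = t_grid[k]
            # Step 1: feedforward (skipped in feedback_only mode)
            if cfg.mode != "feedback_only" and self.feedforward:
                concs = self._concentrations(y[:N_STATE])
                net_k = apply_feedforward(self.network, self.feedforward, concs)
                for link in self.feedforward:
                    act_series[link.reaction_id][k] = link.activity(
                        concs[(link.species, link.compartment)]
                    )
                sol = fba(net_k, self.objective)
            else:
                for link in self.feedforward:
                    act_series[link.reaction_id][k] = 1.0
                # bounds are constant: one LP evaluation suffices
                if cached_solution is None:
                    cached_solution = fba(self.network, self.objective)
                sol = cached_solution
                net_k = self.network
            # Step 2 result
            if not sol.optimal:
                snapshot = {r.id: (r.lower_bound, r.upper_bound)
                            for r in net_k.reactions}
                raise RuntimeError(
                    f"FBA {sol.status} at coupling step {k} (t = {t:.4g} h); "
                    f"bounds snapshot: {snapshot}"
                )
            z_series[k] = sol.z
            if cfg.uniqueness_check and self.feedforward:
                uniqueness_guard(net_k, self.objective,
                                 [l.reaction_id for l in self.feedforward],
                                 tolerance=cfg.uniqueness_tol)
            # Step 3: feedback (skipped in feedforward_only mode)
            if cfg.mode != "feedforward_only" and self.feedback is not None:
                sf = self.feedback.table(sol.z)
            else:
                sf = 1.0
            sf_series[k] = sf
            cyp_series[k] = (
                cyp3a4_scale(max(float(y[N_STATE + 2]), 0.0),
                             self.grn_params.cyp3a4_ref_nm)
                if grn_on else 1.0
            )
            states[k] = y[:N_STATE]
            if grn_on:
                grn_states[k] = y[N_STATE:]
            if k == n_steps:
                break
            # Step 4: advance PBPK (+ GRN) by one time-step
            ta, tb = t_grid[k], t_grid[k + 1]
            for sa, sb in zip(*(lambda s: (s[:-1], s[1:]))(
                    _pbpk._segment_events(self.pbpk_params, ta, tb))):
                infusion, ka = _dose_inputs(self.pbpk_params, 0.5 * (sa + sb))
                ivp = solve_ivp(
                    self._combined_rhs(None, sf, infusion, ka, cortisol),
                    (sa, sb), y, method="LSODA", rtol=rtol, atol=atol,
                )
                if not ivp.success:
                    raise RuntimeError(
                        f"ODE advance failed at step {k} on [{sa:.4g}, {sb:.4g}] h: "
                        f"{ivp.message}"
                    )
                y = ivp.y[:, -1]
                for d in self.pbpk_params.doses:
                    if abs(d.time_h - sb) < 1e-12:
                        if d.route == "iv_bolus":
                            y[1 + _pbpk._IDX["venous"]] += d.amount_mg
                        elif d.route == "oral":
                            y[0] += d.amount_mg

        traj = PBPKTrajectory(times_h=t_grid, states=states, params=self.pbpk_params)
        return MultiscaleTrajectory(
            pbpk=traj, grn_states=grn_states, z=z_series, sf=sf_series,
            cyp_scale=cyp_series, activities=act_series,
        )


def _dose_inputs(params: PBPKParameters, t_mid: float) -> Tuple[float, float]:
    infusion = 0.0
    ka = 0.0
    for d in params.doses:
        if d.route == "iv_infusion" and d.time_h <= t_mid < d.time_h + d.duration_h:
            infusion += d.amount_mg / d.duration_h
        if d.route == "oral":
            ka = d.ka_per_h
    return infusion, ka


def simulate_multiscale(model: MultiscaleModel, duration_h: float,
                        **kw) -> MultiscaleTrajectory:
    """Functional entry point; see :meth:`MultiscaleModel.simulate`."""
    return model.simulate(duration_h, **kw)
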