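"""Whole-body perfusion-limited PBPK model for a parent drug and its toxic
metabolite.

The model is a standard 13-compartment flow-limited human (lung, arterial
and venous blood, liver, kidney, gut, muscle, adipose, skin, brain, heart,
bone, rest-of-body) with gut drained through the portal vein into the
liver. Amounts (mg) are the state variables; the concentration of blood
leaving tissue T is A_T / (V_T · Kp_T / BP).

The parent drug is converted in the liver by CYP3A4-mediated phase-I
metabolism into a toxic metabolite at rate

    v_met = cyp3a4_scale · CL_phaseI · Cu_liver,

with Cu the unbound concentration in liver outflow blood (fup·C_out/BP) and
``cyp3a4_scale`` the dimensionless enzyme-level scale delivered by the gene
-regulation layer. The metabolite is tracked in parent-mass equivalents
(1:1 stoichiometry), so dose reconciliation is exact by construction, and
is cleared in the liver by glutathione (GSH) conjugation,

    GSH conjugation rate = SF(GSHmax) · CLmet · (Atox / Vli) · fup,

where SF is the scaling factor proportional to the maximal GSH
availability computed by the metabolic layer. The formula uses the *total*
liver concentration Atox/Vli of the metabolite; see docs/methods.md for the
reading of this rate law.

All drug-specific parameters are example values within physiological
ranges; the model is a demonstration vehicle, not a description of any
particular compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "COMPARTMENTS",
    "TISSUES",
    "Dose",
    "PBPKParameters",
    "PBPKTrajectory",
    "gsh_conjugation_rate",
    "derivatives",
    "simulate",
]

#: compartment order of the state vector (per species)
COMPARTMENTS = [
    "lung", "arterial", "venous", "liver", "kidney", "gut", "muscle",
    "adipose", "skin", "brain", "heart", "bone", "rest",
]
#: perfused tissues (everything except the three blood/lung nodes)
TISSUES = COMPARTMENTS[3:]

_IDX = {c: i for i, c in enumerate(COMPARTMENTS)}
_NC = len(COMPARTMENTS)
# state layout: [depot, parent(13), metabolite(13),
#                cum_formed, cum_conjugated, cum_parent_renal, cum_met_renal]
N_STATE = 1 + 2 * _NC + 4


@dataclass(frozen=True)
class Dose:
    """One administration: iv-bolus, iv-infusion, or oral first-order."""

    route: str  # "iv_bolus" | "iv_infusion" | "oral"
    amount_mg: float
    time_h: float = 0.0
    ka_per_h: float = 1.0         # oral absorption rate constant
    duration_h: float = 1.0       # infusion duration

    def __post_init__(self):
        if self.route not in ("iv_bolus", "iv_infusion", "oral"):
            raise ValueError(f"unknown dosing route {self.route!r}")
        if self.amount_mg < 0:
            raise ValueError("dose amount must be >= 0")


def _default_volumes() -> Dict[str, float]:
    # L, ~70 kg adult; standard physiology-table values
    return {
        "lung": 0.5, "arterial": 1.7, "venous": 3.9, "liver": 1.8,
        "kidney": 0.31, "gut": 1.65, "muscle": 29.0, "adipose": 13.5,
        "skin": 3.4, "brain": 1.45, "heart": 0.33, "bone": 10.5, "rest": 4.1,
    }


def _default_flows() -> Dict[str, float]:
    # L/h; fractions of a 390 L/h cardiac output. "liver" is the hepatic
    # artery only; portal inflow arrives via the gut compartment.
    return {
        "liver": 25.35, "kidney": 74.1, "gut": 58.5, "muscle": 66.3,
        "adipose": 19.5, "skin": 19.5, "brain": 46.8, "heart": 15.6,
        "bone": 19.5, "rest": 44.85,
    }


def _default_kp() -> Dict[str, float]:
    return {
        "lung": 1.0, "liver": 2.0, "kidney": 2.0, "gut": 1.5, "muscle": 1.2,
        "adipose": 0.8, "skin": 1.0, "brain": 1.0, "heart": 1.2, "bone": 0.6,
        "rest": 1.0,
    }


@dataclass
class PBPKParameters:
    """Physiology + example-drug parameters. All values config-overridable."""

    volumes_l: Dict[str, float] = field(default_factory=_default_volumes)
    flows_l_per_h: Dict[str, float] = field(default_factory=_default_flows)
    kp_parent: Dict[str, float] = field(default_factory=_default_kp)
    kp_metabolite: Dict[str, float] = field(default_factory=_default_kp)
    fup_parent: float = 0.3
    fup_metabolite: float = 0.3
    blood_plasma_ratio: float = 1.0
    cl_phase1_l_per_h: float = 30.0     # CYP3A4 pathway at reference enzyme level
    cl_met_l_per_h: float = 12.0        # CLmet: GSH-conjugation intrinsic clearance
    cl_renal_parent_l_per_h: float = 6.0
    cl_renal_metabolite_l_per_h: float = 0.0
    doses: List[Dose] = field(default_factory=lambda: [Dose("oral", 500.0, 0.0, 1.0)])

    def __post_init__(self):
        for name, table in (("volume", self.volumes_l), ("flow", self.flows_l_per_h)):
            for k, v in table.items():
                if v <= 0:
                    raise ValueError(f"{name} of {k!r} must be > 0")
        if not (0 < self.fup_parent <= 1 and 0 < self.fup_metabolite <= 1):
            raise ValueError("fraction unbound must be in (0, 1]")
        missing = set(TISSUES) - set(self.flows_l_per_h)
        if missing:
            raise ValueError(f"missing flows for {sorted(missing)}")
        missing = set(COMPARTMENTS) - set(self.volumes_l)
        if missing:
            raise ValueError(f"missing volumes for {sorted(missing)}")

    @property
    def cardiac_output(self) -> float:
        """Total tissue perfusion; equals lung flow and venous return."""
        return sum(self.flows_l_per_h[t] for t in TISSUES)

    @property
    def liver_volume_l(self) -> float:
        return self.volumes_l["liver"]

    def replace(self, **kw) -> "PBPKParameters":
        return replace(self, **kw)


def gsh_conjugation_rate(
    sf: float, cl_met: float, a_tox: float, v_li: float, fup: float
) -> float:
    """GSH conjugation rate (mg/h) = SF · CLmet · (Atox/Vli) · fup.

    SF is the dimensionless scaling factor proportional to maximal GSH
    availability; SF = 0 (GSH production abolished) shuts conjugation down.
    """
    if min(sf, cl_met, a_tox, fup) < 0:
        raise ValueError("all inputs must be >= 0")
    if v_li <= 0:
        raise ValueError("liver volume must be > 0")
    return sf * cl_met * (a_tox / v_li) * fup


def _blood_out_conc(amount: float, volume: float, kp: float, bp: float) -> float:
    return amount / (volume * kp / bp)


def derivatives(
    state: np.ndarray,
    t: float,
    params: PBPKParameters,
    cyp3a4_scale: float = 1.0,
    gsh_scale: float = 1.0,
    infusion_rate: float = 0.0,
    oral_ka: float = 0.0,
) -> np.ndarray:
    """Time derivative of the full PBPK state (amounts, mg).

    ``cyp3a4_scale`` multiplies the phase-I clearance (enzyme level / its
    homeostatic reference); ``gsh_scale`` is SF(GSHmax) on the conjugation
    rate. Negative state excursions from the integrator are treated as 0.
    """
    if cyp3a4_scale < 0 or gsh_scale < 0:
        raise ValueError("scales must be >= 0")
    y = np.asarray(state, dtype=float)
    if np.any(y < -1e-6):
        logger.info("negative state excursion clipped (min %.3g)", float(y.min()))
    y = np.maximum(y, 0.0)

    p = params
    bp = p.blood_plasma_ratio
    dy = np.zeros_like(y)
    depot = y[0]
    par = y[1:1 + _NC]
    met = y[1 + _NC:1 + 2 * _NC]
    dpar = np.zeros(_NC)
    dmet = np.zeros(_NC)
    q_co = p.cardiac_output

    for species, a, da, kp_t, fup, cl_ren in (
        ("parent", par, dpar, p.kp_parent, p.fup_parent, p.cl_renal_parent_l_per_h),
        ("met", met, dmet, p.kp_metabolite, p.fup_metabolite,
         p.cl_renal_metabolite_l_per_h),
    ):
        c_art = a[_IDX["arterial"]] / p.volumes_l["arterial"]
        c_ven = a[_IDX["venous"]] / p.volumes_l["venous"]
        c_out = {
            tis: _blood_out_conc(a[_IDX[tis]], p.volumes_l[tis], kp_t[tis], bp)
            for tis in TISSUES
        }
        c_lung_out = _blood_out_conc(a[_IDX["lung"]], p.volumes_l["lung"],
                                     kp_t["lung"], bp)
        # blood loop: venous -> lung -> arterial -> tissues
        da[_IDX["lung"]] += q_co * (c_ven - c_lung_out)
        da[_IDX["arterial"]] += q_co * c_lung_out - q_co * c_art
        venous_in = 0.0
        q_liver_out = p.flows_l_per_h["liver"] + p.flows_l_per_h["gut"]
        for tis in TISSUES:
            q = p.flows_l_per_h[tis]
            da[_IDX[tis]] += q * c_art
            if tis == "gut":
                pass  # gut outflow enters the liver, handled below
            elif tis == "liver":
                da[_IDX[tis]] += p.flows_l_per_h["gut"] * c_out["gut"]
                da[_IDX[tis]] -= q_liver_out * c_out["liver"]
                venous_in += q_liver_out * c_out["liver"]
            else:
                da[_IDX[tis]] -= q * c_out[tis]
                venous_in += q * c_out[tis]
        da[_IDX["gut"]] -= p.flows_l_per_h["gut"] * c_out["gut"]
        da[_IDX["venous"]] += venous_in - q_co * c_ven
        # renal elimination on unbound kidney outflow
        cu_kid = fup * c_out["kidney"] / bp
        ren = cl_ren * cu_kid
        da[_IDX["kidney"]] -= ren
        if species == "parent":
            dy[1 + 2 * _NC + 2] = ren  # cum parent renal
        else:
            dy[1 + 2 * _NC + 3] = ren

    # liver phase-I metabolism: parent -> metabolite (parent-equivalents)
    cu_li = p.fup_parent * _blood_out_conc(
        par[_IDX["liver"]], p.volumes_l["liver"], p.kp_parent["liver"], bp
    ) / bp
    v_met = cyp3a4_scale * p.cl_phase1_l_per_h * cu_li
    dpar[_IDX["liver"]] -= v_met
    dmet[_IDX["liver"]] += v_met
    dy[1 + 2 * _NC + 0] = v_met  # cum formed

    # liver GSH conjugation of the metabolite
    v_conj = gsh_conjugation_rate(
        gsh_scale, p.cl_met_l_per_h, met[_IDX["liver"]], p.volumes_l["liver"],
        p.fup_metabolite,
    )
    dmet[_IDX["liver"]] -= v_conj
    dy[1 + 2 * _NC + 1] = v_conj  # cum conjugated

    # dosing inputs
    dy[0] = -oral_ka * depot
    dpar[_IDX["gut"]] += oral_ka * depot
    dpar[_IDX["venous"]] += infusion_rate

    dy[1:1 + _NC] = dpar
    dy[1 + _NC:1 + 2 * _NC] = dmet
    return dy


@dataclass
class PBPKTrajectory:
    """Simulated time series of amounts; concentration helpers in mg/L."""

    times_h: np.ndarray
    states: np.ndarray  # (n_times, N_STATE)
    params: PBPKParameters

    def amount(self, species: str, compartment: str) -> np.ndarray:
        off = 1 if species == "parent" else 1 + _NC
        return self.states[:, off + _IDX[compartment]]

    def concentration(self, species: str, compartment: str) -> np.ndarray:
        return self.amount(species, compartment) / self.params.volumes_l[compartment]

    @property
    def cumulative_formed(self) -> np.ndarray:
        return self.states[:, 1 + 2 * _NC + 0]

    @property
    def cumulative_eliminated(self) -> np.ndarray:
        s = self.states
        return s[:, 1 + 2 * _NC + 1] + s[:, 1 + 2 * _NC + 2] + s[:, 1 + 2 * _NC + 3]

    def total_in_body(self) -> np.ndarray:
        """Depot + parent + metabolite (parent-equivalents), mg."""
        return (self.states[:, 0]
                + self.states[:, 1:1 + _NC].sum(axis=1)
                + self.states[:, 1 + _NC:1 + 2 * _NC].sum(axis=1))

    def dose_administered(self, t: float) -> float:
        return sum(d.amount_mg for d in self.params.doses if d.time_h <= t + 1e-12)

    def mass_balance_error(self) -> float:
        """Max relative reconciliation error vs. administered dose."""
        dosed = np.array([self.dose_administered(t) for t in self.times_h])
        total = self.total_in_body() + self.cumulative_eliminated
        scale = max(float(dosed.max()), 1e-12)
        return float(np.max(np.abs(total - dosed)) / scale)

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times_h}
        for sp in ("parent", "metabolite"):
            for comp in COMPARTMENTS:
                data[f"{sp}_{comp}_mg_per_l"] = self.concentration(sp, comp)
        data["cum_formed_mg"] = self.cumulative_formed
        data["cum_eliminated_mg"] = self.cumulative_eliminated
        return pd.DataFrame(data)


def _segment_events(params: PBPKParameters, t0: float, t1: float) -> List[float]:
    pts = {t0, t1}
    for d in params.doses:
        for t in (d.time_h, d.time_h + (d.duration_h if d.route == "iv_infusion" else 0.0)):
            if t0 < t < t1:
                pts.add(t)
    return sorted(pts)


def simulate(
    params: PBPKParameters,
    t_grid: Sequence[float],
    scale_series: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> PBPKTrajectory:
    """Integrate the PBPK ODEs over ``t_grid`` (h, strictly increasing).

    ``scale_series`` optionally gives piecewise-constant
    (cyp3a4_scale, gsh_scale) values per grid interval (length
    ``len(t_grid) - 1`` each); both default to 1. The result is
    deterministic for fixed inputs.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if scale_series is None:
        cyp = np.ones(len(t_grid) - 1)
        gsh = np.ones(len(t_grid) - 1)
    else:
        cyp = np.asarray(scale_series[0], dtype=float)
        gsh = np.asarray(scale_series[1], dtype=float)
        if len(cyp) != len(t_grid) - 1 or len(gsh) != len(t_grid) - 1:
            raise ValueError("scale_series must have one value per grid interval")

    y = np.zeros(N_STATE)
    states = np.empty((len(t_grid), N_STATE))

    def _apply_bolus_and_depot(t, y):
        for d in params.doses:
            if abs(d.time_h - t) < 1e-12:
                if d.route == "iv_bolus":
                    y[1 + _IDX["venous"]] += d.amount_mg
                elif d.route == "oral":
                    y[0] += d.amount_mg

    def _inputs_at(t_mid):
        inf = 0.0
        ka = 0.0
        for d in params.doses:
            if d.route == "iv_infusion" and d.time_h <= t_mid < d.time_h + d.duration_h:
                inf += d.amount_mg / d.duration_h
            if d.route == "oral":
                ka = d.ka_per_h  # single ka governs the shared depot
        return inf, ka

    _apply_bolus_and_depot(t_grid[0], y)
    states[0] = y
    for k in range(len(t_grid) - 1):
        for ta, tb in zip(*(lambda s: (s[:-1], s[1:]))(
                _segment_events(params, t_grid[k], t_grid[k + 1]))):
            inf, ka = _inputs_at(0.5 * (ta + tb))
            sol = solve_ivp(
                lambda t, yy: derivatives(yy, t, params, cyp[k], gsh[k], inf, ka),
                (ta, tb), y, method=method, rtol=rtol, atol=atol,
            )
            if not sol.success:
                raise RuntimeError(
                    f"PBPK integration failed on [{ta:.4g}, {tb:.4g}] h: {sol.message}"
                )
            y = sol.y[:, -1]
            _apply_bolus_and_depot(tb, y)
        states[k + 1] = y
    return PBPKTrajectory(times_h=t_grid, states=states, params=params)
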