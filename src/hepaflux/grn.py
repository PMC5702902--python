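"""ODE model of cortisol-driven nuclear-receptor regulation of liver CYP3A4.

Cortisol binds three receptors with affinities spanning four orders of
magnitude — mineralocorticoid receptor (MR, Kd ≈ 1 nM), glucocorticoid
receptor (GR, Kd ≈ 10 nM) and pregnane X receptor (PXR, Kd ≈ 10 μM) — so
different receptor sets engage at different cortisol levels. Binding is
treated as rapid equilibrium: the activated (ligand-bound) fraction of a
receptor pool is the occupancy L/(L+Kd).

The regulatory motifs wired here are the ones the biology names:

* activated GR represses GR synthesis (negative feedback),
* activated GR induces PXR synthesis (positive feedforward),
* activated PXR (with a smaller activated-GR contribution) drives CYP3A4
  synthesis through a saturating function,
* every pool turns over by first-order degradation.

Synthesis rate constants are back-calculated from the degradation rates so
that the unperturbed system sits exactly at its homeostatic reference —
in particular total liver CYP3A4 at 705 nM — and therefore leaves drug
metabolism untouched until cortisol deviates from baseline. MR is carried
in the affinity ladder for occupancy readouts but has no downstream edge.

The enzyme→metabolism coupling is linear: a CYP3A4 level of c scales the
phase-I metabolism rate by c / 705 nM, so a 10% enzyme increase yields a
10% faster metabolism.

The exact published equations and constants of the source regulatory model
are not reproduced here; this module implements the minimal motif set with
hour-scale kinetics, all parameters exposed in configuration. See
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence, Tuple

import numpy as np

__all__ = [
    "GRNParameters",
    "GRNState",
    "receptor_occupancy",
    "grn_derivatives",
    "grn_steady_state",
    "cortisol_schedule",
    "cyp3a4_scale",
    "simulate_grn",
]


def receptor_occupancy(ligand_nm: float, kd_nm: float) -> float:
    """Equilibrium receptor occupancy L/(L+Kd) ∈ [0, 1]."""
    if ligand_nm < 0 or kd_nm < 0:
        raise ValueError("ligand and Kd must be >= 0")
    if ligand_nm == 0:
        return 0.0
    return ligand_nm / (ligand_nm + kd_nm)


def cyp3a4_scale(cyp3a4_nm: float, cyp3a4_ref_nm: float) -> float:
    """Linear enzyme→metabolism coupling: scale = CYP3A4 / reference.

    The percentage change in CYP3A4 concentration translates one-to-one
    into the percentage change of the phase-I metabolism rate.
    """
    if cyp3a4_ref_nm <= 0:
        raise ValueError("reference CYP3A4 must be > 0")
    return cyp3a4_nm / cyp3a4_ref_nm


@dataclass
class GRNParameters:
    """Affinity ladder, turnover rates and homeostatic references.

    Units: concentrations nM, first-order rates 1/h. ``stress_multiplier``
    scales the sustained cortisol baseline under chronic stress.
    """

    kd_mr_nm: float = 1.0
    kd_gr_nm: float = 10.0
    kd_pxr_nm: float = 10_000.0          # 10 μM
    cortisol_baseline_nm: float = 30.0   # free plasma cortisol, homeostasis
    stress_multiplier: float = 5.0
    gr_total_ref_nm: float = 100.0
    pxr_total_ref_nm: float = 100.0
    cyp3a4_ref_nm: float = 705.0
    k_deg_gr_per_h: float = 0.2
    k_deg_pxr_per_h: float = 0.2
    k_deg_cyp_per_h: float = 0.06
    feedback_k_nm: float = 200.0     # activated-GR level halving GR synthesis
    feedforward_k_nm: float = 50.0   # activated-GR half-saturation of PXR induction
    feedforward_fold: float = 4.0    # max fold induction of PXR synthesis
    cyp_drive_k_nm: float = 2.0      # half-saturation of the CYP3A4 synthesis drive
    cyp_gr_weight: float = 0.05      # activated-GR weight in the CYP3A4 drive

    def __post_init__(self):
        for name in ("kd_mr_nm", "kd_gr_nm", "kd_pxr_nm", "k_deg_gr_per_h",
                     "k_deg_pxr_per_h", "k_deg_cyp_per_h", "cortisol_baseline_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cyp3a4_ref_nm <= 0:
            raise ValueError("cyp3a4_ref_nm must be > 0")

    def replace(self, **kw) -> "GRNParameters":
        return replace(self, **kw)

    # -- back-calculated synthesis rates (homeostatic fixed point) -----
    def _baseline_activated(self) -> Tuple[float, float]:
        c0 = self.cortisol_baseline_nm
        gra0 = self.gr_total_ref_nm * receptor_occupancy(c0, self.kd_gr_nm)
        pxra0 = self.pxr_total_ref_nm * receptor_occupancy(c0, self.kd_pxr_nm)
        return gra0, pxra0

    def _repression(self, gra: float) -> float:
        return 1.0 / (1.0 + gra / self.feedback_k_nm)

    def _induction(self, gra: float) -> float:
        return 1.0 + (self.feedforward_fold - 1.0) * gra / (gra + self.feedforward_k_nm)

    def _cyp_drive(self, pxra: float, gra: float) -> float:
        d = pxra + self.cyp_gr_weight * gra
        return d / (self.cyp_drive_k_nm + d)

    @property
    def k_syn_gr(self) -> float:
        gra0, _ = self._baseline_activated()
        return self.k_deg_gr_per_h * self.gr_total_ref_nm / self._repression(gra0)

    @property
    def k_syn_pxr(self) -> float:
        gra0, _ = self._baseline_activated()
        return self.k_deg_pxr_per_h * self.pxr_total_ref_nm / self._induction(gra0)

    @property
    def k_syn_cyp(self) -> float:
        gra0, pxra0 = self._baseline_activated()
        return self.k_deg_cyp_per_h * self.cyp3a4_ref_nm / self._cyp_drive(pxra0, gra0)


@dataclass(frozen=True)
class GRNState:
    """Derived view of the regulatory state at one time point (nM)."""

    cortisol_nm: float
    gr_total_nm: float
    pxr_total_nm: float
    cyp3a4_nm: float
    kd_gr_nm: float = 10.0
    kd_pxr_nm: float = 10_000.0

    @property
    def gr_activated_nm(self) -> float:
        return self.gr_total_nm * receptor_occupancy(self.cortisol_nm, self.kd_gr_nm)

    @property
    def gr_free_nm(self) -> float:
        return self.gr_total_nm - self.gr_activated_nm

    @property
    def pxr_activated_nm(self) -> float:
        return self.pxr_total_nm * receptor_occupancy(self.cortisol_nm, self.kd_pxr_nm)

    @property
    def pxr_free_nm(self) -> float:
        return self.pxr_total_nm - self.pxr_activated_nm


def grn_steady_state(params: GRNParameters) -> np.ndarray:
    """Homeostatic state vector [GR_total, PXR_total, CYP3A4] (nM)."""
    return np.array([params.gr_total_ref_nm, params.pxr_total_ref_nm,
                     params.cyp3a4_ref_nm])


def grn_derivatives(
    state: Sequence[float],
    t: float,
    params: GRNParameters,
    cortisol_input: Callable[[float], float] | float,
) -> np.ndarray:
    """d/dt of [GR_total, PXR_total, CYP3A4] under a cortisol forcing.

    At baseline cortisol and the reference state all derivatives vanish by
    construction of the synthesis rates.
    """
    cort = cortisol_input(t) if callable(cortisol_input) else float(cortisol_input)
    gr_tot, pxr_tot, cyp = (max(float(x), 0.0) for x in state)
    gra = gr_tot * receptor_occupancy(cort, params.kd_gr_nm)
    pxra = pxr_tot * receptor_occupancy(cort, params.kd_pxr_nm)
    d_gr = params.k_syn_gr * params._repression(gra) - params.k_deg_gr_per_h * gr_tot
    d_pxr = params.k_syn_pxr * params._induction(gra) - params.k_deg_pxr_per_h * pxr_tot
    d_cyp = params.k_syn_cyp * params._cyp_drive(pxra, gra) - params.k_deg_cyp_per_h * cyp
    return np.array([d_gr, d_pxr, d_cyp])


def cortisol_schedule(
    kind: str,
    params: GRNParameters,
    boluses: Sequence[Tuple[float, float, float]] = (),
) -> Callable[[float], float]:
    """Cortisol forcing function (nM vs h).

    ``homeostatic``: constant baseline. ``chronic_stress``: sustained
    elevated baseline (baseline × stress_multiplier), optionally with
    repeated boluses given as (time_h, amplitude_nm, decay_h) adding
    ``amplitude·exp(-(t-t0)/decay)`` for t ≥ t0. The chronic-stress profile
    never falls below the homeostatic baseline.
    """
    base = params.cortisol_baseline_nm
    if kind == "homeostatic":
        return lambda t: base
    if kind == "chronic_stress":
        elevated = base * params.stress_multiplier
        bol = tuple(boluses)

        def profile(t: float) -> float:
            c = elevated
            for t0, amp, tau in bol:
                if t >= t0:
                    c += amp * np.exp(-(t - t0) / tau)
            return c

        return profile
    raise ValueError(f"unknown cortisol schedule kind {kind!r}")


def simulate_grn(
    params: GRNParameters,
    t_grid: Sequence[float],
    cortisol_input: Callable[[float], float] | float | None = None,
    y0: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the regulatory ODEs alone; returns (t_grid, states array)."""
    from scipy.integrate import solve_ivp

    t_grid = np.asarray(t_grid, dtype=float)
    if cortisol_input is None:
        cortisol_input = cortisol_schedule("homeostatic", params)
    y0 = np.asarray(y0 if y0 is not None else grn_steady_state(params), dtype=float)
    sol = solve_ivp(
        lambda t, y: grn_derivatives(y, t, params, cortisol_input),
        (t_grid[0], t_grid[-1]), y0, t_eval=t_grid, method="LSODA",
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"GRN integration failed: {sol.message}")
    return t_grid, sol.y.T
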