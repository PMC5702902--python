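"""Quasi-steady-state coupling loop: inhibition transform, feedforward bound
scaling, mode semantics, direction checks, uniqueness diagnostics."""

import numpy as np
import pytest

from hepaflux.coupling import (
    CompetitiveInhibition,
    CouplingConfig,
    CouplingConfigError,
    FeedbackLink,
    FeedforwardLink,
    MultiscaleModel,
    ScalingTable,
    apply_feedforward,
    competitive_inhibition_activity,
    uniqueness_guard,
)
from hepaflux.fixtures import make_mini_liver, make_parallel_paths
from hepaflux.grn import GRNParameters, cortisol_schedule
from hepaflux.network import fba, knockout_reactions
from hepaflux.pbpk import Dose, PBPKParameters, simulate


def _fast_pbpk(**kw):
    defaults = dict(doses=[Dose("iv_bolus", 500.0)])
    defaults.update(kw)
    return PBPKParameters(**defaults)


def _model(net, obj, z_ref, **kw):
    defaults = dict(
        network=net,
        objective=obj,
        pbpk_params=_fast_pbpk(),
        feedback=FeedbackLink(table=ScalingTable(mode="proportional", z_ref=z_ref)),
        config=CouplingConfig(mode="full", dt_h=0.25),
    )
    defaults.update(kw)
    return MultiscaleModel(**defaults)


class TestInhibitionTransform:
    def test_no_inhibitor_full_activity(self):
        assert competitive_inhibition_activity(0.0, 50.0) == 1.0

    def test_half_activity_at_twice_ki(self):
        # I = 2·Ki -> v/v0 = 1/(1 + 2Ki/(2Ki)) = 1/2
        assert competitive_inhibition_activity(100.0, 50.0) == pytest.approx(0.5)

    def test_two_thirds_activity_at_ki(self):
        assert competitive_inhibition_activity(50.0, 50.0) == pytest.approx(2.0 / 3.0)

    def test_maps_into_unit_interval(self):
        for i in (0.0, 1.0, 1e3, 1e9):
            assert 0.0 < competitive_inhibition_activity(i, 50.0) <= 1.0

    def test_invalid_ki_rejected(self):
        with pytest.raises(ValueError):
            competitive_inhibition_activity(1.0, 0.0)


class TestFeedforward:
    def _link(self, rid="FTHLDH", ki=50.0, mw=151.2):
        return FeedforwardLink(reaction_id=rid,
                               transform=CompetitiveInhibition(ki_mm=ki),
                               molar_mass_g_per_mol=mw)

    def test_fifty_percent_activity_halves_upper_bound(self, mini_liver):
        net, _ = mini_liver
        net = net.copy()
        net.reaction("FTHLDH").upper_bound = 1.0
        link = self._link(mw=1.0)  # conc in mg/L == mM for unit molar mass
        out = apply_feedforward(net, [link], {("metabolite", "liver"): 100.0})
        assert out.reaction("FTHLDH").upper_bound == pytest.approx(0.5)
        assert out.reaction("FTHLDH").lower_bound == 0.0

    def test_full_activity_leaves_bounds(self, mini_liver):
        net, _ = mini_liver
        out = apply_feedforward(net, [self._link()], {("metabolite", "liver"): 0.0})
        assert out.reaction("FTHLDH").upper_bound == net.reaction("FTHLDH").upper_bound

    def test_scaling_never_compounds_across_steps(self, mini_liver):
        net, _ = mini_liver
        link = self._link(mw=1.0)
        conc = {("metabolite", "liver"): 100.0}
        once = apply_feedforward(net, [link], conc)
        twice = apply_feedforward(net, [link], conc)  # always from wild type
        assert once.reaction("FTHLDH").upper_bound == \
            twice.reaction("FTHLDH").upper_bound

    def test_negative_lower_bound_scaled_symmetrically(self, mini_liver):
        net, _ = mini_liver
        link = self._link(rid="SHMT", mw=1.0)
        out = apply_feedforward(net, [link], {("metabolite", "liver"): 100.0})
        assert out.reaction("SHMT").lower_bound == pytest.approx(-5.0)
        assert out.reaction("SHMT").upper_bound == pytest.approx(5.0)

    def test_unknown_reaction_is_config_error(self, mini_liver):
        net, _ = mini_liver
        with pytest.raises(CouplingConfigError):
            apply_feedforward(net, [self._link(rid="nope")], {})


class TestScalingTable:
    def test_proportional_mode(self):
        sf = ScalingTable(mode="proportional", z_ref=2.0)
        assert sf(1.0) == 0.5 and sf(2.0) == 1.0 and sf(-0.1) == 0.0

    def test_lookup_linear_and_step(self):
        bp = [(0.0, 0.0), (1.0, 0.5), (2.0, 1.0)]
        lin = ScalingTable(mode="lookup", breakpoints=bp, interpolation="linear")
        stp = ScalingTable(mode="lookup", breakpoints=bp, interpolation="step")
        assert lin(0.5) == pytest.approx(0.25)
        assert stp(0.5) == 0.0 and stp(1.0) == pytest.approx(0.5)
        assert lin(10.0) == 1.0

    def test_non_monotone_table_rejected(self):
        with pytest.raises(CouplingConfigError):
            ScalingTable(mode="lookup", breakpoints=[(0, 1.0), (1, 0.5)])


class TestUniquenessGuard:
    def test_symmetric_paths_fire_on_flux_level_coupling(self, parallel):
        net, obj = parallel
        wide = uniqueness_guard(net, obj, ["Rpath1"])
        assert "Rpath1" in wide

    def test_single_path_silent(self, chain3):
        net, obj = chain3
        assert uniqueness_guard(net, obj, ["R2"]) == {}

    def test_strict_mode_raises(self, parallel):
        net, obj = parallel
        with pytest.raises(RuntimeError, match="non-unique"):
            uniqueness_guard(net, obj, ["Rpath2"], strict=True)


class TestQSSLoop:
    def test_feedback_only_with_constant_network_equals_plain_pbpk(self, mini_liver):
        net, obj = mini_liver
        z_wt = fba(net, obj).z
        m = _model(net, obj, z_ref=2.0,
                   config=CouplingConfig(mode="feedback_only", dt_h=0.5))
        traj = m.simulate(12.0)
        sf_const = z_wt / 2.0
        tg = traj.times_h
        plain = simulate(m.pbpk_params, tg,
                         scale_series=(np.ones(len(tg) - 1),
                                       np.full(len(tg) - 1, sf_const)))
        a = traj.pbpk.concentration("metabolite", "liver")
        b = plain.concentration("metabolite", "liver")
        assert np.abs(a - b).max() <= 1e-6 * max(b.max(), 1e-12)
        assert np.all(traj.sf == sf_const)

    def test_feedforward_only_pbpk_equals_uncoupled_while_z_logged(self, mini_liver):
        net, obj = mini_liver
        net = net.copy()
        net.reaction("FTHLDH").upper_bound = 1.0  # make inhibition bite z
        link = FeedforwardLink(reaction_id="FTHLDH",
                               transform=CompetitiveInhibition(ki_mm=0.01),
                               molar_mass_g_per_mol=151.2)
        m = _model(net, obj, z_ref=1.0, feedforward=[link],
                   config=CouplingConfig(mode="feedforward_only", dt_h=0.5))
        traj = m.simulate(12.0)
        assert np.all(traj.sf == 1.0)  # step 3 skipped
        assert traj.z.min() < traj.z.max()  # but z(t) varies as an output
        tg = traj.times_h
        plain = simulate(m.pbpk_params, tg)
        a = traj.pbpk.concentration("metabolite", "liver")
        b = plain.concentration("metabolite", "liver")
        assert np.abs(a - b).max() <= 1e-6 * max(b.max(), 1e-12)

    def test_z_nonincreasing_while_inhibitor_rises(self, mini_liver):
        net, obj = mini_liver
        net = net.copy()
        net.reaction("FTHLDH").upper_bound = 1.0
        link = FeedforwardLink(reaction_id="FTHLDH",
                               transform=CompetitiveInhibition(ki_mm=0.01),
                               molar_mass_g_per_mol=151.2)
        m = _model(net, obj, z_ref=1.0, feedforward=[link],
                   config=CouplingConfig(mode="full", dt_h=0.25))
        traj = m.simulate(12.0)
        conc = traj.pbpk.concentration("metabolite", "liver")
        rising = np.diff(conc) > 0
        dz = np.diff(traj.z)
        assert np.all(dz[rising] <= 1e-9)
        assert traj.z.min() < traj.z.max()

    def test_sf_audit_trail_reproducible_from_logged_z(self, mini_liver):
        net, obj = mini_liver
        m = _model(net, obj, z_ref=1.0,
                   config=CouplingConfig(mode="full", dt_h=0.5))
        traj = m.simulate(6.0)
        table = m.feedback.table
        assert np.allclose(traj.sf, [table(z) for z in traj.z])

    def test_neutral_links_match_uncoupled_cosimulation(self, mini_liver):
        """With every transform ≡ 1 and SF ≡ 1 the multiscale run equals the
        plain PBPK+GRN co-simulation (coupling neutrality)."""
        net, obj = mini_liver
        gp = GRNParameters()
        link = FeedforwardLink(reaction_id="FTHLDH", transform=lambda c: 1.0)
        m = _model(net, obj, z_ref=1.0, feedforward=[link], grn_params=gp,
                   config=CouplingConfig(mode="full", dt_h=0.5))
        traj = m.simulate(12.0)
        assert np.all(traj.sf == 1.0) and np.all(traj.z == traj.z[0])
        tg = traj.times_h
        plain = simulate(m.pbpk_params, tg)  # GRN holds cyp scale at exactly 1
        for sp, comp in (("parent", "venous"), ("metabolite", "liver")):
            a, b = traj.pbpk.concentration(sp, comp), plain.concentration(sp, comp)
            assert np.abs(a - b).max() <= 1e-6 * max(b.max(), 1e-12)

    def test_infeasible_mid_run_aborts_with_step_index(self, chain3):
        net, obj = chain3
        dead = knockout_reactions(net, ["R2"])
        # essentiality-style abort: force infeasibility via an impossible
        # extra demand (lb > achievable) rather than z = 0
        bad = net.copy()
        bad.reaction("R2").lower_bound = 0.5
        bad.reaction("R2").upper_bound = 0.5
        bad.reaction("R1").upper_bound = 0.0
        m = _model(bad, obj, z_ref=1.0)
        with pytest.raises(RuntimeError, match="step 0"):
            m.simulate(1.0)


@pytest.fixture(scope="module")
def runs():
    net, obj = make_mini_liver()
    z_wt = fba(net, obj).z
    gp = GRNParameters()
    kw = dict(pbpk_params=_fast_pbpk(),
              feedback=FeedbackLink(table=ScalingTable(mode="proportional",
                                                       z_ref=z_wt)))
    cfg = CouplingConfig(mode="full", dt_h=0.25)
    base = MultiscaleModel(network=net, objective=obj, grn_params=gp,
                           config=cfg, **kw).simulate(24.0)
    ko = MultiscaleModel(network=knockout_reactions(net, ["MTHFD"]),
                         objective=obj, grn_params=gp, config=cfg,
                         **kw).simulate(24.0)
    stress = MultiscaleModel(network=net, objective=obj, grn_params=gp,
                             config=cfg,
                             cortisol=cortisol_schedule("chronic_stress", gp),
                             **kw).simulate(24.0)
    return base, ko, stress


class TestDirectionChecks:
    def test_essential_gsh_knockout_raises_metabolite_peak(self, runs):
        base, ko, _ = runs
        assert ko.liver_metabolite_cmax() > base.liver_metabolite_cmax()
        assert np.all(ko.sf == 0.0)  # GSH production abolished -> SF = 0

    def test_chronic_stress_raises_metabolite_peak(self, runs):
        base, _, stress = runs
        assert stress.liver_metabolite_cmax() > base.liver_metabolite_cmax()
        assert stress.cyp_scale[-1] > 1.0

    def test_zero_dose_all_series_zero(self, mini_liver):
        net, obj = mini_liver
        m = _model(net, obj, z_ref=1.0,
                   pbpk_params=_fast_pbpk(doses=[Dose("iv_bolus", 0.0)]))
        traj = m.simulate(2.0)
        assert np.abs(traj.pbpk.states).max() == 0.0

    def test_halving_dt_changes_cmax_below_one_percent(self, mini_liver):
        net, obj = mini_liver
        gp = GRNParameters()
        cmax = {}
        for dt in (5.0 / 60.0, 2.5 / 60.0):
            m = _model(net, obj, z_ref=1.0, grn_params=gp,
                       config=CouplingConfig(mode="full", dt_h=dt))
            cmax[dt] = m.simulate(6.0).liver_metabolite_cmax()
        rel = abs(cmax[5.0 / 60.0] - cmax[2.5 / 60.0]) / cmax[2.5 / 60.0]
        assert rel < 0.01
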