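"""Constraint-based kernel: stoichiometric matrix, FBA, knockouts,
essentiality, variability, sampling, exchange bounds."""

import numpy as np
import pytest

from _lp_oracle import oracle_fba
from hepaflux.fixtures import (
    make_fig1_like,
    make_linear_chain,
    make_parallel_paths,
    make_random_network,
)
from hepaflux.network import (
    BALANCE_TOL,
    Metabolite,
    MetabolicNetwork,
    NetworkStructureError,
    Objective,
    Reaction,
    apply_exchange_bounds,
    build_stoichiometric_matrix,
    essentiality_scan,
    fba,
    flux_variability,
    gene_knockout,
    is_exchange,
    knockout_reactions,
    sample_flux_space,
)


def _net(mets, rxns):
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


def _check_feasible(net, sol):
    S = build_stoichiometric_matrix(net)
    v = np.array([sol.v[r] for r in net.reaction_ids])
    assert np.max(np.abs(S @ v)) <= BALANCE_TOL
    for r in net.reactions:
        assert r.lower_bound - BALANCE_TOL <= sol.v[r.id] <= r.upper_bound + BALANCE_TOL


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------

class TestStoichiometricMatrix:
    def test_single_internal_reaction_column(self):
        net = _net([Metabolite("A"), Metabolite("B")],
                   [Reaction(id="r", stoichiometry={"A": -1, "B": 1})])
        S = build_stoichiometric_matrix(net)
        assert S.shape == (2, 1)
        assert dict(zip(net.metabolite_ids, S[:, 0])) == {"A": -1, "B": 1}

    def test_external_metabolites_excluded_from_rows(self):
        net = _net(
            [Metabolite("Axt", is_external=True), Metabolite("B")],
            [Reaction(id="r", stoichiometry={"Axt": -1, "B": 1})],
        )
        S = build_stoichiometric_matrix(net)
        assert S.shape == (1, 1)
        assert S[0, 0] == 1  # only the internal product B is balanced

    def test_coefficient_placement(self):
        net = _net(
            [Metabolite(m) for m in "ABC"],
            [Reaction(id="r", stoichiometry={"A": -2, "B": -1, "C": 1},
                      lower_bound=0, upper_bound=1)],
        )
        S = build_stoichiometric_matrix(net)
        assert list(S[:, 0]) == [-2, -1, 1]

    def test_unresolved_metabolite_names_the_reaction(self):
        with pytest.raises(NetworkStructureError, match="rbad"):
            _net([Metabolite("A")],
                 [Reaction(id="rbad", stoichiometry={"A": -1, "ghost": 1})])


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

class TestFBA:
    def test_single_path_chain_hits_bound(self, chain3):
        net, obj = chain3
        sol = fba(net, obj)
        assert sol.optimal
        assert sol.z == pytest.approx(1.0, abs=1e-9)
        _check_feasible(net, sol)

    def test_blocked_path_gives_zero_objective(self, chain3):
        net, obj = chain3
        sol = fba(knockout_reactions(net, ["R2"]), obj)
        # z = 0 with optimal status: the metabolic function is infeasible
        assert sol.optimal and sol.z == pytest.approx(0.0, abs=1e-9)

    def test_unbounded_objective_reported_as_status(self):
        # a reversible 2-cycle with free bounds carries unbounded cyclic flux
        net = _net(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction(id="f", stoichiometry={"A": -1, "B": 1},
                         lower_bound=-np.inf, upper_bound=np.inf),
                Reaction(id="b", stoichiometry={"B": -1, "A": 1},
                         lower_bound=-np.inf, upper_bound=np.inf),
            ],
        )
        sol = fba(net, Objective({"f": 1.0}))
        assert sol.status == "unbounded"
        assert np.isnan(sol.z)

    def test_objective_must_reference_existing_reactions(self, chain3):
        net, _ = chain3
        with pytest.raises(KeyError):
            fba(net, Objective({"nope": 1.0}))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_vertex_enumeration_oracle_on_random_networks(self, seed):
        net, obj = make_random_network(n_reactions=7, seed=seed)
        z_oracle, _ = oracle_fba(net, obj)
        sol = fba(net, obj)
        assert sol.optimal
        assert sol.z == pytest.approx(z_oracle, rel=1e-8, abs=1e-8)
        _check_feasible(net, sol)

    @pytest.mark.parametrize("seed", range(6))
    def test_bound_tightening_never_increases_optimum(self, seed):
        rng = np.random.default_rng(seed)
        net, obj = make_random_network(n_reactions=7, seed=100 + seed)
        z_prev = fba(net, obj).z
        current = net
        for _ in range(4):
            tightened = current.copy()
            rxn = tightened.reactions[rng.integers(len(tightened.reactions))]
            width = rxn.upper_bound - rxn.lower_bound
            shrink = 0.3 * width * rng.random()
            if rng.random() < 0.5:
                rxn.upper_bound -= shrink
            else:
                rxn.lower_bound += shrink
            sol = fba(tightened, obj)
            z_new = sol.z if sol.optimal else -np.inf
            assert z_new <= z_prev + 1e-8
            current, z_prev = tightened, z_new


# ---------------------------------------------------------------------------
# knockouts
# ---------------------------------------------------------------------------

class TestKnockouts:
    def test_empty_knockout_is_identity(self, chain3):
        net, obj = chain3
        out = knockout_reactions(net, [])
        assert [(r.lower_bound, r.upper_bound) for r in out.reactions] == \
            [(r.lower_bound, r.upper_bound) for r in net.reactions]

    def test_input_network_unmodified(self, chain3):
        net, _ = chain3
        knockout_reactions(net, ["R1"])
        assert net.reaction("R1").upper_bound == 1.0

    def test_unknown_id_raises(self, chain3):
        net, _ = chain3
        with pytest.raises(KeyError):
            knockout_reactions(net, ["nope"])

    def test_essential_import_knockout_abolishes_objective(self, fig1):
        net, obj = fig1
        assert fba(knockout_reactions(net, ["R1"]), obj).z == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("rid", ["R4", "R5", "R6", "R7", "R8"])
    def test_any_other_single_deletion_leaves_optimum(self, fig1, rid):
        net, obj = fig1
        assert fba(knockout_reactions(net, [rid]), obj).z == pytest.approx(1.0, abs=1e-9)

    def test_gene_and_semantics_disable(self):
        net = _net(
            [Metabolite("Axt", is_external=True), Metabolite("B")],
            [Reaction(id="r", stoichiometry={"Axt": -1, "B": 1}, gpr="g1 AND g2")],
        )
        assert gene_knockout(net, ["g1"]).reaction("r").upper_bound == 0.0

    def test_gene_or_semantics_keep_active(self):
        net = _net(
            [Metabolite("Axt", is_external=True), Metabolite("B")],
            [Reaction(id="r", stoichiometry={"Axt": -1, "B": 1}, gpr="g1 OR g2")],
        )
        assert gene_knockout(net, ["g1"]).reaction("r").upper_bound > 0

    def test_gene_knockout_commutes_with_reaction_knockout(self, mini_liver):
        """Disabling genes then solving equals disabling the GPR-false
        reactions directly then solving, for every single-gene deletion."""
        net, obj = mini_liver
        for gene in sorted(net.genes):
            via_genes = fba(gene_knockout(net, [gene]), obj)
            disabled = [
                r.id for r in net.reactions
                if r.gpr and not r.gpr_rule.evaluate(knocked_out={gene})
            ]
            via_reactions = fba(knockout_reactions(net, disabled), obj)
            assert via_genes.z == pytest.approx(via_reactions.z, abs=1e-9)


# ---------------------------------------------------------------------------
# essentiality
# ---------------------------------------------------------------------------

class TestEssentiality:
    def test_linear_chain_every_reaction_essential(self, chain3):
        net, obj = chain3
        records = essentiality_scan(net, obj)
        assert all(r.z_relative == pytest.approx(0.0, abs=1e-9) for r in records)
        assert all(r.influences_objective for r in records)

    def test_parallel_paths_are_redundant(self, parallel):
        net, obj = parallel
        by_id = {r.reaction_id: r for r in essentiality_scan(net, obj)}
        for rid in ("Rpath1", "Rpath2"):
            assert by_id[rid].z_relative == pytest.approx(1.0, abs=1e-9)
            assert not by_id[rid].influences_objective

    def test_matches_exhaustive_oracle_loop(self):
        net, obj = make_random_network(n_reactions=10, seed=7)
        records = {r.reaction_id: r for r in essentiality_scan(net, obj)}
        for rid in net.reaction_ids:
            z_ko, _ = oracle_fba(knockout_reactions(net, [rid]), obj)
            z_ko = max(z_ko or 0.0, 0.0)
            assert records[rid].z_knockout == pytest.approx(z_ko, rel=1e-7, abs=1e-7)

    def test_scan_invariant_to_reaction_ordering(self, fig1):
        net, obj = fig1
        fwd = essentiality_scan(net, obj)
        rev = essentiality_scan(net, obj, reaction_ids=net.reaction_ids[::-1])
        assert {r.reaction_id: r.z_relative for r in fwd} == \
            {r.reaction_id: r.z_relative for r in rev}

    def test_refused_when_wild_type_infeasible(self, chain3):
        net, obj = chain3
        dead = knockout_reactions(net, ["R1"])
        with pytest.raises(RuntimeError, match="refused|not positive"):
            essentiality_scan(dead, obj)


# ---------------------------------------------------------------------------
# flux variability
# ---------------------------------------------------------------------------

class TestFluxVariability:
    def test_single_path_all_ranges_degenerate(self, chain3):
        net, obj = chain3
        for lo, hi in flux_variability(net, obj).values():
            assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_paths_range_over_full_split(self, parallel):
        net, obj = parallel
        ranges = flux_variability(net, obj)
        for rid in ("Rpath1", "Rpath2"):
            assert ranges[rid][0] == pytest.approx(0.0, abs=1e-8)
            assert ranges[rid][1] == pytest.approx(1.0, abs=1e-8)

    def test_essential_import_pinned_while_alternatives_vary(self, fig1):
        net, obj = fig1
        ranges = flux_variability(net, obj)
        lo, hi = ranges["R1"]
        assert hi - lo == pytest.approx(0.0, abs=1e-8)
        assert ranges["R4"][1] - ranges["R4"][0] == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_per_reaction_oracle_vertices(self, fig1):
        """FVA extrema at the optimum match the min/max over the oracle's
        enumerated optimal vertices."""
        net, obj = fig1
        _, optima = oracle_fba(net, obj)
        V = np.array(optima)
        ranges = flux_variability(net, obj)
        for j, rid in enumerate(net.reaction_ids):
            assert ranges[rid][0] == pytest.approx(V[:, j].min(), abs=1e-7)
            assert ranges[rid][1] == pytest.approx(V[:, j].max(), abs=1e-7)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_samples_satisfy_balance_and_bounds(self, fig1):
        net, _ = fig1
        S = build_stoichiometric_matrix(net)
        X = sample_flux_space(net, n_samples=200, seed=42)
        assert np.max(np.abs(S @ X.T)) <= 1e-6
        lb = np.array([r.lower_bound for r in net.reactions])
        ub = np.array([r.upper_bound for r in net.reactions])
        assert np.all(X >= lb - 1e-9) and np.all(X <= ub + 1e-9)

    def test_symmetric_paths_split_evenly(self, parallel):
        net, _ = parallel
        X = sample_flux_space(net, n_samples=2000, seed=1)
        idx = {rid: i for i, rid in enumerate(net.reaction_ids)}
        total = X[:, idx["Rpath1"]] + X[:, idx["Rpath2"]]
        share = X[total > 1e-9, idx["Rpath1"]] / total[total > 1e-9]
        # symmetry ⇒ mean share 1/2; generous Monte-Carlo interval
        assert abs(share.mean() - 0.5) < 0.05

    def test_disabled_reaction_sampled_at_zero(self, fig1):
        net, _ = fig1
        net_ko = knockout_reactions(net, ["R4"])
        X = sample_flux_space(net_ko, n_samples=100, seed=3)
        j = net_ko.reaction_ids.index("R4")
        assert np.max(np.abs(X[:, j])) <= 1e-9

    def test_reproducible_under_fixed_seed(self, fig1):
        net, _ = fig1
        a = sample_flux_space(net, n_samples=50, seed=9)
        b = sample_flux_space(net, n_samples=50, seed=9)
        assert np.array_equal(a, b)

    def test_empty_region_is_explicit_error(self):
        net = _net(
            [Metabolite("A")],
            [
                Reaction(id="in_", stoichiometry={"A": 1}, lower_bound=1,
                         upper_bound=2),
                Reaction(id="out", stoichiometry={"A": -1}, lower_bound=0,
                         upper_bound=0.5),
            ],
        )
        with pytest.raises(RuntimeError, match="empty"):
            sample_flux_space(net, n_samples=5, seed=0)


# ---------------------------------------------------------------------------
# exchange bounds
# ---------------------------------------------------------------------------

class TestExchangeBounds:
    def test_empty_table_without_restriction_is_identity(self, fig1):
        net, _ = fig1
        out = apply_exchange_bounds(net, {}, restrict_to_listed=False)
        assert [(r.lower_bound, r.upper_bound) for r in out.reactions] == \
            [(r.lower_bound, r.upper_bound) for r in net.reactions]

    def test_listed_exchange_gets_table_bounds(self, fig1):
        net, _ = fig1
        out = apply_exchange_bounds(net, {"R1": (-2.5, 0.0)})
        assert (out.reaction("R1").lower_bound, out.reaction("R1").upper_bound) == (-2.5, 0.0)

    def test_non_exchange_row_skipped_with_warning(self, fig1, caplog):
        net, _ = fig1
        with caplog.at_level("WARNING"):
            out = apply_exchange_bounds(net, {"R5": (0.0, 0.1)})
        assert "non-exchange" in caplog.text
        assert out.reaction("R5").upper_bound == 1.0  # untouched

    def test_restriction_closes_unlisted_import_and_starves_objective(self, chain3):
        net, obj = chain3
        # R1 (import) unlisted -> closed; R3 (export) kept open
        out = apply_exchange_bounds(net, {"R3": (0.0, 1.0)}, restrict_to_listed=True)
        assert (out.reaction("R1").lower_bound, out.reaction("R1").upper_bound) == (0.0, 0.0)
        assert fba(out, obj).z == pytest.approx(0.0, abs=1e-9)

    def test_structural_exchange_detection(self, fig1):
        net, _ = fig1
        assert is_exchange(net, net.reaction("R1"))     # source: only produces A
        assert is_exchange(net, net.reaction("R4"))     # sink: only consumes A
        assert not is_exchange(net, net.reaction("R5"))  # A -> B conversion
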