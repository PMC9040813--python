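"""FBA and its second-stage variants against independent oracles."""

import numpy as np
import pytest

from methanoflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    essentiality_scan,
    gene_knockout_growth,
    model_qc,
    phase_plane,
    prune_gapfill_reactions,
    solve_cycle_free,
    solve_fba,
    solve_linear_moma,
)
from methanoflux.model import GeneRule

from conftest import brute_force_fba, random_small_model


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------


def test_bound_limited_chain(chain_model):
    state = solve_fba(chain_model)
    assert state.ok
    assert state.objective_value == pytest.approx(10.0)
    assert state.flux["EX_a"] == pytest.approx(-10.0)


def test_all_exchanges_closed_means_no_growth():
    from methanoflux import ReducedNetworkConfig, apply_medium, build_reduced_network

    # without the maintenance demand the starved model is exactly at rest;
    # with it (default) the closed medium is outright infeasible
    resting = apply_medium(build_reduced_network(ReducedNetworkConfig(ngam=0.0)), {})
    state = solve_fba(resting)
    assert state.ok
    assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    starved = apply_medium(build_reduced_network(), {})
    assert solve_fba(starved).status == "infeasible"


def test_reduced_model_ratio_in_feasible_band(fresh_reduced_model):
    m = fresh_reduced_model
    m.reactions["EX_ch4_e"].bounds = (-10, 0)
    m.reactions["EX_o2_e"].bounds = (-30, 0)
    state = solve_fba(m)
    assert state.ok and state.objective_value > 0
    ratio = state.flux["EX_o2_e"] / state.flux["EX_ch4_e"]
    assert 1.0 <= ratio <= 2.5


def test_infeasible_model_reports_honestly():
    model = MetabolicModel(metabolites=[Metabolite("a")])
    model.add_reaction(Reaction("make", {"a": 1}, 5, 10))  # forced production
    model.add_reaction(Reaction("use", {"a": -1}, 0, 1))  # insufficient sink
    model.objective_reaction_id = "use"
    state = solve_fba(model)
    assert state.status == "infeasible"
    assert state.flux == {}


def test_fba_matches_brute_force_enumeration():
    """HiGHS optimum equals exhaustive vertex enumeration on 50 random
    small bounded models."""
    rng = np.random.default_rng(1234)
    checked = 0
    while checked < 50:
        model = random_small_model(rng)
        state = solve_fba(model)
        assert state.ok, "bounded feasible LP must solve"
        expected = brute_force_fba(model, model.objective_reaction_id)
        assert state.objective_value == pytest.approx(expected, abs=1e-6)
        checked += 1


# ---------------------------------------------------------------------------
# cycle-free FBA
# ---------------------------------------------------------------------------


def make_cycle_model() -> MetabolicModel:
    """A productive chain with a 2-reaction futile cycle a<->b superimposed.

    cyc_fwd/cyc_rev are a reversible pair whose simultaneous operation moves
    nothing but can carry arbitrary circulating flux.
    """
    model = MetabolicModel(
        metabolites=[Metabolite("a"), Metabolite("b"), Metabolite("x", compartment="e"),
                     Metabolite("y", compartment="e")],
    )
    model.add_reaction(Reaction("EX_x", {"x": -1}, -5, 0, is_exchange=True))
    model.add_reaction(Reaction("in_a", {"x": -1, "a": 1}, 0, 1000))
    model.add_reaction(Reaction("cyc_fwd", {"a": -1, "b": 1}, 0, 1000))
    model.add_reaction(Reaction("cyc_rev", {"b": -1, "a": 1}, 0, 1000))
    model.add_reaction(Reaction("out_b", {"b": -1, "y": 1}, 0, 1000))
    model.add_reaction(Reaction("EX_y", {"y": -1}, 0, 1000, is_exchange=True))
    model.objective_reaction_id = "EX_y"
    return model


def test_cffba_drains_futile_cycle():
    model = make_cycle_model()
    # hand enumeration of loop-free vertices: the only productive route is
    # x -> a -> b -> y at flux 5; any added circulation a<->b is a pure loop
    state = solve_cycle_free(model)
    assert state.ok
    assert state.objective_value == pytest.approx(5.0)
    assert state.flux["cyc_fwd"] == pytest.approx(5.0, abs=1e-6)
    assert state.flux["cyc_rev"] == pytest.approx(0.0, abs=1e-6)
    assert state.flux["EX_x"] == pytest.approx(-5.0)


def test_cffba_preserves_exchanges_objective_and_shrinks_internals(fresh_reduced_model):
    m = fresh_reduced_model
    m.reactions["EX_o2_e"].bounds = (-15, 0)
    fba = solve_fba(m)
    cf = solve_cycle_free(m)
    assert cf.ok
    assert cf.objective_value == pytest.approx(fba.objective_value, abs=1e-6)
    exchange_ids = [r.id for r in m.exchanges()]
    for rid in exchange_ids:
        assert cf.flux[rid] == pytest.approx(fba.flux[rid], abs=1e-6)
    internals = [rid for rid in m.reaction_ids if rid not in exchange_ids]
    for rid in internals:
        assert abs(cf.flux[rid]) <= abs(fba.flux[rid]) + 1e-6
    total = lambda s: sum(abs(s.flux[r]) for r in internals)  # noqa: E731
    assert total(cf) <= total(fba) + 1e-6


def test_cffba_identity_on_loop_free_solution(chain_model):
    fba = solve_fba(chain_model)
    cf = solve_cycle_free(chain_model)
    for rid in chain_model.reaction_ids:
        assert cf.flux[rid] == pytest.approx(fba.flux[rid], abs=1e-9)


# ---------------------------------------------------------------------------
# linear MOMA
# ---------------------------------------------------------------------------


def make_diamond_model() -> MetabolicModel:
    """The 4-reaction diamond: uptake -> two parallel paths a->b -> secretion."""
    model = MetabolicModel(
        metabolites=[Metabolite("a"), Metabolite("b"),
                     Metabolite("s", compartment="e"),
                     Metabolite("t", compartment="e")],
    )
    model.add_reaction(Reaction("EX_s", {"s": -1}, -4, 0, is_exchange=True))
    model.add_reaction(Reaction("upt", {"s": -1, "a": 1}, 0, 1000))
    model.add_reaction(Reaction("p1", {"a": -1, "b": 1}, 0, 1000))
    model.add_reaction(Reaction("p2", {"a": -1, "b": 1}, 0, 1000))
    model.add_reaction(Reaction("sec", {"b": -1, "t": 1}, 0, 1000))
    model.add_reaction(Reaction("EX_t", {"t": -1}, 0, 1000, is_exchange=True))
    model.objective_reaction_id = "EX_t"
    return model


def test_moma_zero_flux_knockout_keeps_reference():
    model = make_diamond_model()
    ref = solve_cycle_free(model)
    unused = "p2" if ref.flux["p1"] > 0 else "p1"
    ko = model.copy()
    ko.reactions[unused].bounds = (0, 0)  # knock out the path carrying no flux
    state = solve_linear_moma(ko, ref)
    assert state.ok
    assert state.moma_distance == pytest.approx(0.0, abs=1e-6)
    for rid in model.reaction_ids:
        assert state.flux[rid] == pytest.approx(ref.flux[rid], abs=1e-6)


def test_moma_rerouting_distance_on_diamond():
    # by vertex enumeration of the diamond: with the used path blocked, the
    # L1-closest feasible state reroutes all flux f through the other path,
    # changing the two parallel reactions by f each: distance = 2 f.
    model = make_diamond_model()
    ref = solve_cycle_free(model)
    flux = ref.objective_value
    assert flux == pytest.approx(4.0)
    used = "p1" if ref.flux["p1"] > 0 else "p2"
    ko = model.copy()
    ko.reactions[used].bounds = (0, 0)
    state = solve_linear_moma(ko, ref)
    assert state.ok
    assert state.objective_value == pytest.approx(flux)
    assert state.moma_distance == pytest.approx(2 * flux, abs=1e-6)


def test_moma_infeasible_knockout_status():
    model = make_diamond_model()
    ref = solve_cycle_free(model)
    ko = model.copy()
    ko.reactions["upt"].bounds = (2, 1000)  # force flux the KO cannot carry
    ko.reactions["sec"].bounds = (0, 0)
    state = solve_linear_moma(ko, ref)
    assert state.status == "infeasible"


def test_moma_sole_methane_sink_knockout_kills_growth(fresh_reduced_model):
    ref = solve_cycle_free(fresh_reduced_model)
    ko = fresh_reduced_model.copy()
    ko.reactions["pmmo_c"].bounds = (0, 0)
    state = solve_linear_moma(ko, ref)
    # with no methane entry the maintenance demand cannot be met, so the
    # knockout is infeasible; a zero-growth optimum would also be acceptable
    assert state.status == "infeasible" or state.objective_value == pytest.approx(
        0.0, abs=1e-6
    )


# ---------------------------------------------------------------------------
# knockouts and essentiality
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("method", ["fba", "moma"])
def test_pmmo_knockout_is_lethal(reduced_model, method):
    result = gene_knockout_growth(reduced_model, "g_pmoA", method)
    assert result.growth_ratio == pytest.approx(0.0, abs=1e-6)


def test_isozyme_pair_tolerates_single_knockout(reduced_model):
    # formate dehydrogenase carries (g_fdsA or g_fdsB)
    result = gene_knockout_growth(reduced_model, "g_fdsA", "fba")
    assert result.growth_ratio == pytest.approx(1.0, abs=1e-4)


def test_unknown_gene_is_an_error(reduced_model):
    with pytest.raises(KeyError):
        gene_knockout_growth(reduced_model, "g_missing", "fba")


def test_essentiality_scan_on_fixture(reduced_model):
    essential = essentiality_scan(reduced_model, "fba")
    # the methane entry point, methanol dehydrogenase and the RuMP entry
    # are all single points of failure in the fixture topology
    for gene in ("g_pmoA", "g_pmoB", "g_pmoC", "g_mxaF", "g_hxlA", "g_hxlB",
                 "g_nasA"):
        assert gene in essential
    # isozyme-covered and overflow reactions are not essential
    for gene in ("g_fdsA", "g_nox", "g_mdh2"):
        assert gene not in essential


def test_essentiality_degenerate_threshold(reduced_model):
    # a threshold above every attainable growth ratio marks all genes
    # (the maintenance-gene knockout relieves NGAM, so ratios can top 1)
    everything = essentiality_scan(reduced_model, "fba", threshold=10.0)
    assert everything == set(reduced_model.genes)


def test_duplicate_gene_rules_do_not_change_the_scan(reduced_model):
    clone = reduced_model.copy()
    # duplicating a rule on a second reaction must not alter essentiality
    clone.reactions["t_ch4_c"].gene_rule = GeneRule.from_string("g_mtC or g_mtC")
    assert essentiality_scan(clone, "fba") == essentiality_scan(reduced_model, "fba")


# ---------------------------------------------------------------------------
# gap-fill pruning
# ---------------------------------------------------------------------------


def test_prune_gapfill_keeps_essential_discards_redundant(fresh_reduced_model):
    m = fresh_reduced_model
    # add a candidate duplicating the formate dehydrogenase path
    m.add_reaction(
        Reaction(
            "gapfill_dup_c",
            dict(m.reactions["fdh_c"].stoichiometry),
            0,
            1000,
            gene_rule=GeneRule.from_string("g_gap1"),
        )
    )
    result = prune_gapfill_reactions(m, ["gapfill_dup_c", "hps_c"])
    assert result.discarded == ["gapfill_dup_c"]
    assert result.retained == ["hps_c"]  # sole route into the RuMP cycle
    assert "gapfill_dup_c" not in result.model.reactions
    assert "hps_c" in result.model.reactions


def test_prune_gapfill_empty_candidates(reduced_model):
    result = prune_gapfill_reactions(reduced_model, [])
    assert result.retained == [] and result.discarded == []
    assert result.model.reaction_ids == reduced_model.reaction_ids


# ---------------------------------------------------------------------------
# phase plane
# ---------------------------------------------------------------------------


def test_phase_plane_single_cell_equals_clamped_fba(fresh_reduced_model):
    m = fresh_reduced_model
    pp = phase_plane(m, "EX_ch4_e", "EX_o2_e", [10.0], [15.0])
    clamped = m.copy()
    clamped.reactions["EX_ch4_e"].bounds = (-10, -10)
    clamped.reactions["EX_o2_e"].bounds = (-15, -15)
    assert pp.objective_values[0, 0] == pytest.approx(
        solve_fba(clamped).objective_value, abs=1e-8
    )


def test_phase_plane_requires_oxygen_at_least_methane(reduced_model):
    grid_a = np.linspace(2, 10, 5)
    grid_b = np.linspace(0, 25, 26)
    pp = phase_plane(reduced_model, "EX_ch4_e", "EX_o2_e", grid_a, grid_b)
    for i, a in enumerate(grid_a):
        for j, b in enumerate(grid_b):
            if b < a:  # pMMO consumes them 1:1 and is the sole methane sink
                assert pp.objective_values[i, j] == pytest.approx(0.0, abs=1e-9)


def test_phase_plane_ridge_slope_and_unimodality(reduced_model):
    grid_a = np.array([4.0, 6.0, 8.0, 10.0])
    grid_b = np.linspace(0, 25, 101)
    pp = phase_plane(reduced_model, "EX_ch4_e", "EX_o2_e", grid_a, grid_b)
    assert pp.ridge_slope == pytest.approx(1.5, abs=0.1)
    for i in range(len(grid_a)):
        row = pp.objective_values[i]
        k = int(np.argmax(row))
        assert np.all(np.diff(row[: k + 1]) >= -1e-9)  # rising to the ridge
        assert np.all(np.diff(row[k:]) <= 1e-9)  # falling beyond it


def test_phase_plane_rejects_non_exchange_axis(reduced_model):
    from methanoflux import ModelValidationError

    with pytest.raises(ModelValidationError):
        phase_plane(reduced_model, "pmmo_c", "EX_o2_e", [1.0], [1.0])


# ---------------------------------------------------------------------------
# model QC
# ---------------------------------------------------------------------------


def test_qc_reports_clamped_and_orphans(reduced_model):
    report = model_qc(reduced_model)
    assert "mdh_alt_c" in report.blocked_reaction_ids
    assert "mdh_alt_c" in report.clamped_reaction_ids
    exchange_ids = {r.id for r in reduced_model.exchanges()}
    # every non-exchange reaction of the fixture carries a gene rule
    assert report.orphan_reaction_ids == exchange_ids
    assert report.exchange_orphan_ids == exchange_ids


def test_qc_invariant_to_order_and_bound_scaling(fresh_reduced_model):
    base = model_qc(fresh_reduced_model)
    scaled = fresh_reduced_model.copy()
    for rxn in scaled.reactions.values():
        rxn.bounds = (rxn.lower_bound * 3.0, rxn.upper_bound * 3.0)
    assert model_qc(scaled).blocked_reaction_ids == base.blocked_reaction_ids

    reordered = MetabolicModel(
        model_id="reordered",
        metabolites=list(fresh_reduced_model.metabolites.values()),
        genes=fresh_reduced_model.genes,
        objective_reaction_id=fresh_reduced_model.objective_reaction_id,
    )
    for rid in reversed(fresh_reduced_model.reaction_ids):
        reordered.add_reaction(fresh_reduced_model.reactions[rid])
    assert model_qc(reordered).blocked_reaction_ids == base.blocked_reaction_ids


def test_qc_clamped_example(chain_model):
    chain_model.reactions["conv"].bounds = (0, 0)
    report = model_qc(chain_model)
    assert "conv" in report.blocked_reaction_ids


# ---------------------------------------------------------------------------
# independent cross-check against COBRApy/GLPK
# ---------------------------------------------------------------------------


def test_fba_agrees_with_cobrapy_on_reduced_network(reduced_model):
    """The HiGHS-based FBA optimum matches COBRApy's GLPK solution."""
    cobra = pytest.importorskip("cobra")

    cm = cobra.Model("cross")
    mets = {
        mid: cobra.Metabolite(mid, compartment=m.compartment)
        for mid, m in reduced_model.metabolites.items()
    }
    for rxn in reduced_model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound, cr.upper_bound = rxn.bounds
        cm.add_reactions([cr])
        cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoichiometry.items()})
    cm.objective = reduced_model.objective_reaction_id
    expected = cm.optimize().objective_value
    state = solve_fba(reduced_model)
    assert state.objective_value == pytest.approx(expected, rel=1e-6)
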