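"""Draft reconstruction, FBA, gap filling, community simulation, O2 sweeps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mucoseq.gem import (BIG, DietConstraint, FluxResult, MetabolicModel,
                         Metabolite, OxygenSweepConfig, Reaction,
                         UniversalReactionDB, build_draft, community_fixture,
                         community_simulate, default_diet, exchange_jaccard,
                         fba, fermentation_universe, gap_fill, jaccard_matrix,
                         oxygen_sweep, trp_indole_report)
from mucoseq.synth import species_ko_set


def toy_db():
    """glc uptake -> conversion -> biomass, with an acetate by-product.

    One glucose yields 2 acetate and 0.1 biomass; uptake capped at 10, so
    maximal growth is 1.0 with acetate secretion 20.
    """
    mets = [Metabolite("glc_e", "glucose", "extracellular"),
            Metabolite("ac_e", "acetate", "extracellular"),
            Metabolite("glc_c", "glucose", "cytosol"),
            Metabolite("ac_c", "acetate", "cytosol"),
            Metabolite("bm_c", "biomass precursor", "cytosol")]
    rxns = [
        Reaction("EX_glc", {"glc_e": -1.0}, exchange=True),
        Reaction("EX_ac", {"ac_e": -1.0}, exchange=True),
        Reaction("GLCt", {"glc_e": -1, "glc_c": 1}, kos=frozenset({"K1"})),
        Reaction("ACt", {"ac_c": -1, "ac_e": 1}, kos=frozenset({"K2"})),
        Reaction("CONV", {"glc_c": -1, "ac_c": 2, "bm_c": 0.1},
                 kos=frozenset({"K3"})),
        Reaction("BIOMASS", {"bm_c": -1.0}),
    ]
    return UniversalReactionDB(mets, rxns, "BIOMASS")


@pytest.fixture
def toy():
    db = toy_db()
    return db, MetabolicModel(db, list(db.reactions)), DietConstraint(
        uptake={"glc_e": 10.0})


class TestDatabaseValidation:
    def test_exchange_must_touch_one_extracellular_metabolite(self):
        mets = [Metabolite("a_c", "a", "cytosol")]
        with pytest.raises(ValueError, match="extracellular"):
            UniversalReactionDB(
                mets, [Reaction("EX_a", {"a_c": -1.0}, exchange=True),
                       Reaction("BIOMASS", {"a_c": -1.0})], "BIOMASS")

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolite"):
            UniversalReactionDB([], [Reaction("BIOMASS", {"x": -1.0})],
                                "BIOMASS")

    def test_json_round_trip(self, universe):
        again = UniversalReactionDB.from_json(universe.to_json())
        assert set(again.reactions) == set(universe.reactions)
        assert again.reactions["PFL"].stoich == universe.reactions["PFL"].stoich


class TestBuildDraft:
    def test_all_kos_gives_full_database(self, universe):
        all_kos = set().union(*(r.kos for r in universe.reactions.values()))
        model = build_draft(all_kos, universe)
        assert set(model.reaction_ids) == set(universe.reactions)

    def test_empty_ko_set_gives_exchanges_plus_biomass_no_growth(
            self, universe, diet):
        model = build_draft(set(), universe)
        assert set(model.reaction_ids) == set(universe.exchange_ids) | {"BIOMASS"}
        assert fba(model, diet).objective_value == pytest.approx(0.0)

    def test_licensed_reaction_subset(self, toy):
        db, _, _ = toy
        model = build_draft({"K1", "K3"}, db)
        assert set(model.reaction_ids) == {"GLCt", "CONV", "EX_glc", "EX_ac",
                                           "BIOMASS"}


class TestFBA:
    def test_all_exchanges_closed_no_growth(self, toy):
        db, model, _ = toy
        res = fba(model, DietConstraint(uptake={}))
        assert res.objective_value == pytest.approx(0.0)

    def test_hand_solved_toy(self, toy):
        db, model, diet = toy
        res = fba(model, diet)
        assert res.objective_value == pytest.approx(1.0)
        assert res.exchanges["ac_e"] == pytest.approx(20.0)
        assert res.exchanges["glc_e"] == pytest.approx(-10.0)

    def test_matches_cobra_on_toy(self, toy):
        cobra = pytest.importorskip("cobra")
        db, model, diet = toy
        cm = cobra.Model("toy")
        for m in db.metabolites.values():
            cm.add_metabolites(cobra.Metabolite(m.id))
        for rid in model.reaction_ids:
            r = db.reactions[rid]
            cr = cobra.Reaction(rid)
            cm.add_reactions([cr])
            cr.add_metabolites({cm.metabolites.get_by_id(m): c
                                for m, c in r.stoich.items()})
            lb, ub = model.bounds(diet)[rid]
            cr.lower_bound, cr.upper_bound = lb, ub
        cm.objective = "BIOMASS"
        sol = cm.optimize()
        ours = fba(model, diet)
        assert ours.objective_value == pytest.approx(sol.objective_value,
                                                     abs=1e-6)

    def test_steady_state_and_bounds_hold(self, universe, diet):
        model = build_draft(species_ko_set("Bacteroides"), universe)
        res = fba(model, diet)
        S = model.stoichiometric_matrix()
        np.testing.assert_allclose(S.to_numpy() @ res.fluxes.to_numpy(), 0.0,
                                   atol=1e-6)
        for rid, (lb, ub) in model.bounds(diet).items():
            assert lb - 1e-6 <= res.fluxes[rid] <= ub + 1e-6

    def test_optimum_monotone_under_bound_relaxation(self, universe):
        model = build_draft(species_ko_set("Escherichia"), universe)
        base = default_diet()
        g0 = fba(model, base, parsimonious=False).objective_value
        for met, extra in [("glc_e", 5.0), ("trp_e", 3.0)]:
            relaxed = base.augmented({met: extra})
            g1 = fba(model, relaxed, parsimonious=False).objective_value
            assert g1 >= g0 - 1e-9


class TestGapFill:
    def test_already_functional_draft_unchanged(self, universe, diet):
        draft = build_draft(species_ko_set("Bacteroides"), universe)
        filled = gap_fill(draft, universe, diet, 0.01)
        assert [r for r, t in filled.provenance.items() if t == "gapfill"] == []

    def test_single_missing_link_repaired_exactly(self, toy):
        db, _, diet = toy
        # transporters present, the middle glucose->acetate+biomass
        # conversion knocked out: the unique minimal repair is that reaction
        draft = build_draft({"K1", "K2"}, db)
        filled = gap_fill(draft, db, diet, 0.5)
        added = [r for r, t in filled.provenance.items() if t == "gapfill"]
        assert added == ["CONV"]

    def test_infeasible_target_reported(self, toy):
        db, _, _ = toy
        draft = build_draft(set(), db)
        with pytest.raises(RuntimeError, match="infeasible"):
            gap_fill(draft, db, DietConstraint(uptake={}), 0.1)

    def test_minimality_matches_exhaustive_search(self, universe, diet, rng):
        """Random 1-3 reaction knockouts from a functional model: the repair
        must be as small as the exhaustive-search minimum."""
        base = build_draft(species_ko_set("Escherichia"), universe)
        essential_pool = [r for r in base.reaction_ids
                          if not universe.reactions[r].exchange
                          and r != "BIOMASS"]
        for _ in range(10):
            knocked = sorted(rng.choice(essential_pool,
                                        size=int(rng.integers(1, 4)),
                                        replace=False))
            draft = MetabolicModel(
                universe, [r for r in base.reaction_ids if r not in knocked],
                provenance=None)
            small_db = UniversalReactionDB(
                list(universe.metabolites.values()),
                [universe.reactions[r] for r in base.reaction_ids],
                "BIOMASS")
            filled = gap_fill(draft, small_db, diet, 0.01)
            added = [r for r, t in filled.provenance.items() if t == "gapfill"]
            # independent exhaustive minimum over subsets of the knocked set
            minimum = None
            for k in range(0, len(knocked) + 1):
                for combo in itertools.combinations(knocked, k):
                    trial = draft.with_reactions(list(combo))
                    if fba(trial, diet,
                           parsimonious=False).objective_value >= 0.01:
                        minimum = k
                        break
                if minimum is not None:
                    break
            assert minimum is not None
            assert len(added) == minimum


class TestExchangeJaccard:
    def _res(self, ex):
        return FluxResult(pd.Series(dtype=float), 1.0, "optimal",
                          exchanges=pd.Series(ex, dtype=float))

    def test_identical_results_one(self):
        a = self._res({"ac_e": 2.0, "glc_e": -3.0})
        assert exchange_jaccard(a, a) == pytest.approx(1.0)

    def test_disjoint_zero(self):
        a = self._res({"ac_e": 2.0})
        b = self._res({"but_e": 1.0})
        assert exchange_jaccard(a, b) == pytest.approx(0.0)

    def test_hand_enumeration_half(self):
        a = self._res({"ac_e": 1.0, "for_e": 1.0, "glc_e": -2.0})
        b = self._res({"ac_e": 0.5, "glc_e": -1.0, "trp_e": -0.2})
        assert exchange_jaccard(a, b) == pytest.approx(0.5)

    def test_opposite_direction_does_not_match(self):
        a = self._res({"ac_e": 1.0})
        b = self._res({"ac_e": -1.0})
        assert exchange_jaccard(a, b) == pytest.approx(0.0)

    def test_empty_sets_defined_as_one_and_matrix_symmetric(self, universe, diet):
        assert exchange_jaccard(self._res({}), self._res({})) == 1.0
        models, ab, d = community_fixture()
        phase1 = {s: fba(m, d) for s, m in models.items()}
        J = jaccard_matrix(phase1)
        assert np.allclose(J.values, J.values.T)
        assert ((J.values >= 0) & (J.values <= 1)).all()
        assert np.allclose(np.diag(J.values), 1.0)


class TestOxygenSweep:
    def test_fraction_zero_equals_anaerobic_bitwise(self, universe, diet):
        model = build_draft(species_ko_set("Escherichia"), universe)
        curve = oxygen_sweep(model, diet)
        anaerobic = fba(model, diet, anaerobic=True,
                        parsimonious=False).objective_value
        assert curve[0.0] == anaerobic

    def test_respiring_model_grows_faster_with_oxygen(self, universe, diet):
        model = build_draft(species_ko_set("Escherichia"), universe)
        curve = oxygen_sweep(model, diet)
        assert curve[0.05] >= curve[0.0]
        fr = sorted(curve)
        assert all(curve[a] <= curve[b] + 1e-9 for a, b in zip(fr, fr[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="include 0"):
            OxygenSweepConfig(fractions=(0.05, 0.5))
        with pytest.raises(ValueError, match="sorted"):
            OxygenSweepConfig(fractions=(0.5, 0.0))

    def test_model_without_o2_exchange_rejected(self, toy):
        db, model, diet = toy
        with pytest.raises(ValueError, match="O2"):
            oxygen_sweep(model, diet)


class TestCommunity:
    def test_single_species_equals_own_exchanges(self, universe, diet):
        model = gap_fill(build_draft(species_ko_set("Bacteroides"), universe),
                         universe, diet)
        com = community_simulate({"b": model}, {"TI*": {"b": 1.0}}, diet)
        r = com["TI*"]
        pd.testing.assert_series_equal(r.weighted_exchange,
                                       r.species_exchanges.loc["b"],
                                       check_names=False)

    def test_weighted_totals_linear_in_abundance(self):
        models, ab, diet = community_fixture()
        com = community_simulate(models, ab, diet)
        for loc, r in com.items():
            expect = sum(r.abundances[s] * r.species_exchanges.loc[s]
                         for s in r.species_exchanges.index)
            np.testing.assert_allclose(r.weighted_exchange, expect, atol=1e-9)

    def test_bad_abundances_rejected(self):
        models, ab, diet = community_fixture()
        with pytest.raises(ValueError, match="sum"):
            community_simulate(models, {"TI*": {"acetogen": 0.5}}, diet)

    def test_scfa_ordering_on_fixture(self):
        models, ab, diet = community_fixture()
        com = community_simulate(models, ab, diet)
        for loc, r in com.items():
            w = r.weighted_exchange
            assert w["ac_e"] > w["ppa_e"] > w["but_e"] > 0, loc

    def test_trp_indole_localisation_and_stoichiometry(self):
        models, ab, diet = community_fixture()
        com = community_simulate(models, ab, diet)
        rep = trp_indole_report(com)
        assert rep.loc["TI*", "indole_secretion"] > 0
        assert rep.loc["TC", "indole_secretion"] > 0
        assert rep.loc["RE", "indole_secretion"] == pytest.approx(0.0)
        for loc in ("TI*", "TC"):
            assert rep.loc[loc, "indole_secretion"] == pytest.approx(
                rep.loc[loc, "tryptophanase_flux"], abs=1e-8)

    def test_missing_metabolite_named(self):
        models, ab, diet = community_fixture()
        com = community_simulate(models, ab, diet)
        with pytest.raises(KeyError, match="xyz_e"):
            trp_indole_report(com, trp_met="xyz_e")
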