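import numpy as np
import pytest

from optenvelope import (
    MediumSpec,
    RoleConfig,
    apply_medium,
    classify_roles,
    fba,
    load_model,
    save_json,
    to_irreversible,
)
from optenvelope.model_io import (
    REVERSE_SUFFIX,
    MetabolicModel,
    ModelReadError,
    UnknownReactionError,
    check_model_invariants,
    detect_exchanges,
    inorganic_exchanges,
)
from tests.conftest import BIOMASS, PRODUCT


class TestLoadModel:
    def test_json_round_trip(self, toy, toy_json):
        back = load_model(toy_json, "json")
        assert back.reaction_ids == toy.reaction_ids
        assert back.metabolite_ids == toy.metabolite_ids
        assert np.allclose(back.S, toy.S)
        assert np.allclose(back.lower_bounds, toy.lower_bounds)
        assert np.allclose(back.upper_bounds, toy.upper_bounds)
        assert np.allclose(back.objective_coeffs, toy.objective_coeffs)

    def test_sbml_round_trip(self, toy, toy_json, tmp_path):
        cobra = pytest.importorskip("cobra")
        import cobra.io

        cmodel = cobra.io.load_json_model(toy_json)
        sbml_path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cmodel, str(sbml_path))
        back = load_model(str(sbml_path), "sbml")
        assert back.n_reactions == toy.n_reactions
        assert back.n_metabolites == toy.n_metabolites
        assert sorted(back.reaction_ids) == sorted(toy.reaction_ids)
        # same optimum regardless of serialisation route
        assert fba(back, BIOMASS)[0] == pytest.approx(4.5)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("")
        with pytest.raises(ModelReadError):
            load_model(str(path), "json")

    def test_unreadable_file_errors(self):
        with pytest.raises(ModelReadError):
            load_model("/nonexistent/model.json", "json")

    def test_duplicate_reaction_ids_rejected(self):
        with pytest.raises(ModelReadError):
            MetabolicModel(
                metabolite_ids=["A"],
                reaction_ids=["R", "R"],
                S=np.array([[1.0, -1.0]]),
                lower_bounds=[0, 0],
                upper_bounds=[10, 10],
                objective_coeffs=[0, 0],
            )


class TestToIrreversible:
    def test_split_bounds_and_column(self):
        model = MetabolicModel(
            metabolite_ids=["A", "B"],
            reaction_ids=["EX_A", "R", "EX_B"],
            S=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
            lower_bounds=[0, -5, 0],
            upper_bounds=[10, 10, 10],
            objective_coeffs=[0, 0, 0],
        )
        split = to_irreversible(model)
        assert split.reaction_ids == ["EX_A", "R", "R" + REVERSE_SUFFIX, "EX_B"]
        j_f, j_b = split.index("R"), split.index("R" + REVERSE_SUFFIX)
        assert (split.lower_bounds[j_f], split.upper_bounds[j_f]) == (0, 10)
        assert (split.lower_bounds[j_b], split.upper_bounds[j_b]) == (0, 5)
        assert np.allclose(split.S[:, j_f], -split.S[:, j_b])
        assert split.reversible_pairs == {"R": "R" + REVERSE_SUFFIX}
        assert split.original_ids == {"R": "R", "R" + REVERSE_SUFFIX: "R"}
        check_model_invariants(split)

    def test_idempotent_on_irreversible_model(self, toy):
        split = to_irreversible(toy)
        assert split.reaction_ids == toy.reaction_ids
        assert np.allclose(split.S, toy.S)
        again = to_irreversible(split)
        assert again.reaction_ids == split.reaction_ids

    def test_lp_equivalence(self, rev_toy):
        split = to_irreversible(rev_toy)
        for objective in ["R3", "EX_P", "R1"]:
            orig, _ = fba(rev_toy, objective)
            new, _ = fba(split, objective)
            assert new == pytest.approx(orig, abs=1e-9)

    def test_roles_propagate_to_both_halves(self, rev_toy):
        split = to_irreversible(rev_toy)
        assert split.roles["R5"] == "internal"
        assert split.roles["R5" + REVERSE_SUFFIX] == "internal"


class TestApplyMedium:
    def test_substrate_bound(self, toy):
        out = apply_medium(toy, MediumSpec(substrate_exchange="EX_A", substrate_uptake=7.0))
        assert fba(out, "EX_A")[0] == pytest.approx(7.0)

    def test_other_uptakes_closed(self, toy):
        # make EX_P reversible (could re-import P), then check medium closes it
        model = toy.copy()
        model.lower_bounds[model.index("EX_P")] = -1000.0
        split = to_irreversible(model)
        out = apply_medium(split, MediumSpec(substrate_exchange="EX_A"))
        j = out.index("EX_P" + REVERSE_SUFFIX)
        assert out.upper_bounds[j] == 0.0

    def test_unknown_exchange_errors(self, toy):
        with pytest.raises(UnknownReactionError):
            apply_medium(toy, MediumSpec(substrate_exchange="EX_MISSING"))

    def test_non_exchange_substrate_errors(self, toy):
        with pytest.raises(UnknownReactionError):
            apply_medium(toy, MediumSpec(substrate_exchange="R1"))

    def test_anaerobic_oxygen_bound(self, toy):
        out = apply_medium(
            toy,
            MediumSpec(
                substrate_exchange="EX_A", aerobic=False, oxygen_exchange="EX_A"
            ),
        )
        # oxygen stand-in EX_A has its uptake closed after the substrate bound
        assert out.upper_bounds[out.index("EX_A")] == 0.0

    def test_anaerobic_deletions(self, toy):
        out = apply_medium(
            toy,
            MediumSpec(
                substrate_exchange="EX_A", aerobic=False, anaerobic_deletions=["R5"]
            ),
        )
        j = out.index("R5")
        assert out.upper_bounds[j] == 0.0 and out.lower_bounds[j] == 0.0

    def test_substrate_bound_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            MediumSpec(substrate_exchange="EX_A", substrate_uptake=0.0)

    def test_auto_inorganic_free_exchanges(self, toy):
        model = toy.copy()
        model.metabolite_formulas = {"A": "C6H12O6", "P": "C2H4O2"}
        # no carbon-free exchanged metabolite -> substrate only
        assert inorganic_exchanges(model) == []
        model.metabolite_formulas["P"] = "H3PO4"
        assert inorganic_exchanges(model) == ["EX_P"]
        out = apply_medium(
            model,
            MediumSpec(substrate_exchange="EX_A", free_exchanges="auto-inorganic"),
        )
        assert out.upper_bounds[out.index("EX_P")] == 1000.0


class TestClassifyRoles:
    def test_toy_partition(self, toy):
        assert {r for r, role in toy.roles.items() if role == "exchange"} == {
            "EX_A", "EX_P", "EX_BM",
        }
        assert toy.roles[BIOMASS] == "biomass"
        assert toy.roles["ATPM"] == "maintenance"
        assert {r for r, role in toy.roles.items() if role == "internal"} == {
            "R1", "R2", "R5",
        }

    def test_partition_total_and_disjoint(self, toy):
        assert set(toy.roles) == set(toy.reaction_ids)
        check_model_invariants(toy)

    def test_missing_biomass_errors(self, toy):
        with pytest.raises(UnknownReactionError):
            classify_roles(toy, RoleConfig(biomass_id="NOPE"))

    def test_diffusion_transport_from_config(self, toy):
        out = classify_roles(
            toy,
            RoleConfig(
                biomass_id=BIOMASS,
                maintenance_ids=["ATPM"],
                diffusion_transport_ids=["R5"],
            ),
        )
        assert out.roles["R5"] == "diffusion_transport"

    def test_exchange_detection_structural(self, toy):
        # the maintenance sink is structurally single-entry too; classify_roles
        # overrides it with the configured maintenance role afterwards
        assert sorted(detect_exchanges(toy)) == ["ATPM", "EX_A", "EX_BM", "EX_P"]


class TestKnockoutSemantics:
    def test_knockout_removes_both_directions(self, rev_toy):
        split = to_irreversible(rev_toy)
        split.knock_out(["R5"])
        for rid in ("R5", "R5" + REVERSE_SUFFIX):
            j = split.index(rid)
            assert split.lower_bounds[j] == 0.0 and split.upper_bounds[j] == 0.0

    def test_save_json_survives_split_model(self, rev_toy, tmp_path):
        split = to_irreversible(rev_toy)
        path = tmp_path / "split.json"
        save_json(split, str(path))
        back = load_model(str(path), "json")
        assert back.n_reactions == split.n_reactions
        assert fba(back, BIOMASS)[0] == pytest.approx(4.5)
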