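"""Model data types, JSON round-trips, GPR logic, deletions."""

import json

import numpy as np
import pytest

from fucsim.model import (
    ConstraintModel,
    Metabolite,
    ParseError,
    Reaction,
    ValidationError,
    apply_deletions,
    assemble_matrix,
    evaluate_gpr,
    gpr_genes,
    parse_gpr,
    parse_model,
    write_model,
)


def _minimal_doc():
    return {
        "metabolites": [{"id": "a_e", "compartment": "e"}],
        "reactions": [
            {
                "id": "EX_a",
                "metabolites": {"a_e": -1.0},
                "lower_bound": -10.0,
                "upper_bound": 1000.0,
                "gene_reaction_rule": "",
            }
        ],
        "genes": [],
    }


class TestParse:
    def test_minimal_document(self):
        model = parse_model(_minimal_doc())
        assert len(model.reactions) == 1
        assert model.reactions[0].lower_bound == -10.0

    def test_round_trip_preserves_all_fields(self, extended):
        doc = write_model(extended)
        again = parse_model(json.loads(json.dumps(doc)))
        assert again.objective == extended.objective
        assert again.genes == extended.genes
        for r1, r2 in zip(extended.reactions, again.reactions):
            assert (r1.id, r1.stoichiometry, r1.lower_bound, r1.upper_bound, r1.gpr) == (
                r2.id, r2.stoichiometry, r2.lower_bound, r2.upper_bound, r2.gpr)
        for m1, m2 in zip(extended.metabolites, again.metabolites):
            assert (m1.id, m1.compartment, m1.formula) == (m2.id, m2.compartment, m2.formula)

    @pytest.mark.parametrize("missing", ["metabolites", "reactions", "genes"])
    def test_missing_top_level_key_named_in_error(self, missing):
        doc = _minimal_doc()
        del doc[missing]
        with pytest.raises(ParseError, match=missing):
            parse_model(doc)

    def test_dangling_metabolite_reference(self):
        doc = _minimal_doc()
        doc["reactions"][0]["metabolites"] = {"xyz_c": -1.0}
        with pytest.raises(ValidationError, match="xyz_c"):
            parse_model(doc)

    def test_duplicate_reaction_id(self):
        doc = _minimal_doc()
        doc["reactions"].append(dict(doc["reactions"][0]))
        with pytest.raises(ValidationError, match="duplicate"):
            parse_model(doc)

    def test_inverted_bounds_rejected(self):
        doc = _minimal_doc()
        doc["reactions"][0]["lower_bound"] = 5.0
        doc["reactions"][0]["upper_bound"] = -5.0
        with pytest.raises(ValidationError, match="lower_bound"):
            parse_model(doc)


class TestMatrix:
    def test_single_conversion_column(self):
        model = ConstraintModel(
            metabolites=[Metabolite("A_c"), Metabolite("B_c")],
            reactions=[Reaction("R", {"A_c": -1.0, "B_c": 1.0})],
        )
        S, mets, rxns = assemble_matrix(model)
        assert mets == ["A_c", "B_c"] and rxns == ["R"]
        assert S[:, 0].tolist() == [-1.0, 1.0]

    def test_aldolase_column_condenses_dhap_and_lad(self, extended):
        S, mets, rxns = assemble_matrix(extended)
        col = S[:, rxns.index("FCPA")]
        coef = {mets[i]: col[i] for i in np.nonzero(col)[0]}
        assert coef == {"dhap_c": -1.0, "lad_c": -1.0, "fc1p_c": 1.0}

    def test_shape_and_no_orphan_metabolites(self, extended):
        S, mets, rxns = assemble_matrix(extended)
        assert S.shape == (len(mets), len(rxns))
        assert not np.any(np.all(S == 0, axis=1)), "orphan metabolite row"

    def test_adding_reaction_appends_one_column(self, mini_core):
        S0, _, _ = assemble_matrix(mini_core)
        grown = mini_core.copy()
        grown.reactions.append(Reaction("DHAP_SINK", {"dhap_c": -1.0}))
        S1, _, _ = assemble_matrix(grown)
        assert S1.shape[1] == S0.shape[1] + 1
        assert np.array_equal(S1[:, : S0.shape[1]], S0)


class TestGpr:
    @pytest.mark.parametrize(
        "rule,deleted,kept",
        [
            ("fucO", {"fucO"}, False),
            ("g1 or g2", {"g1"}, True),
            ("g1 and g2", {"g2"}, False),
            ("g1 and (g2 or g3)", {"g2"}, True),
            ("g1 and (g2 or g3)", {"g2", "g3"}, False),
            ("g1 or g2 and g3", {"g2"}, True),  # AND binds tighter than OR
            ("g1 or g2 and g3", {"g1", "g3"}, False),
            ("", {"anything"}, True),
        ],
    )
    def test_evaluation(self, rule, deleted, kept):
        assert evaluate_gpr(rule, deleted) is kept

    def test_genes_collects_leaves(self):
        assert gpr_genes("a and (b or c) or a") == {"a", "b", "c"}

    @pytest.mark.parametrize("bad", ["(a or b", "and b", "a or", "a (b)"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_gpr(bad)


class TestDeletions:
    def test_empty_deletion_is_identity(self, extended):
        out = apply_deletions(extended, set())
        assert write_model(out) == write_model(extended)

    def test_fuc1_genotype_zero_bounds_two_reactions(self, extended):
        out = apply_deletions(extended, {"fucI", "fucK"})
        for rid in ("FUCI", "FCLK"):
            rxn = out.get_reaction(rid)
            assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        changed = [
            r.id for r, r0 in zip(out.reactions, extended.reactions)
            if (r.lower_bound, r.upper_bound) != (r0.lower_bound, r0.upper_bound)
        ]
        assert sorted(changed) == ["FCLK", "FUCI"]

    def test_fuc4_genotype_zero_bounds_five_reactions(self, extended):
        out = apply_deletions(extended, {"fucI", "fucK", "tpiA", "fucO", "aldA"})
        zeroed = [r.id for r in out.reactions
                  if (r.lower_bound, r.upper_bound) == (0.0, 0.0)
                  and extended.get_reaction(r.id).upper_bound != 0.0]
        assert sorted(zeroed) == ["ALDA", "FCLK", "FUCI", "FUCO", "TPI"]

    def test_input_model_unmodified(self, extended):
        before = write_model(extended)
        apply_deletions(extended, {"fucO"})
        assert write_model(extended) == before

    def test_idempotent_and_monotone(self, extended):
        once = apply_deletions(extended, {"fucI", "tpiA"})
        twice = apply_deletions(once, {"fucI", "tpiA"})
        assert write_model(once) == write_model(twice)

        def zeroed(model):
            return {r.id for r in model.reactions
                    if (r.lower_bound, r.upper_bound) == (0.0, 0.0)}

        small = zeroed(apply_deletions(extended, {"fucI"}))
        large = zeroed(apply_deletions(extended, {"fucI", "fucK", "fucO"}))
        assert small <= large

    def test_unknown_gene_warns_and_is_noop(self, extended):
        with pytest.warns(UserWarning, match="not in model"):
            out = apply_deletions(extended, {"no_such_gene"})
        assert write_model(out) == write_model(extended)
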