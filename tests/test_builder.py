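"""The reconstruction workflow: genome, tables and M-model to ME-model."""

import pytest
from hypothesis import given, strategies as st

from memodel import io
from memodel.builder import (
    add_dummy_complex,
    build_me_model,
    gpr_conjunctions,
    reverse_complement,
)
from memodel.core import MEModel
from memodel.exceptions import AlphabetError, CompositionError
from memodel.process_data import GenericData


class TestReverseComplement:
    @pytest.mark.parametrize("seq, expected", [("ATGC", "GCAT"), ("", ""),
                                               ("AAAA", "TTTT")])
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(st.text(alphabet="ACGT", max_size=200))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_non_dna_rejected(self):
        with pytest.raises(AlphabetError):
            reverse_complement("ATGU")


class TestGprExpansion:
    @pytest.mark.parametrize(
        "rule, expected",
        [
            ("", []),
            ("g1", [{"g1"}]),
            ("g1 and g2", [{"g1", "g2"}]),
            ("(g1 and g2) or g3", [{"g1", "g2"}, {"g3"}]),
            ("g1 or g2 or g3", [{"g1"}, {"g2"}, {"g3"}]),
        ],
    )
    def test_dnf_expansion(self, rule, expected):
        assert [set(c) for c in gpr_conjunctions(rule)] == expected


class TestBuildWorkflow:
    def test_every_coding_gene_has_exactly_one_translation_reaction(self, toy_model):
        genes = [f"g{i:02d}" for i in range(1, 11)] + ["dummy"]
        translations = [
            r for r in toy_model.reactions if r.startswith("translation_")
        ]
        assert sorted(translations) == sorted(f"translation_{g}" for g in genes)

    def test_two_sigma_factors_give_two_transcription_reactions(self, toy_model):
        matches = [
            r for r in toy_model.reactions if r.startswith("transcription_TU_g04")
        ]
        assert sorted(matches) == [
            "transcription_TU_g04_from_RNAP_sigA",
            "transcription_TU_g04_from_RNAP_sigB",
        ]

    def test_orphan_reaction_is_catalyzed_by_the_dummy_complex(self, toy_model):
        reaction = toy_model.reactions["LIPID_SYN_FWD_CPLX_dummy"]
        assert reaction.complex_id == "CPLX_dummy"
        assert reaction.stoichiometry["CPLX_dummy"].mu_coefficient < 0

    def test_spontaneous_reactions_have_no_catalyst(self, toy_model):
        reaction = toy_model.reactions["PPIASE_FWD_SPONT"]
        assert reaction.complex_id is None

    def test_every_metabolic_reaction_links_stoichiometric_data(self, toy_model):
        from memodel.process_data import StoichiometricData

        metabolics = toy_model.reactions_of_type("metabolic")
        assert metabolics
        for reaction in metabolics:
            sdata = toy_model.get_process_data(
                reaction.stoichiometric_data_id, StoichiometricData
            )
            assert sdata.stoichiometry

    def test_generic_formation_count_is_total_membership(self, toy_model):
        total_members = sum(
            len(g.members) for g in toy_model.process_data_of_type(GenericData)
        )
        assert total_members > 0
        assert len(toy_model.reactions_of_type("generic_formation")) == total_members

    def test_building_twice_yields_identical_models(self, toy_bundle):
        a = build_me_model(toy_bundle.build_inputs())
        b = build_me_model(toy_bundle.build_inputs())
        assert io.models_equal(a, b)

    def test_minimal_bundle_uses_auto_generated_single_gene_tus(self, toy_minimal):
        auto = [r for r in toy_minimal.reactions if "TU_auto_" in r]
        assert any("TU_auto_g02" in r for r in auto)
        assert any("TU_auto_rrna_1" in r for r in auto)

    def test_membrane_protein_is_translocated_before_complex_assembly(
        self, toy_model
    ):
        post = toy_model.reactions["post_translation_g01"]
        assert post.stoichiometry["protein_g01"].constant == -1.0
        assert post.stoichiometry["protein_g01_Membrane"].constant == 1.0
        formation = toy_model.reactions["formation_CPLX_GLC"]
        assert formation.stoichiometry["protein_g01_Membrane"].constant == -2.0


class TestDummyComplex:
    def test_uniform_composition_gives_requested_length(self, toy_model):
        protein = toy_model.get_metabolite("protein_dummy")
        assert len(protein.amino_acid_sequence) == 100
        assert protein.amino_acid_sequence.startswith("M")

    def test_dummy_demand_carries_flux_at_feasible_growth(self, toy_solution):
        assert toy_solution.fluxes["DM_dummy"] > 0

    def test_invalid_composition_is_rejected(self):
        model = MEModel()
        with pytest.raises(CompositionError):
            add_dummy_complex(model, {"ala__L": 0.4, "gly": 0.4})
        with pytest.raises(CompositionError):
            add_dummy_complex(model, {"ala__L": 0.5, "unobtainium": 0.5})

    def test_orphan_without_dummy_cost_grows_at_least_as_fast(
        self, tmp_path, toy_bundle
    ):
        """Making the orphan reaction spontaneous removes its expression
        cost, restoring the old bias toward free orphan flux."""
        import json

        from memodel.solver import bisect_max_growth

        with_dummy = build_me_model(toy_bundle.build_inputs())
        mu_with = bisect_max_growth(with_dummy, 0, 2, 1e-6).mu_star

        data = json.loads(toy_bundle.m_model_path.read_text())
        for reaction in data["reactions"]:
            if reaction["id"] == "LIPID_SYN":
                reaction.setdefault("notes", {})["spontaneous"] = True
        biased_path = tmp_path / "m_model_biased.json"
        biased_path.write_text(json.dumps(data))
        inputs = toy_bundle.build_inputs()
        inputs.m_model_path = str(biased_path)
        without_dummy = build_me_model(inputs)
        assert "LIPID_SYN_FWD_SPONT" in without_dummy.reactions
        mu_without = bisect_max_growth(without_dummy, 0, 2, 1e-6).mu_star
        assert mu_without >= mu_with - 1e-6
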