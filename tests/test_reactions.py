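"""Coupling coefficients, reaction compilation and the explicit-mode oracle."""

import pytest

from memodel import balance, chemistry, solver
from memodel.core import GrowthExpression
from memodel.exceptions import DomainError, ModeError
from memodel.reactions import (
    convert_to_explicit_constraints,
    dilution_coefficient,
    machine_coupling_coefficient,
)


class TestDilutionCoefficient:
    def test_zero_growth_means_zero_dilution(self):
        assert dilution_coefficient(65.0).evaluate(0.0) == 0.0

    def test_keff_of_one_per_hour_gives_identity(self):
        assert dilution_coefficient(1.0 / 3600.0).evaluate(1.0) == pytest.approx(1.0)

    def test_direct_value(self):
        assert dilution_coefficient(65.0).evaluate(0.5) == pytest.approx(0.5 / 234000)

    def test_constant_term_is_zero(self):
        assert dilution_coefficient(10.0).constant == 0.0

    @pytest.mark.parametrize("keff", [0.0, -3.0])
    def test_nonpositive_keff_rejected(self, keff):
        with pytest.raises(DomainError):
            dilution_coefficient(keff)


class TestMachineCoupling:
    def test_matches_length_over_rate(self):
        coeff = machine_coupling_coefficient(300, 12.0)
        assert coeff.mu_coefficient == pytest.approx(300 / 43200)

    def test_doubling_length_doubles_coefficient(self):
        one = machine_coupling_coefficient(150, 12.0)
        two = machine_coupling_coefficient(300, 12.0)
        assert two.evaluate(0.7) == pytest.approx(2 * one.evaluate(0.7))

    @pytest.mark.parametrize("length, rate", [(0, 12.0), (100, 0.0), (-5, 12.0)])
    def test_nonpositive_inputs_rejected(self, length, rate):
        with pytest.raises(DomainError):
            machine_coupling_coefficient(length, rate)


class TestCompiledReactions:
    def test_update_is_idempotent_for_every_reaction_type(self, toy_model):
        seen_types = set()
        for reaction in toy_model.reactions.values():
            before = dict(reaction.stoichiometry)
            bounds = (reaction.lower_bound, reaction.upper_bound)
            reaction.update(toy_model)
            assert reaction.stoichiometry == before, reaction.id
            assert (reaction.lower_bound, reaction.upper_bound) == bounds
            seen_types.add(reaction.reaction_type)
        assert len(seen_types) == 9

    def test_translation_reaction_couples_ribosome_by_protein_length(self, toy_model):
        reaction = toy_model.reactions["translation_g01"]
        protein = toy_model.get_metabolite("protein_g01")
        length = len(protein.amino_acid_sequence)
        coeff = reaction.stoichiometry["ribosome"]
        assert coeff.constant == 0.0
        assert coeff.mu_coefficient == pytest.approx(-length / (12.0 * 3600.0))

    def test_translation_consumes_one_charged_trna_per_residue(self, toy_model):
        reaction = toy_model.reactions["translation_g01"]
        protein = toy_model.get_metabolite("protein_g01")
        consumed = -sum(
            coeff.constant
            for met, coeff in reaction.stoichiometry.items()
            if met.startswith("generic_tRNA_")
        )
        assert consumed == pytest.approx(len(protein.amino_acid_sequence))

    def test_transcription_releases_one_ppi_per_nucleotide(self, toy_model):
        from memodel.process_data import TranscriptionData

        reaction = toy_model.reactions["transcription_TU_g02_from_RNAP_sigA"]
        txd = toy_model.get_process_data(
            reaction.transcription_data_id, TranscriptionData
        )
        assert reaction.stoichiometry["ppi_c"].constant == len(
            txd.nucleotide_sequence
        )

    def test_transcription_couples_polymerase_by_unit_length(self, toy_model):
        from memodel.process_data import TranscriptionData

        reaction = toy_model.reactions["transcription_TU_stable_from_RNAP_sigA"]
        txd = toy_model.get_process_data(
            reaction.transcription_data_id, TranscriptionData
        )
        coeff = reaction.stoichiometry["RNAP_sigA"]
        expected = -len(txd.nucleotide_sequence) / (55.0 * 3600.0)
        assert coeff.mu_coefficient == pytest.approx(expected)

    def test_stable_rna_operon_returns_spacer_nucleotides(self, toy_model):
        """TU length minus mature products reappears as NMPs."""
        from memodel.process_data import TranscriptionData

        reaction = toy_model.reactions["transcription_TU_stable_from_RNAP_sigA"]
        txd = toy_model.get_process_data(
            reaction.transcription_data_id, TranscriptionData
        )
        product_nt = sum(
            len(toy_model.get_metabolite(p).nucleotide_sequence)
            for p in txd.rna_products
        )
        spacer = len(txd.nucleotide_sequence) - product_nt
        assert spacer > 0
        recovered = sum(
            reaction.stoichiometry.get(nmp, GrowthExpression()).constant
            for nmp in ("amp_c", "gmp_c", "cmp_c", "ump_c")
        )
        assert recovered == pytest.approx(spacer)

    def test_mrna_coupling_has_degradation_floor_and_dilution_slope(self, toy_model):
        reaction = toy_model.reactions["translation_g03"]
        coeff = reaction.stoichiometry["RNA_g03"]
        protein = toy_model.get_metabolite("protein_g03")
        k_transl = 12.0 * 3600.0 / len(protein.amino_acid_sequence)
        k_deg = toy_model.global_parameters.k_deg_mrna_per_hr
        assert coeff.constant == pytest.approx(-k_deg / k_transl)
        assert coeff.mu_coefficient == pytest.approx(-1.0 / k_transl)

    def test_generic_formation_is_one_to_one(self, toy_model):
        reaction = toy_model.reactions["protein_g05_to_generic_EFTu"]
        assert reaction.stoichiometry["protein_g05"].constant == -1.0
        assert reaction.stoichiometry["generic_EFTu"].constant == 1.0

    def test_modified_complex_carries_cofactor_in_its_formula(self, toy_model):
        formation = toy_model.reactions["formation_CPLX_AA"]
        assert formation.stoichiometry["mg2_c"].constant == -1.0
        assert toy_model.get_metabolite("CPLX_AA").formula["Mg"] == 1.0


class TestMassBalance:
    def test_compiled_model_is_elementally_balanced(self, toy_model):
        assert balance.check_model_balance(toy_model, mu=0.0) == {}

    def test_growth_terms_fall_only_on_macromolecule_dilution(self, toy_model):
        """Every mu-proportional stoichiometric term drains a macromolecule
        (or a bookkeeping pseudo-metabolite) -- the imbalance at mu > 0 is
        exactly the machinery diluted to daughter cells."""
        from memodel.core import MACROMOLECULE_KINDS

        pseudo = set(toy_model.global_info["pseudo_metabolites"])
        for reaction in toy_model.reactions.values():
            if reaction.reaction_type == "summary":
                continue
            for met, coeff in reaction.stoichiometry.items():
                if coeff.mu_coefficient == 0.0 or met in pseudo:
                    continue
                kind = toy_model.get_metabolite(met).kind
                assert kind in MACROMOLECULE_KINDS, (reaction.id, met)

    def test_reaction_imbalance_at_growth_equals_dilution_drain(self, toy_model):
        reaction = toy_model.reactions["translation_g02"]
        residual = balance.elemental_imbalance(toy_model, reaction, mu=0.8)
        drain = balance.dilution_drain(toy_model, reaction, mu=0.8)
        for element, value in residual.items():
            assert value == pytest.approx(drain.get(element, 0.0), abs=1e-9)


class TestExplicitMode:
    def test_explicit_model_is_strictly_larger(self, toy_model):
        explicit = convert_to_explicit_constraints(toy_model)
        assert len(explicit.reactions) > len(toy_model.reactions)
        assert len(explicit.metabolites) > len(toy_model.metabolites)

    def test_feasibility_matches_embedded_at_fixed_growth_rates(self, toy_model):
        explicit = convert_to_explicit_constraints(toy_model)
        for mu in (0.1, 0.5, 1.0):
            embedded = solver.feasible_at(toy_model, mu).feasible
            converted = solver.feasible_at(explicit, mu).feasible
            assert embedded == converted

    def test_converting_twice_is_a_mode_error(self, toy_model):
        explicit = convert_to_explicit_constraints(toy_model)
        with pytest.raises(ModeError):
            convert_to_explicit_constraints(explicit)

    def test_conversion_leaves_the_input_model_untouched(self, toy_model):
        before = len(toy_model.reactions)
        convert_to_explicit_constraints(toy_model)
        assert len(toy_model.reactions) == before
        assert toy_model.coupling_mode == "embedded"
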