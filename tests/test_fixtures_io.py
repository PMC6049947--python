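"""Toy-organism generation, serialization round-trips and flux tables."""

import json
from pathlib import Path

import pytest

from memodel import io, solver
from memodel.balance import check_model_balance
from memodel.builder import build_me_model
from memodel.exceptions import (
    InfeasibleAtMinError,
    ParameterError,
    SchemaVersionError,
    ValidationError,
)
from memodel.core import ZERO
from memodel.process_data import PROCESS_DATA_TYPES
from memodel.toy import (
    balance_from_currencies,
    brute_force_max_mu,
    generate_toy_organism,
)
from memodel import chemistry


class TestGenerator:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        a = generate_toy_organism(tmp_path / "a", n_genes=10, seed=3,
                                  difficulty="full")
        b = generate_toy_organism(tmp_path / "b", n_genes=10, seed=3,
                                  difficulty="full")
        for name in ("genome.gb", "m_model.json", "tu_table.tsv",
                     "enzyme_table.tsv", "keff_table.tsv",
                     "translocation_table.tsv", "bundle.json"):
            assert (a.directory / name).read_bytes() == (
                b.directory / name
            ).read_bytes(), name

    def test_different_seeds_differ(self, tmp_path):
        a = generate_toy_organism(tmp_path / "a", seed=1)
        b = generate_toy_organism(tmp_path / "b", seed=2)
        assert a.genbank_path.read_bytes() != b.genbank_path.read_bytes()

    def test_full_bundle_instantiates_all_nine_process_data_types(self, toy_model):
        present = {
            type(p).__name__ for p in toy_model.process_data.values()
        }
        assert present == {cls.__name__ for cls in PROCESS_DATA_TYPES}

    def test_full_bundle_compiles_all_nine_reaction_types(self, toy_model):
        present = {r.reaction_type for r in toy_model.reactions.values()}
        assert present == {
            "plain", "summary", "metabolic", "complex_formation",
            "translation", "transcription", "post_translation",
            "trna_charging", "generic_formation",
        }

    def test_parameter_validation(self, tmp_path):
        with pytest.raises(ParameterError):
            generate_toy_organism(tmp_path, n_genes=2)
        with pytest.raises(ParameterError):
            generate_toy_organism(tmp_path, n_genes=5, difficulty="full")
        with pytest.raises(ParameterError):
            generate_toy_organism(tmp_path, difficulty="extreme")

    def test_currency_balancer_is_elementally_exact(self):
        for formula in ("C10H16N5O13P3", "C3H7NO2S", "C30H58O4", "C2H5NO2"):
            stoich = dict(balance_from_currencies(formula))
            stoich["__target__"] = 1.0
            totals = {}
            for met, coeff in stoich.items():
                source = formula if met == "__target__" else {
                    "glc__D_c": "C6H12O6", "nh3_c": "H3N", "h2s_c": "H2S",
                    "pi_c": chemistry.PI_FORMULA, "h2o_c": "H2O", "h2_c": "H2",
                }[met]
                for element, count in chemistry.parse_formula(source).items():
                    totals[element] = totals.get(element, 0.0) + coeff * count
            assert all(abs(v) < 1e-9 for v in totals.values()), formula

    def test_minimal_bundle_builds_balanced_and_grows(self, toy_minimal):
        assert check_model_balance(toy_minimal, mu=0.0) == {}
        result = solver.feasible_at(toy_minimal, 0.0)
        assert result.feasible


class TestGrowthOracle:
    def test_grid_scan_brackets_the_bisection_result(self, toy_model, toy_solution):
        oracle = brute_force_max_mu(toy_model, 0.0, 2.0, 0.05)
        assert oracle <= toy_solution.mu_star <= oracle + 0.05

    def test_halving_the_step_refines_within_the_old_step(self, toy_model):
        coarse = brute_force_max_mu(toy_model, 1.0, 2.0, 0.08)
        fine = brute_force_max_mu(toy_model, coarse, coarse + 0.08, 0.04)
        assert 0 <= fine - coarse < 0.08

    def test_closed_exchanges_at_positive_growth_are_infeasible(self, toy_model):
        model = toy_model.copy()
        for reaction in model.reactions.values():
            if reaction.id.startswith("EX_"):
                reaction.lower_bound = ZERO
        with pytest.raises(InfeasibleAtMinError):
            brute_force_max_mu(model, 0.05, 1.0, 0.05)


class TestSerialization:
    def test_round_trip_preserves_the_model(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        io.write_me_json(toy_model, path)
        restored = io.read_me_json(path)
        assert io.models_equal(toy_model, restored)

    def test_round_trip_preserves_coefficient_evaluation(self, toy_model, tmp_path):
        path = tmp_path / "model.json"
        io.write_me_json(toy_model, path)
        restored = io.read_me_json(path)
        for rid in ("translation_g01", "transcription_TU_stable_from_RNAP_sigA"):
            original = toy_model.reactions[rid].evaluated_stoichiometry(0.7)
            again = restored.reactions[rid].evaluated_stoichiometry(0.7)
            assert original == again

    def test_unknown_reaction_type_names_the_offending_entry(
        self, toy_model, tmp_path
    ):
        path = tmp_path / "model.json"
        io.write_me_json(toy_model, path)
        data = json.loads(path.read_text())
        data["reactions"][3]["rtype"] = "alchemy"
        with pytest.raises(ValidationError, match="/reactions/3"):
            io.model_from_dict(data)

    def test_newer_schema_major_is_rejected(self, toy_model):
        data = io.model_to_dict(toy_model)
        data["schema_version"] = "2.0"
        with pytest.raises(SchemaVersionError):
            io.model_from_dict(data)

    def test_serialized_solved_round_trip_gives_same_growth_rate(
        self, toy_model, toy_solution, tmp_path
    ):
        path = tmp_path / "model.json"
        io.write_me_json(toy_model, path)
        restored = io.read_me_json(path)
        solution = solver.bisect_max_growth(restored, 0.0, 2.0, 1e-6)
        assert solution.mu_star == pytest.approx(toy_solution.mu_star, abs=2e-6)


class TestFluxTable:
    def test_table_has_one_row_per_reported_reaction(
        self, toy_model, toy_solution, tmp_path
    ):
        path = tmp_path / "fluxes.tsv"
        io.write_flux_tsv(toy_solution, path, model=toy_model)
        lines = path.read_text().splitlines()
        assert lines[0] == "reaction_id\tflux\treaction_type"
        assert len(lines) - 1 == len(toy_solution.fluxes)

    def test_rewriting_is_byte_stable(self, toy_model, toy_solution, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        io.write_flux_tsv(toy_solution, p1, model=toy_model)
        io.write_flux_tsv(toy_solution, p2, model=toy_model)
        assert p1.read_bytes() == p2.read_bytes()

    def test_floor_replaces_tiny_fluxes(self, toy_model, toy_solution, tmp_path):
        path = tmp_path / "fluxes.tsv"
        io.write_flux_tsv(toy_solution, path, model=toy_model, floor=1e-15)
        for line in path.read_text().splitlines()[1:]:
            flux = float(line.split("\t")[1])
            assert flux == 0 or abs(flux) >= 1e-15


def test_full_pipeline_over_seeds(tmp_path):
    """Generate, build, solve and knockout-screen several seeds; every
    optimum obeys the quasi-convex prefix property."""
    for seed in (11, 12):
        bundle = generate_toy_organism(tmp_path / f"s{seed}", n_genes=10,
                                       seed=seed, difficulty="full")
        model = build_me_model(bundle.build_inputs())
        solution = solver.bisect_max_growth(model, 0.0, 2.0, 1e-6)
        assert 0.0 < solution.mu_star < 10.0
        assert solver.feasible_at(model, 0.5 * solution.mu_star).feasible
        assert not solver.feasible_at(model, 1.05 * solution.mu_star + 1e-3).feasible
        calls = solver.essentiality_screen(model, ["g01", "g05"], 0.1)
        assert calls["g01"] == "essential"
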