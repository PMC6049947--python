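"""Growth-rate substitution, bisection, FVA and knockout screening."""

import pytest

from memodel import solver
from memodel.core import GrowthExpression, ZERO
from memodel.exceptions import (
    DomainError,
    InfeasibleAtMinError,
    UnknownGeneError,
)


class TestSubstitution:
    def test_coefficients_are_evaluated_at_mu(self, toy_model):
        lp = solver.substitute_growth_rate(toy_model, 0.72)
        j = lp.col_index["translation_g01"]
        i = lp.row_ids.index("ribosome")
        length = len(toy_model.get_metabolite("protein_g01").amino_acid_sequence)
        assert lp.matrix[i, j] == pytest.approx(-0.72 * length / 43200.0)

    def test_biomass_dilution_bounds_equal_mu(self, toy_model):
        lp = solver.substitute_growth_rate(toy_model, 0.5)
        j = lp.col_index["biomass_dilution"]
        assert lp.lower[j] == lp.upper[j] == 0.5

    def test_zero_growth_removes_pure_dilution_couplings(self, toy_model):
        lp = solver.substitute_growth_rate(toy_model, 0.0)
        j = lp.col_index["GLCt_FWD_CPLX_GLC"]
        i = lp.row_ids.index("CPLX_GLC")
        assert lp.matrix[i, j] == 0.0

    def test_negative_mu_is_rejected(self, toy_model):
        with pytest.raises(DomainError):
            solver.substitute_growth_rate(toy_model, -0.1)


class TestFeasibility:
    def test_zero_growth_is_always_feasible(self, toy_model):
        result = solver.feasible_at(toy_model, 0.0)
        assert result.feasible
        assert result.residual <= 1e-9

    def test_growth_far_beyond_optimum_is_infeasible(self, toy_model, toy_solution):
        assert not solver.feasible_at(toy_model, toy_solution.mu_star + 0.5).feasible

    def test_all_closed_exchanges_leave_the_zero_flux_state(self, toy_model):
        model = toy_model.copy()
        for reaction in model.reactions.values():
            if reaction.id.startswith("EX_"):
                reaction.lower_bound = ZERO
                reaction.upper_bound = ZERO
        result = solver.feasible_at(model, 0.0)
        assert result.feasible
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)


class TestBisection:
    def test_quasi_convex_prefix_property_on_a_grid(self, toy_model, toy_solution):
        """Feasibility is a prefix of the mu axis: everything below the
        optimum is feasible, everything above is not."""
        mu_star = toy_solution.mu_star
        grid = [mu_star * f for f in
                (0.1, 0.3, 0.5, 0.7, 0.9, 0.999, 1.01, 1.1, 1.3, 1.5)]
        pattern = [solver.feasible_at(toy_model, mu).feasible for mu in grid]
        assert pattern == sorted(pattern, reverse=True)
        assert pattern[:6] == [True] * 6
        assert pattern[6:] == [False] * 4

    def test_tolerance_controls_the_bracketing_gap(self, toy_model, toy_solution):
        coarse = solver.bisect_max_growth(toy_model, 0.0, 2.0, 1e-3)
        assert abs(coarse.mu_star - toy_solution.mu_star) <= 1e-3

    def test_biomass_dilution_flux_equals_mu_star(self, toy_solution):
        assert toy_solution.fluxes["biomass_dilution"] == pytest.approx(
            toy_solution.mu_star, abs=1e-9
        )

    def test_trace_records_every_probe(self, toy_solution):
        assert len(toy_solution.bisection_trace) >= 30
        feasibles = [mu for mu, ok in toy_solution.bisection_trace if ok]
        infeasibles = [mu for mu, ok in toy_solution.bisection_trace if not ok]
        assert max(feasibles) == pytest.approx(toy_solution.mu_star)
        assert min(infeasibles) - max(feasibles) <= 1e-9 * (1 + 1e-6)

    def test_upper_bracket_below_optimum_returns_the_bracket(self, toy_model):
        solution = solver.bisect_max_growth(toy_model, 0.0, 0.25, 1e-6)
        assert solution.mu_star == 0.25
        assert solution.status == "optimal"

    def test_infeasible_lower_bracket_raises(self, toy_model):
        model = toy_model.copy()
        model.reactions["EX_glc__D_e"].lower_bound = ZERO
        with pytest.raises(InfeasibleAtMinError):
            solver.bisect_max_growth(model, 0.5, 2.0, 1e-6)

    def test_invalid_bracket_or_tolerance_rejected(self, toy_model):
        with pytest.raises(DomainError):
            solver.bisect_max_growth(toy_model, 1.0, 0.5, 1e-6)
        with pytest.raises(DomainError):
            solver.bisect_max_growth(toy_model, 0.0, 1.0, 0.0)


class TestFluxVariability:
    def test_blocked_reaction_has_zero_range(self, toy_model):
        # reverse water exchange transport direction is unused when no
        # net water source exists beyond the exchange itself
        ranges = solver.flux_variability_at_mu(
            toy_model, 0.0, ["DM_dummy"], fraction_of_optimum=1.0
        )
        vmin, vmax = ranges["DM_dummy"]
        assert vmin == pytest.approx(0.0, abs=1e-9)
        assert vmax == pytest.approx(0.0, abs=1e-9)

    def test_ranges_contain_the_reported_solution_flux(self, toy_model, toy_solution):
        mu = 0.9 * toy_solution.mu_star
        result = solver.feasible_at(toy_model, mu)
        ids = ["translation_g01", "GLCt_FWD_CPLX_GLC", "transcription_TU_stable_from_RNAP_sigA"]
        ranges = solver.flux_variability_at_mu(toy_model, mu, ids)
        for reaction_id in ids:
            vmin, vmax = ranges[reaction_id]
            assert vmin <= vmax + 1e-12
            assert vmin - 1e-7 <= result.fluxes[reaction_id] <= vmax + 1e-7

    def test_essential_translation_range_shrinks_with_bisection_precision(
        self, toy_model
    ):
        """Evaluating FVA at the growth rate found with a tighter bisection
        tolerance pins expression fluxes progressively harder."""
        widths = []
        for tolerance in (1e-2, 1e-4, 1e-6):
            mu = solver.bisect_max_growth(toy_model, 0.0, 2.0, tolerance).mu_star
            ranges = solver.flux_variability_at_mu(
                toy_model, mu, ["translation_g01"]
            )
            vmin, vmax = ranges["translation_g01"]
            widths.append(vmax - vmin)
        assert widths[0] >= widths[1] >= widths[2]

    def test_floor_clips_reported_values_from_below(self, toy_model):
        ranges = solver.flux_variability_at_mu(
            toy_model, 0.0, ["translation_g01"], floor=1e-15
        )
        assert ranges["translation_g01"] == (1e-15, 1e-15)


class TestEssentiality:
    THRESHOLD = 0.1

    def test_machinery_and_uptake_genes_are_essential(self, toy_model_11):
        calls = solver.essentiality_screen(
            toy_model_11, [f"g{i:02d}" for i in range(1, 12)], self.THRESHOLD
        )
        essential = {g for g, c in calls.items() if c == "essential"}
        assert essential == {"g01", "g02", "g03", "g04", "g07", "g08", "g09"}

    def test_gene_outside_all_complexes_is_nonessential(self, toy_model_11):
        calls = solver.essentiality_screen(toy_model_11, ["g11"], self.THRESHOLD)
        assert calls["g11"] == "nonessential"

    def test_redundant_paralogs_cover_for_each_other(self, toy_model_11):
        calls = solver.essentiality_screen(
            toy_model_11, ["g05", "g06"], self.THRESHOLD
        )
        assert calls == {"g05": "nonessential", "g06": "nonessential"}

    def test_screen_is_order_independent(self, toy_model_11):
        genes = ["g01", "g05", "g10", "g11"]
        forward = solver.essentiality_screen(toy_model_11, genes, self.THRESHOLD)
        backward = solver.essentiality_screen(
            toy_model_11, genes[::-1], self.THRESHOLD
        )
        assert forward == backward

    def test_knockout_restores_model_state(self, toy_model_11):
        before = {
            r.id: (r.lower_bound, r.upper_bound)
            for r in toy_model_11.reactions.values()
        }
        solver.essentiality_screen(toy_model_11, ["g01"], self.THRESHOLD)
        after = {
            r.id: (r.lower_bound, r.upper_bound)
            for r in toy_model_11.reactions.values()
        }
        assert before == after

    def test_unknown_gene_is_reported(self, toy_model_11):
        with pytest.raises(UnknownGeneError):
            solver.essentiality_screen(toy_model_11, ["nope"], self.THRESHOLD)
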