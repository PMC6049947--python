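"""Growth-rate optimization by bisection over mu-substituted LPs.

The ME stoichiometric matrix contains growth-rate dependent coefficients
and bounds, so the model is not a single LP. It is, however, quasi-convex
in mu: if a growth rate is feasible, every smaller growth rate is feasible
too. The maximum feasible mu is therefore found by bisection, solving one
LP (maximizing production of the representative dummy complex) at each
probe. The same procedure covers batch and nutrient-limited growth.

The LP backend contract is small: accept a sparse equality system with
column bounds and an objective, return status/primal values, and allow
min/max over a single column (for FVA). scipy's HiGHS interface fulfils it
here; residual verification after each solve guards against backend
numerical failure without requiring an extended-precision solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .exceptions import (
    DomainError,
    InfeasibleAtMinError,
    InfeasibleError,
    NonConvergenceError,
    SolverBackendError,
    UnknownGeneError,
)

logger = logging.getLogger(__name__)

FEASIBILITY_TOLERANCE = 1e-9


@dataclass
class NumericLP:
    """A mu-substituted LP: S v = 0, lb <= v <= ub, maximize c."""

    matrix: sparse.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    row_ids: list
    col_ids: list
    objective_id: str | None
    col_index: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.col_index:
            self.col_index = {c: i for i, c in enumerate(self.col_ids)}


@dataclass
class FeasibilityResult:
    feasible: bool
    fluxes: dict | None
    residual: float
    objective_value: float | None


@dataclass
class Solution:
    """Outcome of a growth-rate search."""

    status: str  # "optimal" | "infeasible"
    mu_star: float
    fluxes: dict
    bisection_trace: list
    residual_norm: float
    objective_value: float | None = None


def substitute_growth_rate(model, mu):
    """Evaluate every coefficient and bound at a numeric growth rate."""
    if mu < 0:
        raise DomainError(f"growth rate must be non-negative, got {mu}")
    row_ids = list(model.metabolites)
    row_index = {m: i for i, m in enumerate(row_ids)}
    col_ids = list(model.reactions)
    rows, cols, values = [], [], []
    lower = np.zeros(len(col_ids))
    upper = np.zeros(len(col_ids))
    for j, reaction_id in enumerate(col_ids):
        reaction = model.reactions[reaction_id]
        lower[j] = reaction.lower_bound.evaluate(mu)
        upper[j] = reaction.upper_bound.evaluate(mu)
        for metabolite_id, coefficient in reaction.stoichiometry.items():
            value = coefficient.evaluate(mu)
            if value != 0.0:
                rows.append(row_index[metabolite_id])
                cols.append(j)
                values.append(value)
    matrix = sparse.csr_matrix(
        (values, (rows, cols)), shape=(len(row_ids), len(col_ids))
    )
    objective = np.zeros(len(col_ids))
    objective_id = model.objective_id
    if objective_id is not None:
        objective[col_ids.index(objective_id)] = 1.0
    return NumericLP(matrix, lower, upper, objective, row_ids, col_ids, objective_id)


def _scaled_matrix(lp):
    """Row-equilibrated constraint matrix (cached on the LP).

    ME matrices are ill-scaled -- coupling coefficients of order 1e-6 share
    rows with biomass coefficients of order 10. Dividing each row by its
    largest magnitude is exact here (the right-hand side is zero) and makes
    the backend's feasibility verdicts far more consistent near the growth
    boundary.
    """
    cached = getattr(lp, "_scaled", None)
    if cached is None:
        row_max = np.maximum(
            np.abs(lp.matrix).max(axis=1).toarray().ravel(), 1e-300
        )
        cached = sparse.diags(1.0 / row_max) @ lp.matrix
        lp._scaled = cached
    return cached


#: backend defaults: tight primal tolerance keeps the per-row violation
#: budget far below the smallest coupling coefficients
_BACKEND_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}


def _linprog(lp, cost, options=None):
    bounds = np.column_stack([lp.lower, lp.upper])
    matrix = _scaled_matrix(lp)
    return linprog(
        cost,
        A_eq=matrix,
        b_eq=np.zeros(matrix.shape[0]),
        bounds=bounds,
        method="highs",
        options={**_BACKEND_OPTIONS, **(options or {})},
    )


def _residual(lp, x):
    return float(np.abs(lp.matrix @ x).max()) if lp.matrix.nnz else 0.0


def check_feasible(lp):
    """Maximize the dummy-complex objective; report feasibility + fluxes.

    Infeasible LP status maps to ``feasible=False``. Numerical trouble is
    retried with presolve disabled before being raised as
    :class:`SolverBackendError`, distinct from genuine infeasibility. When
    the verified residual exceeds the feasibility tolerance (possible at
    near-degenerate growth rates), one re-solve with tightened backend
    tolerances is attempted and the better solution kept; a residual above
    1e-6 is treated as a backend failure.
    """
    result = _linprog(lp, -lp.objective)
    if result.status not in (0, 2):
        result = _linprog(lp, -lp.objective, options={"presolve": False})
    if result.status == 2:
        return FeasibilityResult(False, None, np.inf, None)
    if result.status != 0:
        raise SolverBackendError(
            f"LP backend failure (status {result.status}): {result.message}"
        )
    residual = _residual(lp, result.x)
    if residual > FEASIBILITY_TOLERANCE:
        tightened = _linprog(
            lp, -lp.objective, options={"primal_feasibility_tolerance": 1e-10}
        )
        if tightened.status == 0 and _residual(lp, tightened.x) < residual:
            result = tightened
            residual = _residual(lp, result.x)
    if residual > 1e-6:
        raise SolverBackendError(f"solution residual {residual:.2e} above tolerance")
    fluxes = dict(zip(lp.col_ids, result.x.tolist()))
    return FeasibilityResult(True, fluxes, residual, float(-result.fun))


def feasible_at(model, mu):
    """Convenience: substitute and test feasibility at one growth rate."""
    return check_feasible(substitute_growth_rate(model, mu))


def bisect_max_growth(model, mu_min=0.0, mu_max=2.0, tolerance=1e-12, max_iter=200):
    """Largest feasible growth rate by bisection.

    Returns a :class:`Solution` whose ``mu_star`` is the last *feasible*
    probe (a lower bound on the true optimum), with
    ``mu_hi - mu_star <= tolerance`` for the infeasible upper bracket. A
    probe that fails numerically even after retry is treated as infeasible
    and logged -- a conservative bias.
    """
    if mu_min >= mu_max:
        raise DomainError("mu_min must be strictly below mu_max")
    if tolerance <= 0:
        raise DomainError("tolerance must be positive")
    trace = []

    def probe(mu):
        try:
            result = feasible_at(model, mu)
        except SolverBackendError as err:
            logger.warning("treating mu=%g as infeasible after backend failure: %s",
                           mu, err)
            result = FeasibilityResult(False, None, np.inf, None)
        trace.append((mu, result.feasible))
        return result

    best = probe(mu_min)
    if not best.feasible:
        raise InfeasibleAtMinError(f"model infeasible at mu_min={mu_min}")
    result_hi = probe(mu_max)
    if result_hi.feasible:
        return Solution("optimal", mu_max, result_hi.fluxes, trace,
                        result_hi.residual, result_hi.objective_value)
    lo, hi = mu_min, mu_max
    iterations = 0
    while hi - lo > tolerance:
        iterations += 1
        if iterations > max_iter:
            raise NonConvergenceError(
                f"bisection did not reach tolerance {tolerance} in {max_iter} "
                f"iterations (bracket [{lo}, {hi}])"
            )
        mid = 0.5 * (lo + hi)
        result = probe(mid)
        if result.feasible:
            lo, best = mid, result
        else:
            hi = mid
    return Solution("optimal", lo, best.fluxes, trace, best.residual,
                    best.objective_value)


def _fva_subproblem(lp, cost):
    """Min/max over one column with degeneracy fallbacks.

    At a growth rate sitting on the feasibility boundary (where FVA is
    most interesting) the subproblems are borderline; retries without
    presolve and, last, with a relaxed primal tolerance keep them
    solvable.
    """
    result = _linprog(lp, cost)
    if result.status != 0:
        result = _linprog(lp, cost, options={"presolve": False})
    if result.status != 0:
        result = _linprog(
            lp, cost,
            options={"presolve": False, "primal_feasibility_tolerance": 1e-6},
        )
    return result


def flux_variability_at_mu(model, mu, reaction_ids, fraction_of_optimum=0.0,
                           floor=None):
    """Per-reaction (min, max) flux over the feasible set at fixed mu.

    With ``fraction_of_optimum > 0`` the dummy-complex objective is first
    maximized and its column constrained to that fraction of the optimum.
    ``floor`` optionally clips reported magnitudes from below (the
    convention used when plotting expression fluxes on a log scale).
    """
    lp = substitute_growth_rate(model, mu)
    base = check_feasible(lp)
    if not base.feasible:
        raise InfeasibleError(f"model infeasible at mu={mu}")
    if fraction_of_optimum > 0 and lp.objective_id is not None:
        j = lp.col_index[lp.objective_id]
        lp.lower[j] = max(lp.lower[j], fraction_of_optimum * base.objective_value)
    ranges = {}
    for reaction_id in reaction_ids:
        try:
            j = lp.col_index[reaction_id]
        except KeyError:
            raise InfeasibleError(f"unknown reaction {reaction_id!r}") from None
        cost = np.zeros(len(lp.col_ids))
        cost[j] = 1.0
        low = _fva_subproblem(lp, cost)
        high = _fva_subproblem(lp, -cost)
        if low.status != 0 or high.status != 0:
            raise SolverBackendError(
                f"FVA subproblem failed for {reaction_id} "
                f"(status {low.status}/{high.status})"
            )
        vmin, vmax = float(low.fun), float(-high.fun)
        if floor is not None:
            # log-scale reporting convention for nonnegative fluxes:
            # values below the floor are reported as the floor
            vmin, vmax = max(vmin, floor), max(vmax, floor)
        ranges[reaction_id] = (vmin, vmax)
    return ranges


def knockout_reaction_ids(model, gene_id):
    """Reactions silenced by a gene knockout: the gene's translation, and
    any transcription whose TU produces only this gene's RNA."""
    from .process_data import TranscriptionData, TranslationData

    ids = []
    rna_id = "RNA_" + gene_id
    for reaction in model.reactions.values():
        if reaction.reaction_type == "translation":
            td = model.get_process_data(reaction.translation_data_id, TranslationData)
            if td.mrna_id == rna_id or reaction.id == "translation_" + gene_id:
                ids.append(reaction.id)
        elif reaction.reaction_type == "transcription":
            txd = model.get_process_data(
                reaction.transcription_data_id, TranscriptionData
            )
            if txd.rna_products == [rna_id]:
                ids.append(reaction.id)
    if not any(r.startswith("translation_") for r in ids):
        raise UnknownGeneError(f"no translation reaction for gene {gene_id!r}")
    return ids


def essentiality_screen(model, gene_ids, growth_threshold):
    """Classify knockouts as essential/nonessential at a growth threshold.

    A gene is essential when the knockout model cannot reach the threshold
    growth rate. By quasi-convexity a single feasibility probe at the
    threshold decides this: feasible there means the maximum feasible mu is
    at least the threshold. Bounds are restored after every knockout, so
    the screen is stateless and order-independent.
    """
    if growth_threshold <= 0:
        raise DomainError("growth_threshold must be positive")
    from .core import ZERO

    calls = {}
    for gene_id in gene_ids:
        reaction_ids = knockout_reaction_ids(model, gene_id)
        saved = {}
        for reaction_id in reaction_ids:
            reaction = model.reactions[reaction_id]
            saved[reaction_id] = (reaction.lower_bound, reaction.upper_bound)
            reaction.lower_bound = ZERO
            reaction.upper_bound = ZERO
        try:
            result = feasible_at(model, growth_threshold)
        finally:
            for reaction_id, (lb, ub) in saved.items():
                reaction = model.reactions[reaction_id]
                reaction.lower_bound, reaction.upper_bound = lb, ub
        calls[gene_id] = "nonessential" if result.feasible else "essential"
    return calls
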