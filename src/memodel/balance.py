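"""Elemental mass-balance checks for compiled ME-models.

Every macromolecule carries a composition derived from its sequence
(residues minus water per bond), so compiled transcription, translation,
complex-formation and metabolic reactions can be checked element by
element. At mu = 0 the dilution couplings vanish and each reaction must
balance exactly; at mu > 0 the only imbalance permitted is the elemental
drain of diluted macromolecules.
"""

from __future__ import annotations

from . import chemistry

#: Reactions never checked: exchanges/demands (single species), summary
#: variables (biomass bookkeeping) and explicit-mode dilution arcs.
_CHECK_TYPES = {
    "metabolic",
    "transcription",
    "translation",
    "complex_formation",
    "trna_charging",
    "post_translation",
    "generic_formation",
}


def _skipped_metabolites(model):
    skip = set(model.global_info.get("pseudo_metabolites", ()))
    for metabolite in model.metabolites.values():
        if metabolite.kind == "constraint":
            skip.add(metabolite.id)
    return skip


def elemental_imbalance(model, reaction, mu=0.0, skip=None):
    """Per-element residual of a compiled reaction at a fixed growth rate.

    Positive residual means the element is created. Metabolites without a
    formula that are not registered pseudo-metabolites are reported under
    the pseudo-element ``"missing:<id>"`` so absent compositions cannot
    silently pass.
    """
    skip = _skipped_metabolites(model) if skip is None else skip
    residual = {}
    for metabolite_id, coefficient in reaction.stoichiometry.items():
        if metabolite_id in skip:
            continue
        value = coefficient.evaluate(mu)
        if value == 0.0:
            continue
        formula = model.get_metabolite(metabolite_id).formula
        if formula is None:
            residual[f"missing:{metabolite_id}"] = value
            continue
        for element, count in formula.items():
            residual[element] = residual.get(element, 0.0) + value * count
    return {e: r for e, r in residual.items() if abs(r) > 1e-12}


def dilution_drain(model, reaction, mu):
    """Elemental drain of all mu-proportional macromolecule consumptions."""
    terms = []
    for metabolite_id, coefficient in reaction.stoichiometry.items():
        metabolite = model.get_metabolite(metabolite_id)
        if coefficient.mu_coefficient < 0 and metabolite.formula is not None:
            terms.append((coefficient.mu_coefficient * mu, metabolite.formula))
    return chemistry.combine(*terms)


def check_model_balance(model, mu=0.0, tolerance=1e-8):
    """Balance every checkable reaction; returns {reaction_id: residuals}.

    An empty dict means the model passes. Reactions touching constraint
    pseudo-metabolites (explicit mode) and summary variables are exempt.
    """
    skip = _skipped_metabolites(model)
    failures = {}
    for reaction in model.reactions.values():
        if reaction.reaction_type not in _CHECK_TYPES:
            continue
        if any(m in skip and model.get_metabolite(m).kind == "constraint"
               for m in reaction.stoichiometry):
            continue
        residual = elemental_imbalance(model, reaction, mu=mu, skip=skip)
        bad = {e: r for e, r in residual.items() if abs(r) > tolerance}
        if bad:
            failures[reaction.id] = bad
    return failures
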