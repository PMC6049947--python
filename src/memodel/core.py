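"""Core containers for metabolism-and-expression (ME) models.

A ME-model layers gene-expression machinery (transcription, translation,
tRNA charging, complex formation, translocation) on top of a metabolic
network. Macromolecule synthesis is tied to the reactions the macromolecules
catalyze through coupling coefficients that are linear in the specific
growth rate mu (hr^-1): as the cell grows it dilutes its machinery to
daughter cells, so carrying flux v through a catalyzed reaction consumes
mu/k_eff * v of the catalyst.

This module defines:

* :class:`GrowthExpression` -- an exact ``constant + slope * mu`` coefficient;
* the metabolite taxonomy (small molecules, RNA, protein, complexes, ...);
* :class:`MEModel` -- the container holding metabolites, reactions, the
  ProcessData registry and the global coupling parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

from .chemistry import format_formula, parse_formula
from .exceptions import DomainError, DuplicateIdError, UnlinkedDataError


@dataclass(frozen=True)
class GrowthExpression:
    """A stoichiometric coefficient or bound linear in the growth rate.

    ``value(mu) = constant + mu_coefficient * mu``. The constant term lives
    on the flux scale (mmol gDW^-1 hr^-1 for bounds, dimensionless for
    stoichiometry); ``mu_coefficient`` multiplies mu in hr^-1, so pure
    dilution couplings have ``constant == 0``.
    """

    constant: float = 0.0
    mu_coefficient: float = 0.0

    def evaluate(self, mu):
        if mu < 0:
            raise DomainError(f"growth rate must be non-negative, got {mu}")
        value = self.constant + self.mu_coefficient * mu
        if not math.isfinite(value):
            raise DomainError(f"non-finite coefficient at mu={mu}")
        return value

    __call__ = evaluate

    @property
    def is_zero(self):
        return self.constant == 0.0 and self.mu_coefficient == 0.0

    def __add__(self, other):
        other = _as_expression(other)
        return GrowthExpression(
            self.constant + other.constant,
            self.mu_coefficient + other.mu_coefficient,
        )

    __radd__ = __add__

    def __neg__(self):
        return GrowthExpression(-self.constant, -self.mu_coefficient)

    def __sub__(self, other):
        return self + (-_as_expression(other))

    def __mul__(self, scalar):
        return GrowthExpression(self.constant * scalar, self.mu_coefficient * scalar)

    __rmul__ = __mul__

    def __repr__(self):
        return f"GrowthExpression({self.constant!r} + {self.mu_coefficient!r}*mu)"


def _as_expression(value):
    if isinstance(value, GrowthExpression):
        return value
    return GrowthExpression(float(value), 0.0)


ZERO = GrowthExpression()


def evaluate_growth_expression(expression, mu):
    """Evaluate ``constant + mu_coefficient * mu`` at a numeric growth rate."""
    return _as_expression(expression).evaluate(mu)


# ---------------------------------------------------------------------------
# Metabolite taxonomy
# ---------------------------------------------------------------------------


class MEMetabolite:
    """Base metabolite; subclasses encode the macromolecule taxonomy."""

    kind = "metabolite"

    def __init__(self, id, formula=None, compartment=None):
        self.id = id
        self.formula = parse_formula(formula) if formula is not None else None
        self.compartment = compartment

    @property
    def formula_string(self):
        return None if self.formula is None else format_formula(self.formula)

    def __eq__(self, other):
        return type(self) is type(other) and self.__dict__ == other.__dict__

    def __hash__(self):
        return hash((type(self).__name__, self.id))

    def __repr__(self):
        return f"<{type(self).__name__} {self.id}>"


class SmallMolecule(MEMetabolite):
    kind = "small_molecule"


class TranscribedGene(MEMetabolite):
    """An RNA species; sequence stored as the DNA coding strand."""

    kind = "transcribed_gene"

    def __init__(
        self,
        id,
        rna_type,
        nucleotide_sequence,
        strand=None,
        left=None,
        right=None,
        formula=None,
        compartment="c",
    ):
        super().__init__(id, formula=formula, compartment=compartment)
        if rna_type not in {"mRNA", "tRNA", "rRNA", "ncRNA"}:
            raise ValueError(f"unknown rna_type {rna_type!r}")
        self.rna_type = rna_type
        self.nucleotide_sequence = nucleotide_sequence
        self.strand = strand
        # 1-based inclusive genome coordinates (GenBank convention).
        self.left = left
        self.right = right


class TranslatedGene(MEMetabolite):
    kind = "translated_gene"

    def __init__(self, id, amino_acid_sequence, formula=None, compartment="c"):
        super().__init__(id, formula=formula, compartment=compartment)
        self.amino_acid_sequence = amino_acid_sequence


class ProcessedProtein(MEMetabolite):
    kind = "processed_protein"

    def __init__(self, id, unprocessed_id, formula=None, compartment="c"):
        super().__init__(id, formula=formula, compartment=compartment)
        self.unprocessed_id = unprocessed_id


class Complex(MEMetabolite):
    kind = "complex"


class GenericComponent(MEMetabolite):
    kind = "generic"


class ConstraintPseudoMetabolite(MEMetabolite):
    """Coupling row used only by the explicit-constraint formulation."""

    kind = "constraint"


MACROMOLECULE_KINDS = {
    "transcribed_gene",
    "translated_gene",
    "processed_protein",
    "complex",
    "generic",
}

_METABOLITE_CLASSES = {
    cls.kind: cls
    for cls in (
        SmallMolecule,
        TranscribedGene,
        TranslatedGene,
        ProcessedProtein,
        Complex,
        GenericComponent,
        ConstraintPseudoMetabolite,
    )
}


def metabolite_class(kind):
    return _METABOLITE_CLASSES[kind]


# ---------------------------------------------------------------------------
# Global parameters and the model container
# ---------------------------------------------------------------------------


@dataclass
class GlobalParameters:
    """Organism-level expression parameters.

    Rates given per second are converted to per hour (x3600) where coupling
    coefficients are compiled; defaults are field conventions for a fast
    growing bacterium and are fully configurable.
    """

    ribosome_rate_aa_per_s: float = 12.0
    rnap_rate_nt_per_s: float = 55.0
    default_keff_per_s: float = 65.0
    #: mRNA decay, hr^-1 (half-life ~5 min).
    k_deg_mrna_per_hr: float = math.log(2) / 0.083
    codon_table_id: int = 11
    start_codons: tuple = ("ATG", "GTG", "TTG")
    #: fixed biomass fractions drained per unit growth, g gDW^-1
    dna_biomass_fraction: float = 0.03
    lipid_biomass_fraction: float = 0.09

    def to_dict(self):
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data):
        data = dict(data)
        if "start_codons" in data:
            data["start_codons"] = tuple(data["start_codons"])
        return cls(**data)


class MEModel:
    """Container of metabolites, ME-reactions and the ProcessData registry.

    Insertion order of metabolites and reactions is preserved and defines
    the row/column order of the numeric LP, which keeps builds and
    serializations deterministic.
    """

    def __init__(self, id="me_model", parameters=None):
        self.id = id
        self.metabolites = {}
        self.reactions = {}
        self.process_data = {}
        self.global_parameters = parameters or GlobalParameters()
        self.coupling_mode = "embedded"
        self.objective_id = None
        # Free-form build metadata: machinery ids, pseudo-metabolite ids, ...
        self.global_info = {}

    # -- metabolites ------------------------------------------------------
    def add_metabolite(self, metabolite, exist_ok=False):
        existing = self.metabolites.get(metabolite.id)
        if existing is not None:
            if exist_ok:
                return existing
            raise DuplicateIdError(f"metabolite {metabolite.id!r} already in model")
        self.metabolites[metabolite.id] = metabolite
        return metabolite

    def get_metabolite(self, metabolite_id):
        try:
            return self.metabolites[metabolite_id]
        except KeyError:
            raise KeyError(f"metabolite {metabolite_id!r} not in model") from None

    # -- reactions --------------------------------------------------------
    def add_reaction(self, reaction):
        if reaction.id in self.reactions:
            raise DuplicateIdError(f"reaction {reaction.id!r} already in model")
        self.reactions[reaction.id] = reaction
        return reaction

    def reactions_of_type(self, reaction_type):
        return [r for r in self.reactions.values() if r.reaction_type == reaction_type]

    def update_all(self):
        """Recompile every reaction from its linked ProcessData."""
        for reaction in list(self.reactions.values()):
            reaction.update(self)

    # -- ProcessData registry --------------------------------------------
    def register_process_data(self, pdata):
        """Register a ProcessData record; idempotent for identical content.

        Re-registering the same id with *different* content raises
        :class:`DuplicateIdError` -- silent overwrites would hide data
        inconsistencies between input tables.
        """
        if not pdata.id:
            raise ValueError("ProcessData id must be non-empty")
        existing = self.process_data.get(pdata.id)
        if existing is not None:
            if existing == pdata:
                return pdata.id
            raise DuplicateIdError(
                f"process data {pdata.id!r} already registered with different content"
            )
        self.process_data[pdata.id] = pdata
        return pdata.id

    def get_process_data(self, data_id, expected_type=None):
        try:
            pdata = self.process_data[data_id]
        except KeyError:
            raise UnlinkedDataError(f"process data {data_id!r} not registered") from None
        if expected_type is not None and not isinstance(pdata, expected_type):
            raise UnlinkedDataError(
                f"process data {data_id!r} is {type(pdata).__name__}, "
                f"expected {expected_type.__name__}"
            )
        return pdata

    def process_data_of_type(self, data_type):
        return [p for p in self.process_data.values() if isinstance(p, data_type)]

    def copy(self):
        import copy

        return copy.deepcopy(self)

    def __repr__(self):
        return (
            f"<MEModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, "
            f"{len(self.process_data)} process data ({self.coupling_mode})>"
        )


def register_process_data(model, pdata):
    """Functional alias for :meth:`MEModel.register_process_data`."""
    return model.register_process_data(pdata)
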