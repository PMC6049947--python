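"""The MEReaction family: compiled reactions with growth-rate coupling.

Each reaction type reads its linked ProcessData record(s) and compiles a
complete stoichiometry whose coefficients are :class:`GrowthExpression`
instances (linear in mu). Calling :meth:`~MEReaction.update` recompiles the
stoichiometry from scratch, so update is idempotent and the compiled form is
a pure function of the registry plus global parameters.

Coupling conventions (all rates converted from s^-1 to hr^-1 at compile
time):

* a catalyst turning over at k_eff is consumed at ``mu / (k_eff * 3600)``
  per unit flux (dilution to daughter cells);
* a templated polymerase/ribosome working through a template of length L at
  ``rate`` residues/s is consumed at ``mu * L / (rate * 3600)`` -- the
  dilution form with an effective per-template k_eff of rate/L;
* mRNA is consumed at ``(mu + k_deg) / k_transl_eff`` with
  ``k_transl_eff = ribosome_rate * 3600 / L_aa``; the degraded fraction
  returns its nucleotides as NMPs (plus an ATP cost per nucleotide through a
  degradosome subreaction), the diluted fraction is lost to daughter cells.
"""

from __future__ import annotations

from . import chemistry
from .chemistry import SECONDS_PER_HOUR
from .core import (
    Complex,
    ConstraintPseudoMetabolite,
    GenericComponent,
    GrowthExpression,
    MACROMOLECULE_KINDS,
    ProcessedProtein,
    ZERO,
    _as_expression,
)
from .exceptions import (
    DomainError,
    ModeError,
    UnknownMetaboliteError,
)
from .process_data import (
    ComplexData,
    GenericData,
    PostTranslationData,
    StoichiometricData,
    SubreactionData,
    TranscriptionData,
    TranslationData,
    TranslocationData,
    tRNAData,
)

DEFAULT_UPPER_BOUND = 1e6


def dilution_coefficient(keff_per_s):
    """Catalyst consumed per unit flux: ``mu / (k_eff * 3600)`` (hr units)."""
    if keff_per_s <= 0:
        raise DomainError(f"keff must be positive, got {keff_per_s}")
    return GrowthExpression(0.0, 1.0 / (keff_per_s * SECONDS_PER_HOUR))


def machine_coupling_coefficient(template_length, rate_per_s):
    """Templated-machine usage: ``mu * L / (rate * 3600)``.

    The natural dilution form when turnover is per template: the effective
    k_eff of producing one template copy is rate / L.
    """
    if template_length <= 0 or rate_per_s <= 0:
        raise DomainError(
            f"length and rate must be positive, got L={template_length}, "
            f"rate={rate_per_s}"
        )
    return GrowthExpression(0.0, template_length / (rate_per_s * SECONDS_PER_HOUR))


class MEReaction:
    """Base reaction: id, mu-symbolic stoichiometry and bounds."""

    reaction_type = "plain"

    def __init__(self, id, lower_bound=ZERO, upper_bound=None):
        self.id = id
        self.stoichiometry = {}
        self.lower_bound = _as_expression(lower_bound)
        self.upper_bound = _as_expression(
            DEFAULT_UPPER_BOUND if upper_bound is None else upper_bound
        )

    # -- stoichiometry helpers -------------------------------------------
    def add_term(self, metabolite_id, coefficient):
        current = self.stoichiometry.get(metabolite_id, ZERO)
        total = current + _as_expression(coefficient)
        if total.is_zero:
            self.stoichiometry.pop(metabolite_id, None)
        else:
            self.stoichiometry[metabolite_id] = total

    def evaluated_stoichiometry(self, mu):
        return {m: c.evaluate(mu) for m, c in self.stoichiometry.items()}

    def _require_metabolite(self, model, metabolite_id):
        """Small molecules must pre-exist; creation on demand is reserved
        for macromolecule products."""
        try:
            return model.get_metabolite(metabolite_id)
        except KeyError:
            raise UnknownMetaboliteError(
                f"{self.id}: metabolite {metabolite_id!r} not in model "
                "(small molecules are never created on demand)"
            ) from None

    def _get_or_create(self, model, metabolite_id, factory):
        existing = model.metabolites.get(metabolite_id)
        if existing is not None:
            return existing
        return model.add_metabolite(factory())

    def _use_enzyme(self, model, enzyme_id, coupling):
        """Consume a catalyst at a mu-linear coupling coefficient."""
        self._get_or_create(model, enzyme_id, lambda: Complex(enzyme_id, compartment="c"))
        self.add_term(enzyme_id, -coupling)

    def _apply_subreaction(self, model, subreaction_id, count):
        sdata = model.get_process_data(subreaction_id, SubreactionData)
        for metabolite_id, coefficient in sorted(sdata.stoichiometry.items()):
            metabolite = model.metabolites.get(metabolite_id)
            if metabolite is None:
                raise UnknownMetaboliteError(
                    f"{self.id}: subreaction {subreaction_id} references unknown "
                    f"metabolite {metabolite_id!r}"
                )
            self.add_term(metabolite_id, count * coefficient)
        keff = sdata.keff or model.global_parameters.default_keff_per_s
        for enzyme_id in sdata.enzymes:
            self._use_enzyme(model, enzyme_id, count * dilution_coefficient(keff))
        return sdata

    def _subreaction_net_elements(self, model, subreaction_id, count):
        """Net elemental flow *into* the product of a modification step."""
        sdata = model.get_process_data(subreaction_id, SubreactionData)
        terms = []
        for metabolite_id, coefficient in sdata.stoichiometry.items():
            formula = model.get_metabolite(metabolite_id).formula
            if formula:
                terms.append((-count * coefficient, formula))
        return chemistry.combine(*terms)

    def update(self, model):
        """Recompile stoichiometry from linked ProcessData (no-op here)."""

    def __repr__(self):
        return f"<{type(self).__name__} {self.id}>"


class PlainReaction(MEReaction):
    """A reaction with fixed stoichiometry and no ProcessData link
    (exchanges, demands, explicit-mode dilution arcs)."""

    reaction_type = "plain"

    def __init__(self, id, stoichiometry=None, lower_bound=ZERO, upper_bound=None):
        super().__init__(id, lower_bound, upper_bound)
        for metabolite_id, coefficient in (stoichiometry or {}).items():
            self.add_term(metabolite_id, coefficient)


class SummaryVariable(MEReaction):
    """A global balance (biomass dilution, fixed demands) rather than a
    chemical conversion; exempt from elemental checks."""

    reaction_type = "summary"

    def __init__(self, id, stoichiometry=None, lower_bound=ZERO, upper_bound=None):
        super().__init__(id, lower_bound, upper_bound)
        for metabolite_id, coefficient in (stoichiometry or {}).items():
            self.add_term(metabolite_id, coefficient)


class MetabolicReaction(MEReaction):
    """A direction-split metabolic reaction with its catalyzing complex."""

    reaction_type = "metabolic"

    def __init__(self, id, stoichiometric_data_id, complex_id=None,
                 direction="forward", keff=None):
        super().__init__(id)
        if direction not in {"forward", "reverse"}:
            raise ValueError(f"direction must be forward/reverse, got {direction!r}")
        self.stoichiometric_data_id = stoichiometric_data_id
        self.complex_id = complex_id
        self.direction = direction
        self.keff = keff  # s^-1; None -> model default

    def update(self, model):
        self.stoichiometry = {}
        sdata = model.get_process_data(self.stoichiometric_data_id, StoichiometricData)
        sign = 1.0 if self.direction == "forward" else -1.0
        for metabolite_id, coefficient in sorted(sdata.stoichiometry.items()):
            self._require_metabolite(model, metabolite_id)
            self.add_term(metabolite_id, sign * coefficient)
        if self.complex_id is not None:
            keff = self.keff or model.global_parameters.default_keff_per_s
            self._use_enzyme(model, self.complex_id, dilution_coefficient(keff))
        self.lower_bound = ZERO
        if self.direction == "forward":
            self.upper_bound = GrowthExpression(max(sdata.upper_bound, 0.0))
        else:
            self.upper_bound = GrowthExpression(max(-sdata.lower_bound, 0.0))


class TranscriptionReaction(MEReaction):
    """Lumped transcription of one TU by one RNA polymerase variant."""

    reaction_type = "transcription"

    def __init__(self, id, transcription_data_id):
        super().__init__(id)
        self.transcription_data_id = transcription_data_id

    def update(self, model):
        self.stoichiometry = {}
        txd = model.get_process_data(self.transcription_data_id, TranscriptionData)
        sequence = txd.nucleotide_sequence
        length = len(sequence)
        for ntp, count in sorted(chemistry.nucleotide_counts(sequence).items()):
            ntp_id = ntp + "_c"
            self._require_metabolite(model, ntp_id)
            self.add_term(ntp_id, -count)
        self._require_metabolite(model, "ppi_c")
        self.add_term("ppi_c", float(length))

        rna_mass = 0.0
        product_bases = {}
        for product_id in txd.rna_products:
            product = model.get_metabolite(product_id)
            self.add_term(product_id, 1.0)
            rna_mass += chemistry.formula_mass(product.formula)
            for base, n in chemistry.base_counts(product.nucleotide_sequence).items():
                product_bases[base] = product_bases.get(base, 0.0) + n

        # Excised spacer nucleotides return to the NMP pool; freeing one
        # residue as a nucleoside monophosphate consumes one water.
        spacer_total = 0.0
        for base, n in sorted(chemistry.base_counts(sequence).items()):
            spacer = n - product_bases.get(base, 0.0)
            if spacer > 1e-9:
                nmp_id = chemistry.DNA_BASE_TO_NMP[base] + "_c"
                self._require_metabolite(model, nmp_id)
                self.add_term(nmp_id, spacer)
                spacer_total += spacer
        if spacer_total:
            self._require_metabolite(model, "h2o_c")
            self.add_term("h2o_c", -spacer_total)
        for subreaction_id, count in sorted(txd.excision_subreactions.items()):
            self._apply_subreaction(model, subreaction_id, count)

        rate = model.global_parameters.rnap_rate_nt_per_s
        self._use_enzyme(
            model, txd.rna_polymerase, machine_coupling_coefficient(length, rate)
        )
        constituent = model.global_info.get("rna_biomass_id")
        if constituent and rna_mass:
            self.add_term(constituent, rna_mass / 1000.0)  # g per mmol flux


class TranslationReaction(MEReaction):
    """Lumped translation of one gene: all components and coupling in one
    place (``translation_<gene_id>``)."""

    reaction_type = "translation"

    def __init__(self, id, translation_data_id):
        super().__init__(id)
        self.translation_data_id = translation_data_id

    def update(self, model):
        self.stoichiometry = {}
        params = model.global_parameters
        td = model.get_process_data(self.translation_data_id, TranslationData)
        aa_sequence = td.amino_acid_sequence(params.codon_table_id, params.start_codons)
        protein_length = len(aa_sequence)
        mrna = model.get_metabolite(td.mrna_id)
        mrna_length = len(mrna.nucleotide_sequence)

        for subreaction_id, count in sorted(td.subreactions.items()):
            self._apply_subreaction(model, subreaction_id, count)

        ribosome_id = model.global_info.get("ribosome_id", "ribosome")
        rate = params.ribosome_rate_aa_per_s
        self._use_enzyme(
            model, ribosome_id, machine_coupling_coefficient(protein_length, rate)
        )

        # mRNA: consumed at (mu + k_deg)/k_transl_eff. The k_deg part is
        # degradation -- nucleotides come back as NMPs at one water per
        # residue plus an ATP cost through the degradosome subreaction.
        # The mu part is dilution and is lost to daughter cells.
        k_transl_eff = rate * SECONDS_PER_HOUR / protein_length  # hr^-1
        k_deg = params.k_deg_mrna_per_hr
        self.add_term(td.mrna_id, GrowthExpression(-k_deg / k_transl_eff,
                                                   -1.0 / k_transl_eff))
        degraded = k_deg / k_transl_eff
        for base, n in sorted(chemistry.base_counts(mrna.nucleotide_sequence).items()):
            nmp_id = chemistry.DNA_BASE_TO_NMP[base] + "_c"
            self._require_metabolite(model, nmp_id)
            self.add_term(nmp_id, degraded * n)
        self._require_metabolite(model, "h2o_c")
        self.add_term("h2o_c", -degraded * mrna_length)
        degradation_sub = model.global_info.get("mrna_degradation_subreaction")
        if degradation_sub:
            self._apply_subreaction(model, degradation_sub, degraded * mrna_length)

        protein = model.get_metabolite(td.protein_id)
        self.add_term(td.protein_id, 1.0)
        protein_constituent = model.global_info.get("protein_biomass_id")
        if protein_constituent:
            self.add_term(
                protein_constituent, chemistry.formula_mass(protein.formula) / 1000.0
            )
        rna_constituent = model.global_info.get("rna_biomass_id")
        if rna_constituent:
            # degraded mRNA mass leaves the RNA biomass pool again
            self.add_term(
                rna_constituent, -degraded * chemistry.formula_mass(mrna.formula) / 1000.0
            )


class ComplexFormation(MEReaction):
    """Assembly of an enzyme complex from its subunits plus modifications."""

    reaction_type = "complex_formation"

    def __init__(self, id, complex_data_id):
        super().__init__(id)
        self.complex_data_id = complex_data_id

    def update(self, model):
        self.stoichiometry = {}
        cdata = model.get_process_data(self.complex_data_id, ComplexData)
        composition_terms = []
        for subunit_id, count in sorted(cdata.subunit_stoichiometry.items()):
            subunit = model.get_metabolite(subunit_id)
            self.add_term(subunit_id, -float(count))
            if subunit.formula:
                composition_terms.append((float(count), subunit.formula))
        for subreaction_id, count in sorted(cdata.modifications.items()):
            self._apply_subreaction(model, subreaction_id, count)
            net = self._subreaction_net_elements(model, subreaction_id, count)
            if net:
                composition_terms.append((1.0, net))
        complex_met = self._get_or_create(
            model, cdata.complex_id, lambda: Complex(cdata.complex_id, compartment="c")
        )
        complex_met.formula = chemistry.combine(*composition_terms) or None
        self.add_term(cdata.complex_id, 1.0)


class tRNAChargingReaction(MEReaction):  # noqa: N801
    """Aminoacylation: amino acid + tRNA + ATP -> charged tRNA + AMP + PPi.

    The uncharged tRNA carries an extra mu/(k_eff*3600) consumption so that
    the stable tRNA pool must keep being synthesized in a growing cell.
    """

    reaction_type = "trna_charging"

    def __init__(self, id, trna_data_id):
        super().__init__(id)
        self.trna_data_id = trna_data_id

    def update(self, model):
        self.stoichiometry = {}
        td = model.get_process_data(self.trna_data_id, tRNAData)
        aa_id = td.amino_acid + "_c"
        self._require_metabolite(model, aa_id)
        for met in ("atp_c", "amp_c", "ppi_c"):
            self._require_metabolite(model, met)
        trna_met_id = "RNA_" + td.trna_id
        trna = model.get_metabolite(trna_met_id)

        keff = model.global_parameters.default_keff_per_s
        self.add_term(aa_id, -1.0)
        self.add_term("atp_c", -1.0)
        self.add_term(trna_met_id, GrowthExpression(-1.0) - dilution_coefficient(keff))
        self.add_term("amp_c", 1.0)
        self.add_term("ppi_c", 1.0)
        if td.synthetase:
            self._use_enzyme(model, td.synthetase, dilution_coefficient(keff))

        composition_terms = [(1.0, trna.formula),
                             (1.0, chemistry.AA_FORMULA[chemistry.ID_TO_AA1[td.amino_acid]]),
                             (-1.0, chemistry.WATER)]
        for subreaction_id, count in sorted(td.modifications.items()):
            self._apply_subreaction(model, subreaction_id, count)
            net = self._subreaction_net_elements(model, subreaction_id, count)
            if net:
                composition_terms.append((1.0, net))

        charged_id = "generic_tRNA_" + td.amino_acid
        charged = self._get_or_create(
            model, charged_id, lambda: GenericComponent(charged_id, compartment="c")
        )
        charged.formula = chemistry.combine(*composition_terms)
        self.add_term(charged_id, 1.0)


class PostTranslationReaction(MEReaction):
    """Maturation/translocation of a protein into its processed form."""

    reaction_type = "post_translation"

    def __init__(self, id, post_translation_data_id):
        super().__init__(id)
        self.post_translation_data_id = post_translation_data_id

    def update(self, model):
        self.stoichiometry = {}
        pd = model.get_process_data(self.post_translation_data_id, PostTranslationData)
        protein = model.get_metabolite(pd.protein_id)
        length = float(len(protein.amino_acid_sequence))
        composition_terms = [(1.0, protein.formula)]

        for pathway_id in pd.translocation_pathways:
            tl = model.get_process_data(pathway_id, TranslocationData)
            for metabolite_id, per_residue in sorted(tl.stoichiometry.items()):
                self._require_metabolite(model, metabolite_id)
                self.add_term(metabolite_id, per_residue * length)
            for enzyme_id, usage in sorted(tl.enzymes.items()):
                if usage.get("length_dependent"):
                    coupling = GrowthExpression(
                        0.0, length / (tl.keff * SECONDS_PER_HOUR)
                    )
                else:
                    coupling = dilution_coefficient(tl.keff)
                self._use_enzyme(model, enzyme_id, coupling)
        for subreaction_id, count in sorted(pd.modifications.items()):
            self._apply_subreaction(model, subreaction_id, count)
            net = self._subreaction_net_elements(model, subreaction_id, count)
            if net:
                composition_terms.append((1.0, net))

        self.add_term(pd.protein_id, -1.0)
        processed = self._get_or_create(
            model,
            pd.processed_protein_id,
            lambda: ProcessedProtein(
                pd.processed_protein_id, pd.protein_id, compartment="m"
            ),
        )
        processed.formula = chemistry.combine(*composition_terms)
        self.add_term(pd.processed_protein_id, 1.0)


class GenericFormationReaction(MEReaction):
    """member -> generic, 1:1; one reaction per member of a GenericData."""

    reaction_type = "generic_formation"

    def __init__(self, id, generic_data_id, member_id):
        super().__init__(id)
        self.generic_data_id = generic_data_id
        self.member_id = member_id

    def update(self, model):
        self.stoichiometry = {}
        gdata = model.get_process_data(self.generic_data_id, GenericData)
        if self.member_id not in gdata.members:
            raise UnknownMetaboliteError(
                f"{self.id}: {self.member_id} is not a member of {gdata.id}"
            )
        member = model.get_metabolite(self.member_id)
        generic = self._get_or_create(
            model,
            gdata.generic_id,
            lambda: GenericComponent(gdata.generic_id, compartment="c"),
        )
        if generic.formula is None:
            reference = model.get_metabolite(sorted(gdata.members)[0])
            generic.formula = reference.formula
        self.add_term(self.member_id, -1.0)
        self.add_term(gdata.generic_id, 1.0)


REACTION_TYPES = {
    cls.reaction_type: cls
    for cls in (
        PlainReaction,
        SummaryVariable,
        MetabolicReaction,
        TranscriptionReaction,
        TranslationReaction,
        ComplexFormation,
        tRNAChargingReaction,
        PostTranslationReaction,
        GenericFormationReaction,
    )
}


# ---------------------------------------------------------------------------
# Explicit-constraint (pseudo-metabolite) reformulation
# ---------------------------------------------------------------------------


def convert_to_explicit_constraints(model):
    """Rewrite embedded mu/k_eff couplings as explicit pseudo-metabolites.

    For every macromolecule consumed with a mu-proportional (dilution) term
    ``-s * mu`` inside a reaction, the term is replaced by production of a
    coupling pseudo-metabolite at ``+s * mu`` plus a dedicated dilution
    reaction consuming one pseudo-metabolite and one macromolecule. The LP
    feasible set at every fixed mu is identical to the embedded form; row
    and column counts are strictly larger. Returns a new model; the input
    is untouched.
    """
    if model.coupling_mode != "embedded":
        raise ModeError("model is already in explicit-constraint mode")
    explicit = model.copy()
    for reaction in list(explicit.reactions.values()):
        for metabolite_id in sorted(reaction.stoichiometry):
            coefficient = reaction.stoichiometry[metabolite_id]
            metabolite = explicit.get_metabolite(metabolite_id)
            if metabolite.kind not in MACROMOLECULE_KINDS:
                continue
            if coefficient.mu_coefficient >= 0:
                continue
            slope = -coefficient.mu_coefficient
            reaction.stoichiometry[metabolite_id] = GrowthExpression(
                coefficient.constant, 0.0
            )
            if reaction.stoichiometry[metabolite_id].is_zero:
                del reaction.stoichiometry[metabolite_id]
            pseudo_id = f"constraint_{metabolite_id}_{reaction.id}"
            explicit.add_metabolite(ConstraintPseudoMetabolite(pseudo_id))
            # the pseudo-metabolite is produced at a pure mu coefficient and
            # the k_eff slope lives on the dilution arc, so the new rows are
            # as well-conditioned as the embedded form they replace
            reaction.add_term(pseudo_id, GrowthExpression(0.0, 1.0))
            explicit.add_reaction(
                PlainReaction(
                    f"dilution_{metabolite_id}_{reaction.id}",
                    {pseudo_id: -1.0, metabolite_id: -slope},
                    lower_bound=ZERO,
                    upper_bound=DEFAULT_UPPER_BOUND,
                )
            )
    explicit.coupling_mode = "explicit"
    return explicit
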