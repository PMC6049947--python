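"""Build a ME-model from an M-model, a genome annotation and expression tables.

The workflow mirrors how expression-aware reconstructions are assembled in
practice: load the metabolic model and the GenBank annotation, walk through
each gene-expression process (transcription units, translation, tRNA
charging, complex formation, translocation), populate the corresponding
ProcessData records, attach them to MEReaction instances, and compile the
whole model with :meth:`MEModel.update_all`.

Input conventions (all TSVs tab-delimited, UTF-8, ``#`` comments):

* ``tu_table``: tu_id, left, right, strand, genes (comma list), rnap,
  excision (optional ``<complex>:<n_cuts>`` -- the machinery that excises
  stable RNAs from a polycistronic transcript).
* ``enzyme_table``: complex_id, subunits (``id:count`` comma list),
  modifications (``mod_<met>:count`` comma list). Rows whose id starts with
  ``generic_`` define interchangeable-component pools instead.
* ``keff_table``: target_id, target_type (reaction|complex), keff (s^-1).
* ``translocation_table``: pathway_id, keff, enzymes (``id:fixed`` or
  ``id:length_dependent``), stoichiometry (per-residue ``met:coeff`` list),
  targets (comma list of gene ids using the pathway).
* tRNA GenBank features carry a ``/note="amino_acid:<id>;codon:<codon>"``
  qualifier assigning the isoacceptor.

Modifications named ``mod_<met>`` auto-create a SubreactionData that
consumes one ``<met>_c`` per count, so cofactor loading stays data-driven.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field

import cobra.io
import pandas as pd
from Bio import SeqIO

from . import chemistry
from .chemistry import reverse_complement  # re-exported builder op
from .core import (
    GlobalParameters,
    GrowthExpression,
    MEModel,
    ProcessedProtein,
    SmallMolecule,
    TranscribedGene,
    TranslatedGene,
    ZERO,
)
from .exceptions import (
    CompositionError,
    DanglingReferenceError,
    MissingGeneError,
    UnbalancedReactionError,
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
from .reactions import (
    ComplexFormation,
    GenericFormationReaction,
    MetabolicReaction,
    PlainReaction,
    PostTranslationReaction,
    SummaryVariable,
    TranscriptionReaction,
    TranslationReaction,
    tRNAChargingReaction,
)
from . import balance

logger = logging.getLogger(__name__)

DUMMY_GENE_ID = "dummy"
DUMMY_COMPLEX_ID = "CPLX_dummy"
DUMMY_DEMAND_ID = "DM_dummy"


def uniform_composition():
    """Uniform amino-acid composition over the 20 standard residues."""
    ids = sorted(chemistry.AA1_TO_ID.values())
    return {aa: 1.0 / len(ids) for aa in ids}


@dataclass
class BuildInputs:
    """Paths and organism-level choices feeding one build."""

    m_model_path: str
    genbank_path: str
    tu_table_path: str
    enzyme_table_path: str
    keff_table_path: str
    translocation_table_path: str
    dummy_composition: dict = field(default_factory=uniform_composition)
    dummy_length: int = 100
    default_rnap: str = "RNAP_sigA"
    ribosome_id: str = "ribosome"
    synthetase_id: str | None = None
    degradosome_id: str | None = None
    elongation_enzyme: str | None = None
    lipid_metabolite: str | None = "lipid_toy_c"

    def validate(self):
        total = sum(self.dummy_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(
                f"dummy composition fractions sum to {total}, expected 1"
            )
        unknown = set(self.dummy_composition) - set(chemistry.ID_TO_AA1)
        if unknown:
            raise CompositionError(f"unknown amino acids in composition: {sorted(unknown)}")


def _read_table(path, columns):
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = set(columns) - set(table.columns)
    if missing:
        raise DanglingReferenceError(f"{path}: missing columns {sorted(missing)}")
    return table


def _parse_pairs(text, cast=float):
    """Parse ``'a:1,b:2'`` into ``{'a': 1, 'b': 2}`` (empty string -> {})."""
    out = {}
    for item in filter(None, (s.strip() for s in text.split(","))):
        key, _, value = item.partition(":")
        out[key.strip()] = cast(value) if value else 1
    return out


def gpr_conjunctions(rule):
    """Expand a gene-protein-reaction rule into DNF gene sets.

    Each returned frozenset is one alternative catalyst (AND within,
    OR across). Gene ids must be valid identifiers.
    """
    rule = (rule or "").strip()
    if not rule:
        return []
    tree = ast.parse(rule.replace(" AND ", " and ").replace(" OR ", " or "),
                     mode="eval").body

    def walk(node):
        if isinstance(node, ast.Name):
            return [frozenset([node.id])]
        if isinstance(node, ast.BoolOp):
            parts = [walk(value) for value in node.values]
            if isinstance(node.op, ast.Or):
                return [c for part in parts for c in part]
            combos = [frozenset()]
            for part in parts:
                combos = [a | b for a in combos for b in part]
            return combos
        raise ValueError(f"unsupported GPR construct: {ast.dump(node)}")

    return walk(tree)


class _Builder:
    """One-shot orchestration of the reconstruction workflow."""

    def __init__(self, inputs, parameters=None):
        inputs.validate()
        self.inputs = inputs
        self.model = MEModel(parameters=parameters or GlobalParameters())
        self.genes = {}  # locus_tag -> feature info
        self.trna_of_aa = {}  # amino-acid id -> tRNA gene id
        self.complex_genes = {}  # complex id -> frozenset of base gene ids
        self.keff_by_reaction = {}
        self.keff_by_complex = {}
        self.spontaneous = set()
        self.stoich_complexes = {}  # stoich data id -> list of complex ids

    # -- genome -----------------------------------------------------------
    def read_genome(self):
        record = SeqIO.read(self.inputs.genbank_path, "genbank")
        self.genome = str(record.seq).upper()
        for feature in record.features:
            if feature.type not in {"CDS", "tRNA", "rRNA"}:
                continue
            locus = feature.qualifiers["locus_tag"][0]
            left = int(feature.location.start) + 1  # to 1-based inclusive
            right = int(feature.location.end)
            strand = "+" if feature.location.strand >= 0 else "-"
            sequence = self.genome[left - 1 : right]
            if strand == "-":
                sequence = reverse_complement(sequence)
            info = {
                "type": feature.type,
                "left": left,
                "right": right,
                "strand": strand,
                "sequence": sequence,
            }
            if feature.type == "tRNA":
                note = feature.qualifiers.get("note", [""])[0]
                fields = dict(
                    part.split(":", 1) for part in note.split(";") if ":" in part
                )
                info["amino_acid"] = fields.get("amino_acid", "")
                info["codon"] = fields.get("codon", "")
            self.genes[locus] = info
        for locus, info in self.genes.items():
            rna_type = {"CDS": "mRNA", "tRNA": "tRNA", "rRNA": "rRNA"}[info["type"]]
            self.model.add_metabolite(
                TranscribedGene(
                    "RNA_" + locus,
                    rna_type=rna_type,
                    nucleotide_sequence=info["sequence"],
                    strand=info["strand"],
                    left=info["left"],
                    right=info["right"],
                    formula=chemistry.rna_composition(info["sequence"]),
                )
            )
            if info["type"] == "tRNA":
                self.trna_of_aa[info["amino_acid"]] = locus

    # -- M-model ----------------------------------------------------------
    def read_m_model(self):
        m_model = cobra.io.load_json_model(self.inputs.m_model_path)
        self.m_model = m_model
        for metabolite in m_model.metabolites:
            self.model.add_metabolite(
                SmallMolecule(
                    metabolite.id,
                    formula=metabolite.formula or None,
                    compartment=metabolite.compartment,
                )
            )
        self.m_objective_ids = {
            reaction.id
            for reaction in m_model.reactions
            if reaction.objective_coefficient
        }

    def add_exchanges(self):
        for reaction in self.m_model.reactions:
            if not reaction.boundary:
                continue
            self.model.add_reaction(
                PlainReaction(
                    reaction.id,
                    {m.id: c for m, c in reaction.metabolites.items()},
                    lower_bound=GrowthExpression(reaction.lower_bound),
                    upper_bound=GrowthExpression(reaction.upper_bound),
                )
            )

    # -- expression machinery data ---------------------------------------
    def add_translation_subreactions(self):
        model = self.model
        register = model.register_process_data
        register(
            SubreactionData(
                "translation_initiation",
                stoichiometry={"gtp_c": -1.0, "h2o_c": -1.0, "gdp_c": 1.0, "pi_c": 1.0},
            )
        )
        # termination: one GTP hydrolysis plus one water for peptide release
        register(
            SubreactionData(
                "translation_termination",
                stoichiometry={"gtp_c": -1.0, "h2o_c": -2.0, "gdp_c": 1.0, "pi_c": 1.0},
            )
        )
        elongation_enzymes = (
            [self.inputs.elongation_enzyme] if self.inputs.elongation_enzyme else []
        )
        for aa_id, trna_gene in sorted(self.trna_of_aa.items()):
            # 2 GTP per elongation step (EF-Tu- and EF-G-like factors)
            register(
                SubreactionData(
                    f"addition_{aa_id}",
                    stoichiometry={
                        f"generic_tRNA_{aa_id}": -1.0,
                        f"RNA_{trna_gene}": 1.0,
                        "gtp_c": -2.0,
                        "h2o_c": -2.0,
                        "gdp_c": 2.0,
                        "pi_c": 2.0,
                    },
                    enzymes=list(elongation_enzymes),
                )
            )
        degradosome = self.inputs.degradosome_id
        register(
            SubreactionData(
                "mRNA_degradation",
                stoichiometry={"atp_c": -0.25, "h2o_c": -0.25,
                               "adp_c": 0.25, "pi_c": 0.25},
                enzymes=[degradosome] if degradosome else [],
            )
        )
        model.global_info["mrna_degradation_subreaction"] = "mRNA_degradation"

    def _ensure_modification(self, name):
        if name in self.model.process_data:
            return
        if not name.startswith("mod_"):
            raise DanglingReferenceError(
                f"modification {name!r} is not registered and does not follow "
                "the mod_<metabolite> convention"
            )
        metabolite_id = name[len("mod_"):] + "_c"
        if metabolite_id not in self.model.metabolites:
            raise DanglingReferenceError(
                f"modification {name!r} needs metabolite {metabolite_id!r}"
            )
        self.model.register_process_data(
            SubreactionData(name, stoichiometry={metabolite_id: -1.0})
        )

    def add_complexes(self):
        table = _read_table(
            self.inputs.enzyme_table_path, ["complex_id", "subunits", "modifications"]
        )
        for row in table.itertuples(index=False):
            subunits = _parse_pairs(row.subunits, cast=lambda v: int(float(v)))
            if row.complex_id.startswith("generic_"):
                gdata = GenericData(row.complex_id, members=sorted(subunits))
                self.model.register_process_data(gdata)
                for member in gdata.members:
                    self.model.add_reaction(
                        GenericFormationReaction(
                            f"{member}_to_{gdata.id}", gdata.id, member
                        )
                    )
                continue
            modifications = _parse_pairs(row.modifications, cast=float)
            for name in modifications:
                self._ensure_modification(name)
            cdata = ComplexData(
                row.complex_id,
                subunit_stoichiometry=subunits,
                modifications=modifications,
            )
            self.model.register_process_data(cdata)
            self.model.add_reaction(ComplexFormation(f"formation_{cdata.id}", cdata.id))
            self.complex_genes[cdata.id] = frozenset(
                _base_gene(subunit) for subunit in subunits
            )

    def add_transcription(self):
        table = _read_table(
            self.inputs.tu_table_path,
            ["tu_id", "left", "right", "strand", "genes", "rnap"],
        )
        covered = set()
        for row in table.itertuples(index=False):
            gene_list = [g for g in row.genes.split(",") if g]
            missing = [g for g in gene_list if g not in self.genes]
            if missing:
                raise MissingGeneError(
                    f"TU {row.tu_id} references genes absent from the "
                    f"annotation: {missing}"
                )
            left, right = int(row.left), int(row.right)
            sequence = self.genome[left - 1 : right]
            if row.strand == "-":
                sequence = reverse_complement(sequence)
            excision = {}
            excision_spec = getattr(row, "excision", "")
            if excision_spec:
                machine, _, count = excision_spec.partition(":")
                sub_id = f"excision_{machine}"
                if sub_id not in self.model.process_data:
                    self.model.register_process_data(
                        SubreactionData(sub_id, stoichiometry={}, enzymes=[machine])
                    )
                excision[sub_id] = float(count or 1)
            txd = TranscriptionData(
                f"{row.tu_id}_from_{row.rnap}",
                nucleotide_sequence=sequence,
                rna_products=["RNA_" + g for g in gene_list],
                rna_polymerase=row.rnap,
                excision_subreactions=excision,
            )
            txd.validate_products(self.model)
            self.model.register_process_data(txd)
            self.model.add_reaction(
                TranscriptionReaction(f"transcription_{txd.id}", txd.id)
            )
            covered.update(gene_list)
        for locus in self.genes:
            if locus in covered:
                continue
            info = self.genes[locus]
            txd = TranscriptionData(
                f"TU_auto_{locus}_from_{self.inputs.default_rnap}",
                nucleotide_sequence=info["sequence"],
                rna_products=["RNA_" + locus],
                rna_polymerase=self.inputs.default_rnap,
            )
            self.model.register_process_data(txd)
            self.model.add_reaction(
                TranscriptionReaction(f"transcription_{txd.id}", txd.id)
            )

    def add_translation(self):
        params = self.model.global_parameters
        for locus, info in sorted(self.genes.items()):
            if info["type"] != "CDS":
                continue
            aa_sequence = chemistry.translate_cds(
                info["sequence"], params.codon_table_id, params.start_codons
            )
            self.model.add_metabolite(
                TranslatedGene(
                    "protein_" + locus,
                    amino_acid_sequence=aa_sequence,
                    formula=chemistry.protein_composition(aa_sequence),
                )
            )
            subreactions = self._translation_subreactions(aa_sequence)
            td = TranslationData(
                locus,
                mrna_id="RNA_" + locus,
                nucleotide_sequence=info["sequence"],
                protein_id="protein_" + locus,
                subreactions=subreactions,
            )
            self.model.register_process_data(td)
            self.model.add_reaction(TranslationReaction("translation_" + locus, locus))

    def _translation_subreactions(self, aa_sequence):
        subreactions = {"translation_initiation": 1, "translation_termination": 1}
        for aa1 in aa_sequence:
            aa_id = chemistry.AA1_TO_ID[aa1]
            if aa_id not in self.trna_of_aa:
                raise DanglingReferenceError(
                    f"no tRNA gene assigned to amino acid {aa_id!r}"
                )
            key = f"addition_{aa_id}"
            subreactions[key] = subreactions.get(key, 0) + 1
        return subreactions

    def add_trna_charging(self):
        from .core import GenericComponent

        for aa_id, trna_gene in sorted(self.trna_of_aa.items()):
            info = self.genes[trna_gene]
            codon = info["codon"] or chemistry.codons_for(
                chemistry.ID_TO_AA1[aa_id], self.model.global_parameters.codon_table_id
            )[0]
            td = tRNAData(
                f"tRNA_{trna_gene}",
                codon=codon,
                amino_acid=aa_id,
                trna_id=trna_gene,
                synthetase=self.inputs.synthetase_id,
            )
            self.model.register_process_data(td)
            # charged-tRNA pool metabolite, so translation subreactions that
            # consume it can compile in any update order
            self.model.add_metabolite(
                GenericComponent(f"generic_tRNA_{aa_id}", compartment="c"),
                exist_ok=True,
            )
            self.model.add_reaction(
                tRNAChargingReaction(f"charging_{trna_gene}", td.id)
            )

    def add_translocation(self):
        table = _read_table(
            self.inputs.translocation_table_path,
            ["pathway_id", "keff", "enzymes", "stoichiometry", "targets"],
        )
        for row in table.itertuples(index=False):
            enzymes = {
                name: {"length_dependent": mode == "length_dependent"}
                for name, mode in _parse_pairs(row.enzymes, cast=str).items()
            }
            tl = TranslocationData(
                row.pathway_id,
                keff=float(row.keff),
                enzymes=enzymes,
                stoichiometry=_parse_pairs(row.stoichiometry, cast=float),
            )
            self.model.register_process_data(tl)
            for gene in filter(None, (g.strip() for g in row.targets.split(","))):
                if gene not in self.genes:
                    raise MissingGeneError(
                        f"translocation pathway {tl.id} targets unknown gene {gene!r}"
                    )
                processed_id = f"protein_{gene}_Membrane"
                # formula assigned eagerly so complex assembly can compile
                # in any update order (recomputed by the reaction update)
                protein = self.model.get_metabolite(f"protein_{gene}")
                self.model.add_metabolite(
                    ProcessedProtein(processed_id, f"protein_{gene}",
                                     formula=protein.formula, compartment="m"),
                    exist_ok=True,
                )
                pd_record = PostTranslationData(
                    f"translocation_protein_{gene}",
                    protein_id=f"protein_{gene}",
                    processed_protein_id=processed_id,
                    translocation_pathways=[tl.id],
                )
                self.model.register_process_data(pd_record)
                self.model.add_reaction(
                    PostTranslationReaction(f"post_translation_{gene}", pd_record.id)
                )

    def read_keffs(self):
        table = _read_table(
            self.inputs.keff_table_path, ["target_id", "target_type", "keff"]
        )
        for row in table.itertuples(index=False):
            value = float(row.keff)
            if row.target_type == "reaction":
                self.keff_by_reaction[row.target_id] = value
            elif row.target_type == "complex":
                self.keff_by_complex[row.target_id] = value
            else:
                raise DanglingReferenceError(
                    f"unknown keff target type {row.target_type!r}"
                )

    # -- metabolism -------------------------------------------------------
    def add_metabolic_reactions(self):
        for reaction in self.m_model.reactions:
            if reaction.boundary or reaction.id in self.m_objective_ids:
                continue
            sdata = StoichiometricData(
                reaction.id,
                stoichiometry={m.id: c for m, c in reaction.metabolites.items()},
                lower_bound=reaction.lower_bound,
                upper_bound=reaction.upper_bound,
            )
            self.model.register_process_data(sdata)
            spontaneous = bool(reaction.notes.get("spontaneous"))
            complexes = self._catalysts_for(reaction, spontaneous)
            self.stoich_complexes[sdata.id] = complexes
            directions = []
            if reaction.upper_bound > 0:
                directions.append("forward")
            if reaction.lower_bound < 0:
                directions.append("reverse")
            for complex_id in complexes or [None]:
                for direction in directions:
                    suffix = "FWD" if direction == "forward" else "REV"
                    tag = complex_id if complex_id else "SPONT"
                    keff = self.keff_by_reaction.get(
                        reaction.id, self.keff_by_complex.get(complex_id)
                    )
                    self.model.add_reaction(
                        MetabolicReaction(
                            f"{sdata.id}_{suffix}_{tag}",
                            sdata.id,
                            complex_id=complex_id,
                            direction=direction,
                            keff=keff,
                        )
                    )

    def _catalysts_for(self, reaction, spontaneous):
        """Map a GPR rule to catalyzing complexes via the enzyme table.

        AND-conjunctions are matched against enzyme-table subunit gene sets
        (the table wins on conflict and conflicts are reported); unmatched
        conjunctions get an auto-generated complex. Orphans (no rule,
        non-spontaneous) are assigned the dummy complex later.
        """
        conjunctions = gpr_conjunctions(reaction.gene_reaction_rule)
        if not conjunctions:
            return [] if spontaneous else [DUMMY_COMPLEX_ID]
        complexes = []
        for genes in conjunctions:
            matches = sorted(
                cid for cid, members in self.complex_genes.items() if members == genes
            )
            if len(matches) > 1:
                logger.warning(
                    "reaction %s: gene set %s matches multiple complexes %s; "
                    "using %s",
                    reaction.id, sorted(genes), matches, matches[0],
                )
            if matches:
                complexes.append(matches[0])
                continue
            auto_id = f"CPLX_AUTO_{reaction.id}_{len(complexes)}"
            cdata = ComplexData(
                auto_id,
                subunit_stoichiometry={f"protein_{g}": 1 for g in sorted(genes)},
            )
            self.model.register_process_data(cdata)
            self.model.add_reaction(ComplexFormation(f"formation_{auto_id}", auto_id))
            self.complex_genes[auto_id] = genes
            complexes.append(auto_id)
        return complexes

    # -- dummy complex and biomass ---------------------------------------
    def add_dummy(self):
        add_dummy_complex(
            self.model,
            self.inputs.dummy_composition,
            length=self.inputs.dummy_length,
            rnap=self.inputs.default_rnap,
            trna_of_aa=self.trna_of_aa,
        )

    def add_biomass(self):
        """Growth demand and biomass bookkeeping.

        ``biomass_dilution`` (both bounds = mu) consumes the biomass pool,
        which is filled only by *forced* mu-scaled demands: the dummy
        (unmodeled) protein demand plus fixed DNA and lipid demands. The
        per-gram machinery tallies (protein_biomass, rna_biomass, ...) are
        reporting pools with free sinks; keeping machinery mass out of the
        growth requirement makes every k_eff a pure burden, so tightening
        any coupling can only lower the optimal growth rate.
        """
        model = self.model
        pseudo = []
        for name in ("biomass", "protein_biomass", "rna_biomass",
                     "dna_biomass", "lipid_biomass"):
            model.add_metabolite(SmallMolecule(name), exist_ok=True)
            pseudo.append(name)
        model.global_info["pseudo_metabolites"] = pseudo
        model.global_info["protein_biomass_id"] = "protein_biomass"
        model.global_info["rna_biomass_id"] = "rna_biomass"
        mu = GrowthExpression(0.0, 1.0)
        model.add_reaction(
            SummaryVariable("biomass_dilution", {"biomass": -1.0},
                            lower_bound=mu, upper_bound=mu)
        )
        for constituent in ("protein_biomass", "rna_biomass",
                            "dna_biomass", "lipid_biomass"):
            model.add_reaction(
                SummaryVariable(f"{constituent}_sink", {constituent: -1.0})
            )
        params = model.global_parameters
        dntps = ["datp_c", "dgtp_c", "dctp_c", "dttp_c"]
        if all(m in model.metabolites for m in dntps):
            # equal-parts composition normalized to 1 g DNA per unit flux
            residue_mass = sum(
                chemistry.formula_mass(model.get_metabolite(m).formula)
                - chemistry.formula_mass(chemistry.PPI_FORMULA)
                for m in dntps
            ) / 4.0
            scale = 1000.0 / residue_mass
            stoich = {m: -0.25 * scale for m in dntps}
            stoich["ppi_c"] = scale
            stoich["dna_biomass"] = 1.0
            stoich["biomass"] = 1.0
            demand = GrowthExpression(0.0, params.dna_biomass_fraction)
            model.add_reaction(
                SummaryVariable("DNA_demand", stoich,
                                lower_bound=demand, upper_bound=demand)
            )
        lipid = self.inputs.lipid_metabolite
        if lipid and lipid in model.metabolites:
            mass = chemistry.formula_mass(model.get_metabolite(lipid).formula)
            demand = GrowthExpression(0.0, params.lipid_biomass_fraction)
            model.add_reaction(
                SummaryVariable("lipid_demand",
                                {lipid: -1000.0 / mass, "lipid_biomass": 1.0,
                                 "biomass": 1.0},
                                lower_bound=demand, upper_bound=demand)
            )

    def add_rna_turnover(self):
        """Degradation valves returning each RNA species to the NMP pool.

        Without them, RNAs co-produced on one transcription unit (an rRNA
        and tRNAs on a stable-RNA operon) would be forced into identical
        net demand -- overdetermining the balances and blocking all
        expression. Turnover debits the RNA biomass credit taken at
        transcription, so degraded RNA never counts toward biomass.
        """
        rna_constituent = self.model.global_info.get("rna_biomass_id")
        for metabolite in list(self.model.metabolites.values()):
            if metabolite.kind != "transcribed_gene":
                continue
            sequence = metabolite.nucleotide_sequence
            stoich = {metabolite.id: -1.0, "h2o_c": -float(len(sequence))}
            for base, n in sorted(chemistry.base_counts(sequence).items()):
                nmp_id = chemistry.DNA_BASE_TO_NMP[base] + "_c"
                stoich[nmp_id] = stoich.get(nmp_id, 0.0) + n
            if rna_constituent:
                stoich[rna_constituent] = (
                    -chemistry.formula_mass(metabolite.formula) / 1000.0
                )
            self.model.add_reaction(
                PlainReaction(f"turnover_{metabolite.id}", stoich)
            )

    # -- orchestration ----------------------------------------------------
    def build(self, validate_balance=True):
        self.read_genome()
        self.read_m_model()
        self.add_exchanges()
        self.add_translation_subreactions()
        self.add_complexes()
        self.add_transcription()
        self.add_translation()
        self.add_trna_charging()
        self.add_translocation()
        self.read_keffs()
        self.add_biomass()
        self.add_dummy()
        self.add_rna_turnover()
        self.add_metabolic_reactions()
        model = self.model
        model.global_info["ribosome_id"] = self.inputs.ribosome_id
        model.update_all()
        if validate_balance:
            failures = balance.check_model_balance(model, mu=0.0)
            if failures:
                raise UnbalancedReactionError(
                    f"{len(failures)} reactions fail elemental balance; "
                    f"first: {next(iter(failures.items()))}",
                    residuals=failures,
                )
        return model


def build_me_model(inputs, parameters=None, validate_balance=True):
    """Run the full reconstruction workflow and return a compiled model."""
    return _Builder(inputs, parameters).build(validate_balance=validate_balance)


def add_dummy_complex(model, composition, length=100, rnap="RNAP_sigA",
                      trna_of_aa=None):
    """Create the representative dummy protein and its expression chain.

    A synthetic gene is written from the amino-acid composition (codons
    cycled round-robin), transcribed, translated and assembled into a
    monomer complex that catalyzes orphan reactions; an unbounded demand on
    the complex serves as the optimization objective. Returns the ids of
    the created reactions.
    """
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9 or not composition:
        raise CompositionError(f"composition fractions sum to {total}, expected 1")
    unknown = set(composition) - set(chemistry.ID_TO_AA1)
    if unknown:
        raise CompositionError(f"unknown amino acids: {sorted(unknown)}")
    if length < 1:
        raise CompositionError("dummy protein length must be >= 1")

    # integer residue counts matching the fractions, Met guaranteed for
    # the initiator position
    counts = {aa: int(round(fraction * length)) for aa, fraction in
              sorted(composition.items())}
    drift = length - sum(counts.values())
    ordered = sorted(counts)
    index = 0
    while drift != 0:
        aa = ordered[index % len(ordered)]
        if drift > 0:
            counts[aa] += 1
            drift -= 1
        elif counts[aa] > 0:
            counts[aa] -= 1
            drift += 1
        index += 1
    if counts.get("met__L", 0) == 0:
        donor = max(counts, key=counts.get)
        counts[donor] -= 1
        counts["met__L"] = 1

    residues = []
    for aa_id in sorted(counts):
        residues.extend(chemistry.ID_TO_AA1[aa_id] * counts[aa_id])
    residues.remove("M")
    aa_sequence = "M" + "".join(residues)
    cds = chemistry.back_translate(
        aa_sequence, model.global_parameters.codon_table_id
    )

    rna = TranscribedGene(
        "RNA_" + DUMMY_GENE_ID,
        rna_type="mRNA",
        nucleotide_sequence=cds,
        formula=chemistry.rna_composition(cds),
    )
    model.add_metabolite(rna)
    model.add_metabolite(
        TranslatedGene(
            "protein_" + DUMMY_GENE_ID,
            amino_acid_sequence=aa_sequence,
            formula=chemistry.protein_composition(aa_sequence),
        )
    )
    txd = TranscriptionData(
        f"TU_{DUMMY_GENE_ID}_from_{rnap}",
        nucleotide_sequence=cds,
        rna_products=[rna.id],
        rna_polymerase=rnap,
    )
    model.register_process_data(txd)
    subreactions = {"translation_initiation": 1, "translation_termination": 1}
    trna_of_aa = trna_of_aa or {}
    for aa1 in aa_sequence:
        aa_id = chemistry.AA1_TO_ID[aa1]
        key = f"addition_{aa_id}"
        if key not in model.process_data:
            raise DanglingReferenceError(
                f"no elongation subreaction for amino acid {aa_id!r}; "
                "is a tRNA gene missing?"
            )
        subreactions[key] = subreactions.get(key, 0) + 1
    td = TranslationData(
        DUMMY_GENE_ID,
        mrna_id=rna.id,
        nucleotide_sequence=cds,
        protein_id="protein_" + DUMMY_GENE_ID,
        subreactions=subreactions,
    )
    model.register_process_data(td)
    cdata = ComplexData(
        DUMMY_COMPLEX_ID, subunit_stoichiometry={"protein_" + DUMMY_GENE_ID: 1}
    )
    model.register_process_data(cdata)

    # the demand drains dummy complex into the biomass pool: expressing
    # the representative unmodeled protein is a hard growth requirement
    demand_stoich = {DUMMY_COMPLEX_ID: -1.0}
    if "biomass" in model.metabolites:
        dummy_mass = chemistry.formula_mass(
            model.get_metabolite("protein_" + DUMMY_GENE_ID).formula
        )
        demand_stoich["biomass"] = dummy_mass / 1000.0
    created = []
    for reaction in (
        TranscriptionReaction(f"transcription_{txd.id}", txd.id),
        TranslationReaction(f"translation_{DUMMY_GENE_ID}", td.id),
        ComplexFormation(f"formation_{DUMMY_COMPLEX_ID}", cdata.id),
        SummaryVariable(DUMMY_DEMAND_ID, demand_stoich, lower_bound=ZERO),
    ):
        model.add_reaction(reaction)
        created.append(reaction.id)
    model.objective_id = DUMMY_DEMAND_ID
    return created


def _base_gene(subunit_id):
    """protein_g01_Membrane -> g01; RNA_rrna_1 -> rrna_1."""
    name = subunit_id
    for prefix in ("protein_", "RNA_"):
        if name.startswith(prefix):
            name = name[len(prefix):]
            break
    if name.endswith("_Membrane"):
        name = name[: -len("_Membrane")]
    return name
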