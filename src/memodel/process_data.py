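"""Information-vessel record types ("ProcessData").

Each record compartmentalizes the data describing one cellular process --
the stoichiometry of a metabolic reaction, the subunit composition of an
enzyme complex, the sequence and machinery of a transcription unit, and so
on. Reactions never carry primary data themselves: they read these records
at compile time, which makes every compiled stoichiometry a pure function
of the registry plus the global parameters.

The nine record types:

=================== ======================================================
StoichiometricData  metabolite stoichiometry and bounds of a metabolic
                    reaction
ComplexData         protein-subunit stoichiometry of an enzyme complex and
                    the modifications required for activity
SubreactionData     stoichiometry + catalyzing enzymes of a lumped
                    process step (amino-acid addition, cofactor loading)
TranscriptionData   sequence, RNA products and polymerase of one
                    transcription unit
TranslationData     CDS, mRNA/protein ids and per-residue subreactions of
                    one translated gene
tRNAData            codon, amino acid, tRNA gene and synthetase of one
                    charging route
TranslocationData   k_eff, enzymes and per-residue costs of a membrane
                    translocation pathway
PostTranslationData pathways and modifications turning a raw protein into
                    its functional processed form
GenericData         interchangeable components pooled behind one generic id
=================== ======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import chemistry
from .exceptions import EmptySequenceError


@dataclass
class ProcessData:
    id: str


@dataclass
class StoichiometricData(ProcessData):
    """Metabolite stoichiometry of a metabolic reaction (M-model level)."""

    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0

    def __post_init__(self):
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ValueError(f"{self.id}: stoichiometry has no nonzero coefficient")
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.id}: lower bound exceeds upper bound")


@dataclass
class ComplexData(ProcessData):
    """Subunit stoichiometry and required modifications of a complex."""

    subunit_stoichiometry: dict = field(default_factory=dict)
    modifications: dict = field(default_factory=dict)

    def __post_init__(self):
        for subunit, count in self.subunit_stoichiometry.items():
            if not (float(count).is_integer() and count >= 1):
                raise ValueError(
                    f"{self.id}: subunit count for {subunit} must be a positive "
                    f"integer, got {count}"
                )

    @property
    def complex_id(self):
        return self.id


@dataclass
class SubreactionData(ProcessData):
    """Stoichiometry and catalyzing enzyme(s) of a lumped process step."""

    stoichiometry: dict = field(default_factory=dict)
    enzymes: list = field(default_factory=list)
    keff: float | None = None  # s^-1; None -> model default


@dataclass
class TranscriptionData(ProcessData):
    """One transcription unit under one RNA polymerase (sigma variant)."""

    nucleotide_sequence: str = ""
    rna_products: list = field(default_factory=list)
    rna_polymerase: str = ""
    excision_subreactions: dict = field(default_factory=dict)

    def validate_products(self, model):
        """Every product sequence must be a substring of the TU (either strand)."""
        rc = chemistry.reverse_complement(self.nucleotide_sequence)
        for product_id in self.rna_products:
            product = model.get_metabolite(product_id)
            seq = product.nucleotide_sequence
            if seq not in self.nucleotide_sequence and seq not in rc:
                raise ValueError(
                    f"{self.id}: product {product_id} sequence is not contained "
                    "in the transcription unit"
                )


@dataclass
class TranslationData(ProcessData):
    """CDS and lumped per-residue machinery usage for one gene."""

    mrna_id: str = ""
    nucleotide_sequence: str = ""  # CDS on the coding strand, incl. stop
    protein_id: str = ""
    subreactions: dict = field(default_factory=dict)

    def validate(self, table_id=11, start_codons=("ATG", "GTG", "TTG")):
        chemistry.translate_cds(self.nucleotide_sequence, table_id, start_codons)

    def amino_acid_sequence(self, table_id=11, start_codons=("ATG", "GTG", "TTG")):
        return chemistry.translate_cds(self.nucleotide_sequence, table_id, start_codons)


@dataclass
class tRNAData(ProcessData):  # noqa: N801 - field-conventional capitalization
    """Codon/amino-acid assignment and machinery for one tRNA charging route."""

    codon: str = ""
    amino_acid: str = ""
    trna_id: str = ""
    modifications: dict = field(default_factory=dict)
    synthetase: str | None = None

    def __post_init__(self):
        if len(self.codon) != 3:
            raise ValueError(f"{self.id}: codon must have length 3, got {self.codon!r}")


@dataclass
class TranslocationData(ProcessData):
    """A protein translocation pathway (e.g. Sec-like export)."""

    keff: float = 65.0  # s^-1
    #: enzyme id -> {"length_dependent": bool}
    enzymes: dict = field(default_factory=dict)
    #: per-residue metabolite costs, signed
    stoichiometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.keff <= 0:
            raise ValueError(f"{self.id}: keff must be positive, got {self.keff}")


@dataclass
class PostTranslationData(ProcessData):
    """Maturation of a translated protein into its processed form."""

    protein_id: str = ""
    processed_protein_id: str = ""
    translocation_pathways: list = field(default_factory=list)
    modifications: dict = field(default_factory=dict)


@dataclass
class GenericData(ProcessData):
    """Interchangeable components represented by one generic id."""

    members: list = field(default_factory=list)

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"{self.id}: generic component needs at least one member")

    @property
    def generic_id(self):
        return self.id


PROCESS_DATA_TYPES = (
    StoichiometricData,
    ComplexData,
    SubreactionData,
    TranscriptionData,
    TranslationData,
    tRNAData,
    TranslocationData,
    PostTranslationData,
    GenericData,
)


def amino_acid_counts(translation_data, table_id=11, start_codons=("ATG", "GTG", "TTG")):
    """Per-amino-acid counts of a CDS; the stop codon contributes nothing.

    Counts sum to ``len(CDS)/3 - 1`` and are keyed by one-letter code.
    """
    sequence = translation_data.amino_acid_sequence(table_id, start_codons)
    counts = {}
    for aa in sequence:
        counts[aa] = counts.get(aa, 0) + 1
    return counts


def nucleotide_counts(transcription_data):
    """NTP counts (atp/utp/gtp/ctp ids) to transcribe the full TU sequence."""
    if not transcription_data.nucleotide_sequence:
        raise EmptySequenceError(f"{transcription_data.id}: empty TU sequence")
    return chemistry.nucleotide_counts(transcription_data.nucleotide_sequence)
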