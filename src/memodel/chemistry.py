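"""Elemental and sequence bookkeeping shared across the package.

Formulas are stored as ``{element: count}`` dicts with float counts (coupling
arithmetic produces fractional compositions). Conventions used throughout:

* neutral (uncharged) molecular formulas for all small molecules;
* an RNA chain of N residues has formula ``sum(NMP) - N * H2O``, so that
  polymerization balances exactly as ``N NTP -> RNA + N PPi``;
* a protein of L residues has formula ``sum(AA) - (L - 1) * H2O``.

Codon translation goes through Biopython's codon tables; only the bacterial
initiator convention (GTG/TTG read as Met in first position) is layered on
top.
"""

from __future__ import annotations

import re

from Bio.Data import CodonTable

from .exceptions import AlphabetError, EmptySequenceError, InvalidCodonError

SECONDS_PER_HOUR = 3600.0

ATOMIC_MASS = {
    "C": 12.011,
    "H": 1.008,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Mg": 24.305,
    "Fe": 55.845,
    "Zn": 65.38,
}

#: Free (neutral) amino-acid formulas, one-letter code.
AA_FORMULA = {
    "A": "C3H7NO2",
    "R": "C6H14N4O2",
    "N": "C4H8N2O3",
    "D": "C4H7NO4",
    "C": "C3H7NO2S",
    "E": "C5H9NO4",
    "Q": "C5H10N2O3",
    "G": "C2H5NO2",
    "H": "C6H9N3O2",
    "I": "C6H13NO2",
    "L": "C6H13NO2",
    "K": "C6H14N2O2",
    "M": "C5H11NO2S",
    "F": "C9H11NO2",
    "P": "C5H9NO2",
    "S": "C3H7NO3",
    "T": "C4H9NO3",
    "W": "C11H12N2O2",
    "Y": "C9H11NO3",
    "V": "C5H11NO2",
}

#: BiGG-style metabolite ids for the amino acids (no compartment suffix).
AA1_TO_ID = {
    "A": "ala__L",
    "R": "arg__L",
    "N": "asn__L",
    "D": "asp__L",
    "C": "cys__L",
    "E": "glu__L",
    "Q": "gln__L",
    "G": "gly",
    "H": "his__L",
    "I": "ile__L",
    "L": "leu__L",
    "K": "lys__L",
    "M": "met__L",
    "F": "phe__L",
    "P": "pro__L",
    "S": "ser__L",
    "T": "thr__L",
    "W": "trp__L",
    "Y": "tyr__L",
    "V": "val__L",
}
ID_TO_AA1 = {v: k for k, v in AA1_TO_ID.items()}

# Transcription reads the DNA coding strand: T templates a U in the product.
DNA_BASE_TO_NTP = {"A": "atp", "T": "utp", "G": "gtp", "C": "ctp"}
DNA_BASE_TO_NMP = {"A": "amp", "T": "ump", "G": "gmp", "C": "cmp"}

NTP_FORMULA = {
    "atp": "C10H16N5O13P3",
    "gtp": "C10H16N5O14P3",
    "ctp": "C9H16N3O14P3",
    "utp": "C9H15N2O15P3",
}
NMP_FORMULA = {
    "amp": "C10H14N5O7P",
    "gmp": "C10H14N5O8P",
    "cmp": "C9H14N3O8P",
    "ump": "C9H13N2O9P",
}
NDP_FORMULA = {"adp": "C10H15N5O10P2", "gdp": "C10H15N5O11P2"}
DNTP_FORMULA = {
    "datp": "C10H16N5O12P3",
    "dgtp": "C10H16N5O13P3",
    "dctp": "C9H16N3O13P3",
    "dttp": "C10H17N2O14P3",
}
WATER = {"H": 2.0, "O": 1.0}
PPI_FORMULA = "H4O7P2"
PI_FORMULA = "H3O4P"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")

DNA_ALPHABET = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def parse_formula(formula):
    """Parse ``'C6H12O6'`` into ``{'C': 6.0, 'H': 12.0, 'O': 6.0}``."""
    if isinstance(formula, dict):
        return dict(formula)
    out = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.groups()
        out[element] = out.get(element, 0.0) + (float(count) if count else 1.0)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def format_formula(composition):
    """Render a composition dict as a Hill-ordered formula string."""
    elements = sorted(composition, key=lambda e: (e not in ("C", "H"), e != "C", e))
    parts = []
    for element in elements:
        count = composition[element]
        if abs(count) < 1e-9:
            continue
        if abs(count - round(count)) < 1e-9:
            count = int(round(count))
        parts.append(f"{element}{'' if count == 1 else count}")
    return "".join(parts)


def combine(*terms):
    """Sum weighted compositions; ``terms`` are (coefficient, formula) pairs."""
    total = {}
    for coefficient, formula in terms:
        for element, count in parse_formula(formula).items():
            total[element] = total.get(element, 0.0) + coefficient * count
    return {e: c for e, c in total.items() if abs(c) > 1e-12}


def formula_mass(formula):
    """Molecular mass in g/mol of a formula string or composition dict."""
    return sum(ATOMIC_MASS[e] * c for e, c in parse_formula(formula).items())


def validate_dna(sequence):
    if set(sequence) - DNA_ALPHABET:
        bad = sorted(set(sequence) - DNA_ALPHABET)
        raise AlphabetError(f"non-DNA characters in sequence: {bad}")


def reverse_complement(sequence):
    """Reverse complement of a DNA coding-strand string (involution)."""
    validate_dna(sequence)
    return sequence.translate(_COMPLEMENT)[::-1]


def rna_composition(dna_sequence):
    """Elemental composition of the RNA transcribed from a DNA coding strand."""
    counts = base_counts(dna_sequence)
    terms = [(counts[b], NMP_FORMULA[DNA_BASE_TO_NMP[b]]) for b in counts]
    terms.append((-float(len(dna_sequence)), WATER))
    return combine(*terms)


def protein_composition(aa_sequence):
    """Elemental composition of a peptide chain (free N/C termini)."""
    terms = [(1.0, AA_FORMULA[a]) for a in aa_sequence]
    terms.append((-(len(aa_sequence) - 1.0), WATER))
    return combine(*terms)


def base_counts(dna_sequence):
    validate_dna(dna_sequence)
    return {b: float(dna_sequence.count(b)) for b in "ATGC" if dna_sequence.count(b)}


def nucleotide_counts(dna_sequence):
    """NTP counts (atp/utp/gtp/ctp) needed to transcribe a coding strand."""
    if not dna_sequence:
        raise EmptySequenceError("cannot count nucleotides of an empty sequence")
    return {DNA_BASE_TO_NTP[b]: n for b, n in base_counts(dna_sequence).items()}


def codon_table(table_id):
    return CodonTable.unambiguous_dna_by_id[table_id]


def translate_cds(sequence, table_id=11, start_codons=("ATG", "GTG", "TTG")):
    """Translate a CDS (including stop codon) to a one-letter aa string.

    The first codon is read as Met when it belongs to ``start_codons``,
    the bacterial initiator convention. Raises :class:`InvalidCodonError`
    for ambiguous or unknown codons and :class:`ValueError` for structural
    problems (length, missing stop).
    """
    if len(sequence) % 3 != 0:
        raise ValueError(f"CDS length {len(sequence)} not divisible by 3")
    table = codon_table(table_id)
    codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
    if codons[-1] not in table.stop_codons:
        raise ValueError(f"CDS does not end with a stop codon: {codons[-1]}")
    if codons[0] not in start_codons:
        raise ValueError(f"CDS does not start with a start codon: {codons[0]}")
    protein = ["M"]
    for codon in codons[1:-1]:
        try:
            protein.append(table.forward_table[codon])
        except KeyError:
            if codon in table.stop_codons:
                raise ValueError(f"internal stop codon {codon}") from None
            raise InvalidCodonError(f"unknown or ambiguous codon {codon!r}") from None
    return "".join(protein)


def codons_for(amino_acid_1, table_id=11):
    """Sorted list of codons encoding a one-letter amino acid."""
    table = codon_table(table_id)
    return sorted(c for c, a in table.forward_table.items() if a == amino_acid_1)


def back_translate(aa_sequence, table_id=11, stop_codon="TAA", start_codon="ATG"):
    """Synthesize a CDS for an amino-acid sequence, cycling synonymous codons.

    The first residue is encoded by ``start_codon`` regardless of identity
    (it is read back as Met), matching how synthetic genes are emitted by the
    toy-organism generator.
    """
    counters = {}
    codons = [start_codon]
    for aa in aa_sequence[1:]:
        options = codons_for(aa, table_id)
        index = counters.get(aa, 0)
        codons.append(options[index % len(options)])
        counters[aa] = index + 1
    codons.append(stop_codon)
    return "".join(codons)
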