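"""Synthetic toy-organism bundles for fully self-contained testing.

The generator emits everything a build needs -- a GenBank genome, a
COBRA-schema M-model JSON and the four expression TSV tables -- for a small
imaginary bacterium, deterministically from a seed. The organism is small
but complete: glucose is the sole carbon source, lumped promiscuous enzymes
synthesize amino acids and nucleotides, and the expression machinery
(ribosome, RNA polymerase holoenzymes, tRNAs, elongation-factor pool) is
encoded by dedicated genes so that knockouts propagate through the
expression chain.

Gene roles at "full" difficulty (requires >= 10 coding genes):

====  =====================================================================
g01   glucose transporter; membrane protein translocated via a Sec-like
      pathway, functional form ``protein_g01_Membrane`` (2x in CPLX_GLC)
g02   amino-acid synthase subunit A (2x in CPLX_AA, Mg-modified); GTG start
g03   amino-acid synthase subunit B (1x in CPLX_AA)
g04   nucleotide synthase / degradosome (CPLX_NUC); its TU is transcribed
      by both sigma variants
g05   elongation-factor paralog A (pooled as generic_EFTu)
g06   elongation-factor paralog B -- a residue permutation of g05, so both
      paralogs share one elemental composition
g07   ribosomal protein (4x in the ribosome with the rRNA); also the
      Sec translocase (CPLX_SEC)
g08   RNA-polymerase core (2x in both holoenzymes)
g09   sigma factor A (RNAP_sigA)
g10   sigma factor B (RNAP_sigB)
g11+  fillers: translated but part of no complex
====  =====================================================================

"minimal" difficulty (>= 3 genes) collapses the roles: g01 transports,
g02 catalyzes all synthesis, g03 supplies ribosome and RNAP proteins; no
modifications, generics, translocation, excision or second sigma factor,
and most transcription units are left to the builder's auto-TU fallback.

Lipid synthesis at full difficulty deliberately has no annotated catalyst
and is non-spontaneous -- the canonical orphan reaction that the dummy
complex must catalyze.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass
from pathlib import Path

import cobra
import cobra.io
import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from . import chemistry
from .builder import BuildInputs, build_me_model
from .exceptions import InfeasibleAtMinError, ParameterError, SolverBackendError
from .solver import feasible_at


def _grid_feasible(model, mu):
    """Feasibility probe that treats backend failure as infeasible,
    matching the bisection search's conservative policy."""
    try:
        return feasible_at(model, mu).feasible
    except SolverBackendError:
        return False

AA_IDS = sorted(chemistry.AA1_TO_ID.values())

SMALL_MOLECULES = {
    "glc__D": "C6H12O6",
    "nh3": "H3N",
    "h2s": "H2S",
    "pi": chemistry.PI_FORMULA,
    "h2o": "H2O",
    "h2": "H2",
    "mg2": "Mg",
    "ppi": chemistry.PPI_FORMULA,
    "atp": chemistry.NTP_FORMULA["atp"],
    "gtp": chemistry.NTP_FORMULA["gtp"],
    "ctp": chemistry.NTP_FORMULA["ctp"],
    "utp": chemistry.NTP_FORMULA["utp"],
    "adp": chemistry.NDP_FORMULA["adp"],
    "gdp": chemistry.NDP_FORMULA["gdp"],
    "amp": chemistry.NMP_FORMULA["amp"],
    "gmp": chemistry.NMP_FORMULA["gmp"],
    "cmp": chemistry.NMP_FORMULA["cmp"],
    "ump": chemistry.NMP_FORMULA["ump"],
    "datp": chemistry.DNTP_FORMULA["datp"],
    "dgtp": chemistry.DNTP_FORMULA["dgtp"],
    "dctp": chemistry.DNTP_FORMULA["dctp"],
    "dttp": chemistry.DNTP_FORMULA["dttp"],
    "lipid_toy": "C30H58O4",
}


@dataclass
class ToyOrganismBundle:
    """Paths of one generated bundle plus the parameter sidecar."""

    directory: Path
    genbank_path: Path
    m_model_path: Path
    tu_table_path: Path
    enzyme_table_path: Path
    keff_table_path: Path
    translocation_table_path: Path
    sidecar_path: Path
    params: dict

    def build_inputs(self):
        p = self.params
        return BuildInputs(
            m_model_path=str(self.m_model_path),
            genbank_path=str(self.genbank_path),
            tu_table_path=str(self.tu_table_path),
            enzyme_table_path=str(self.enzyme_table_path),
            keff_table_path=str(self.keff_table_path),
            translocation_table_path=str(self.translocation_table_path),
            default_rnap=p["default_rnap"],
            ribosome_id=p["ribosome_id"],
            synthetase_id=p["synthetase_id"],
            degradosome_id=p["degradosome_id"],
            elongation_enzyme=p["elongation_enzyme"],
        )


def balance_from_currencies(formula):
    """Exact-balance currency stoichiometry synthesizing one target molecule.

    Carbon comes from glucose, nitrogen from ammonia, sulfur from sulfide,
    phosphorus from phosphate; water and molecular hydrogen absorb the
    oxygen and hydrogen residuals (either sign). Returns consumed
    coefficients as negatives, ready to merge with ``{target: +1}``.
    """
    target = chemistry.parse_formula(formula)
    get = target.get
    glc = get("C", 0.0) / 6.0
    nh3 = get("N", 0.0)
    h2s = get("S", 0.0)
    pi = get("P", 0.0)
    h2o = get("O", 0.0) - 6.0 * glc - 4.0 * pi
    h2 = (get("H", 0.0) - 12.0 * glc - 3.0 * nh3 - 2.0 * h2s - 3.0 * pi
          - 2.0 * h2o) / 2.0
    stoich = {"glc__D_c": -glc, "nh3_c": -nh3, "h2s_c": -h2s, "pi_c": -pi,
              "h2o_c": -h2o, "h2_c": -h2}
    return {k: v for k, v in stoich.items() if abs(v) > 1e-12}


def _random_protein(rng, length):
    letters = sorted(chemistry.AA1_TO_ID)
    body = rng.choice(letters, size=length - 1)
    return "M" + "".join(body)


def _random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class _GenomeLayout:
    """Accumulates TU segments into a linear genome with coordinates."""

    def __init__(self, rng):
        self.rng = rng
        self.segments = [_random_dna(rng, 10)]
        self.position = 10  # 1-based coordinate of last placed base
        self.features = []  # (locus, type, left, right, strand, extras)
        self.tu_rows = []

    def place_tu(self, tu_id, parts, strand, rnap_list, excision=""):
        """``parts``: list of (locus|None, sequence, feature_type); None
        locus entries are untranscribed spacers within the TU."""
        segment = "".join(seq for _, seq, _ in parts)
        seg_len = len(segment)
        left = self.position + 1
        right = left + seg_len - 1
        genome_piece = segment if strand == "+" else chemistry.reverse_complement(segment)
        self.segments.append(genome_piece)
        self.position = right
        offset = 0
        genes = []
        for locus, seq, ftype in parts:
            if locus is not None:
                if strand == "+":
                    g_left = left + offset
                    g_right = left + offset + len(seq) - 1
                else:
                    g_left = left + (seg_len - offset - len(seq))
                    g_right = left + (seg_len - offset) - 1
                self.features.append((locus, ftype, g_left, g_right, strand))
                genes.append(locus)
            offset += len(seq)
        for rnap in rnap_list:
            self.tu_rows.append(
                (tu_id, left, right, strand, ",".join(genes), rnap, excision)
            )
        self.segments.append(_random_dna(self.rng, 20))
        self.position += 20

    def genome(self):
        return "".join(self.segments)


def generate_toy_organism(directory, n_genes=10, seed=1, difficulty="full"):
    """Write a complete toy-organism bundle into ``directory``.

    Deterministic in ``seed`` (byte-identical files). ``difficulty``
    "minimal" uses single-gene TUs and no modifications; "full" exercises
    every ProcessData type at least once.
    """
    if n_genes < 3:
        raise ParameterError("n_genes must be at least 3")
    if difficulty not in {"minimal", "full"}:
        raise ParameterError(f"unknown difficulty {difficulty!r}")
    if difficulty == "full" and n_genes < 10:
        raise ParameterError("full difficulty requires at least 10 coding genes")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    full = difficulty == "full"

    gene_ids = [f"g{i + 1:02d}" for i in range(n_genes)]
    lengths = {g: int(rng.integers(30, 61)) for g in gene_ids}
    proteins = {g: _random_protein(rng, lengths[g]) for g in gene_ids}
    if full:
        # paralogous elongation factors share one amino-acid composition
        body = list(proteins["g05"][1:])
        proteins["g06"] = "M" + "".join(rng.permutation(body))
        lengths["g06"] = lengths["g05"]
    cds = {
        g: chemistry.back_translate(
            proteins[g], start_codon="GTG" if g == "g02" else "ATG"
        )
        for g in gene_ids
    }
    trna_genes = {aa: f"trna_{aa}" for aa in AA_IDS}
    trna_seqs = {aa: _random_dna(rng, 76) for aa in AA_IDS}
    rrna_seq = _random_dna(rng, 120)

    layout = _GenomeLayout(rng)
    sigma_a = "RNAP_sigA" if full else "RNAP"
    for i, g in enumerate(gene_ids):
        strand = "+" if i % 2 == 0 else "-"
        rnaps = [sigma_a, "RNAP_sigB"] if (full and g == "g04") else [sigma_a]
        layout.place_tu(f"TU_{g}", [(g, cds[g], "CDS")], strand, rnaps)
    stable_aas = AA_IDS[:2] if full else []
    if full:
        parts = [(None, _random_dna(rng, 4), "spacer"),
                 ("rrna_1", rrna_seq, "rRNA")]
        for aa in stable_aas:
            parts.append((None, _random_dna(rng, 7), "spacer"))
            parts.append((trna_genes[aa], trna_seqs[aa], "tRNA"))
        parts.append((None, _random_dna(rng, 4), "spacer"))
        layout.place_tu("TU_stable", parts, "+", [sigma_a],
                        excision="CPLX_NUC:3")
    else:
        layout.place_tu("TU_rrna", [("rrna_1", rrna_seq, "rRNA")], "+", [sigma_a])
    for aa in AA_IDS:
        if aa in stable_aas:
            continue
        layout.place_tu(f"TU_{trna_genes[aa]}",
                        [(trna_genes[aa], trna_seqs[aa], "tRNA")], "+", [sigma_a])

    _write_genbank(directory / "genome.gb", layout, trna_genes)
    uptake = round(float(rng.uniform(6.0, 12.0)), 2)
    reaction_ids = _write_m_model(directory / "m_model.json", uptake, full)
    keffs = {r: round(float(rng.uniform(20.0, 150.0)), 3) for r in reaction_ids}
    _write_tsv(
        directory / "tu_table.tsv",
        ["tu_id", "left", "right", "strand", "genes", "rnap", "excision"],
        # auto-TU fallback coverage: at minimal difficulty only the first
        # coding TU is declared, the rest comes from the builder default
        [r for r in layout.tu_rows if full or r[0] == "TU_g01"],
    )
    _write_enzyme_table(directory / "enzyme_table.tsv", full)
    _write_tsv(
        directory / "keff_table.tsv",
        ["target_id", "target_type", "keff"],
        [(r, "reaction", keffs[r]) for r in sorted(keffs)],
    )
    translocation_keff = round(float(rng.uniform(15.0, 40.0)), 3)
    _write_tsv(
        directory / "translocation_table.tsv",
        ["pathway_id", "keff", "enzymes", "stoichiometry", "targets"],
        [(
            "sec_translocation",
            translocation_keff,
            "CPLX_SEC:fixed",
            "gtp_c:-0.04,h2o_c:-0.04,gdp_c:0.04,pi_c:0.04",
            "g01",
        )] if full else [],
    )

    params = {
        "seed": int(seed),
        "n_genes": int(n_genes),
        "difficulty": difficulty,
        "glucose_uptake_bound": uptake,
        "default_rnap": sigma_a,
        "ribosome_id": "ribosome",
        "synthetase_id": "CPLX_AA" if full else "CPLX_SYN",
        "degradosome_id": "CPLX_NUC" if full else None,
        "elongation_enzyme": "generic_EFTu" if full else None,
        "translocation_keff": translocation_keff if full else None,
        "reaction_keffs": {k: keffs[k] for k in sorted(keffs)},
    }
    sidecar_path = directory / "bundle.json"
    sidecar_path.write_text(json.dumps(params, indent=1, sort_keys=True) + "\n")
    return ToyOrganismBundle(
        directory=directory,
        genbank_path=directory / "genome.gb",
        m_model_path=directory / "m_model.json",
        tu_table_path=directory / "tu_table.tsv",
        enzyme_table_path=directory / "enzyme_table.tsv",
        keff_table_path=directory / "keff_table.tsv",
        translocation_table_path=directory / "translocation_table.tsv",
        sidecar_path=sidecar_path,
        params=params,
    )


def build_toy_model(n_genes=10, seed=1, difficulty="full", directory=None):
    """Generate a bundle (into a temp dir unless given) and build it."""
    if directory is None:
        directory = tempfile.mkdtemp(prefix="memodel_toy_")
    bundle = generate_toy_organism(directory, n_genes=n_genes, seed=seed,
                                   difficulty=difficulty)
    return build_me_model(bundle.build_inputs())


# ---------------------------------------------------------------------------
# file writers
# ---------------------------------------------------------------------------


def _write_tsv(path, columns, rows):
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_genbank(path, layout, trna_genes):
    genome = layout.genome()
    record = SeqRecord(
        Seq(genome),
        id="TOYCHR1",
        name="TOYCHR1",
        description="synthetic toy-organism chromosome",
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "date": "01-JAN-2000",
        },
    )
    aa_of_trna = {v: k for k, v in trna_genes.items()}
    for locus, ftype, left, right, strand in layout.features:
        qualifiers = {"locus_tag": [locus]}
        if ftype == "CDS":
            qualifiers["transl_table"] = ["11"]
        elif ftype == "tRNA":
            aa = aa_of_trna[locus]
            codon = chemistry.codons_for(chemistry.ID_TO_AA1[aa])[0]
            qualifiers["note"] = [f"amino_acid:{aa};codon:{codon}"]
        record.features.append(
            SeqFeature(
                FeatureLocation(left - 1, right, strand=1 if strand == "+" else -1),
                type=ftype,
                qualifiers=qualifiers,
            )
        )
    SeqIO.write(record, str(path), "genbank")


def _write_m_model(path, uptake, full):
    """COBRA-schema M-model; returns ids of the enzyme-catalyzed reactions."""
    model = cobra.Model("toy_m_model")
    mets = {}
    for name, formula in SMALL_MOLECULES.items():
        mets[name + "_c"] = cobra.Metabolite(
            name + "_c", formula=formula, compartment="c"
        )
    for aa in AA_IDS:
        mets[aa + "_c"] = cobra.Metabolite(
            aa + "_c",
            formula=chemistry.AA_FORMULA[chemistry.ID_TO_AA1[aa]],
            compartment="c",
        )
    for name in ("glc__D", "nh3", "h2s", "pi", "h2o", "h2", "mg2"):
        mets[name + "_e"] = cobra.Metabolite(
            name + "_e", formula=SMALL_MOLECULES[name], compartment="e"
        )
    model.add_metabolites(list(mets.values()))

    def add(rid, stoich, lb, ub, rule="", spontaneous=False):
        reaction = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        model.add_reactions([reaction])
        reaction.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if rule:
            reaction.gene_reaction_rule = rule
        if spontaneous:
            reaction.notes["spontaneous"] = True
        return rid

    catalyzed = []
    add("EX_glc__D_e", {"glc__D_e": -1}, -uptake, 1000.0)
    for name in ("nh3", "h2s", "pi", "mg2"):
        add(f"EX_{name}_e", {f"{name}_e": -1}, -1000.0, 1000.0)
    for name in ("h2o", "h2"):
        add(f"EX_{name}_e", {f"{name}_e": -1}, -1000.0, 1000.0)

    transport_rule = "g01"
    catalyzed.append(
        add("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0.0, 1000.0, rule=transport_rule)
    )
    for name in ("nh3", "h2s", "pi", "mg2"):
        add(f"{name.upper()}t", {f"{name}_e": -1, f"{name}_c": 1},
            -1000.0, 1000.0, spontaneous=True)
    for name in ("h2o", "h2"):
        add(f"{name.upper()}t", {f"{name}_e": -1, f"{name}_c": 1},
            -1000.0, 1000.0, spontaneous=True)

    synth_rule = "(g02 and g03)" if full else "g02"
    nuc_rule = "g04" if full else "g02"
    for aa in AA_IDS:
        stoich = balance_from_currencies(chemistry.AA_FORMULA[chemistry.ID_TO_AA1[aa]])
        stoich[aa + "_c"] = 1.0
        catalyzed.append(add(f"SYN_{aa}", stoich, 0.0, 1000.0, rule=synth_rule))
    for nmp in ("amp", "gmp", "cmp", "ump"):
        stoich = balance_from_currencies(chemistry.NMP_FORMULA[nmp])
        stoich[nmp + "_c"] = 1.0
        catalyzed.append(add(f"SYN_{nmp}", stoich, 0.0, 1000.0, rule=nuc_rule))
    for dntp in ("datp", "dgtp", "dctp", "dttp"):
        stoich = balance_from_currencies(chemistry.DNTP_FORMULA[dntp])
        stoich[dntp + "_c"] = 1.0
        catalyzed.append(add(f"SYN_{dntp}", stoich, 0.0, 1000.0, rule=nuc_rule))
    # (d)NMP -> NTP at the cost of two phosphates; NDP -> NTP at one
    for nmp, ntp in (("amp", "atp"), ("gmp", "gtp"), ("cmp", "ctp"), ("ump", "utp")):
        catalyzed.append(
            add(f"PHOS_{nmp}",
                {f"{nmp}_c": -1, "pi_c": -2, f"{ntp}_c": 1, "h2o_c": 2},
                0.0, 1000.0, rule=nuc_rule)
        )
    for ndp, ntp in (("adp", "atp"), ("gdp", "gtp")):
        catalyzed.append(
            add(f"PHOS_{ndp}",
                {f"{ndp}_c": -1, "pi_c": -1, f"{ntp}_c": 1, "h2o_c": 1},
                0.0, 1000.0, rule=nuc_rule)
        )
    add("PPIASE", {"ppi_c": -1, "h2o_c": -1, "pi_c": 2}, 0.0, 1000.0,
        spontaneous=True)
    lipid_stoich = balance_from_currencies(SMALL_MOLECULES["lipid_toy"])
    lipid_stoich["lipid_toy_c"] = 1.0
    # full difficulty: no catalyst and not spontaneous -> orphan reaction
    add("LIPID_SYN", lipid_stoich, 0.0, 1000.0,
        rule="" if full else "g02", spontaneous=False)

    legacy = add("BIOMASS_legacy", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                 0.0, 1000.0)
    model.objective = legacy
    cobra.io.save_json_model(model, str(path), sort=False, pretty=True)
    return catalyzed


def _write_enzyme_table(path, full):
    if full:
        rows = [
            ("CPLX_GLC", "protein_g01_Membrane:2", ""),
            ("CPLX_AA", "protein_g02:2,protein_g03:1", "mod_mg2:1"),
            ("CPLX_NUC", "protein_g04:1", ""),
            ("CPLX_SEC", "protein_g07:2", ""),
            ("generic_EFTu", "protein_g05:1,protein_g06:1", ""),
            ("ribosome", "RNA_rrna_1:1,protein_g07:4", ""),
            ("RNAP_sigA", "protein_g08:2,protein_g09:1", ""),
            ("RNAP_sigB", "protein_g08:2,protein_g10:1", ""),
        ]
    else:
        rows = [
            ("CPLX_GLC", "protein_g01:2", ""),
            ("CPLX_SYN", "protein_g02:1", ""),
            ("ribosome", "RNA_rrna_1:1,protein_g03:4", ""),
            ("RNAP", "protein_g03:2", ""),
        ]
    _write_tsv(path, ["complex_id", "subunits", "modifications"], rows)


# ---------------------------------------------------------------------------
# growth-rate oracles (independent of the bisection code path)
# ---------------------------------------------------------------------------


def brute_force_max_mu(model, mu_lo, mu_hi, step):
    """Largest grid growth rate with a feasible LP, by upward linear scan.

    Scans ``mu_lo, mu_lo + step, ...`` and stops at the first infeasible
    point (valid under the quasi-convex prefix property, which the test
    suite verifies separately). Raises :class:`InfeasibleAtMinError` if the
    very first point is infeasible.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    if not _grid_feasible(model, mu_lo):
        raise InfeasibleAtMinError(f"model infeasible at mu={mu_lo}")
    best = mu_lo
    k = 1
    while True:
        mu = mu_lo + k * step
        if mu > mu_hi + 1e-15:
            return best
        if not _grid_feasible(model, mu):
            return best
        best = mu
        k += 1


def refined_max_mu(model, mu_lo=0.0, mu_hi=2.0,
                   steps=(0.05, 1e-3, 2e-5, 1e-6)):
    """Staged grid-scan oracle: coarse-to-fine linear scans, final
    resolution ``steps[-1]``. Purely scan-based; shares no code with the
    bisection search."""
    lo, hi = mu_lo, mu_hi
    best = None
    for step in steps:
        best = brute_force_max_mu(model, lo, hi, step)
        lo, hi = best, min(best + step, mu_hi)
    return best
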