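"""ME-model JSON serialization and flux-table output.

The JSON schema stores each growth-rate-linear coefficient as a
``[constant, mu_coefficient]`` pair, the full ProcessData registry, and
every reaction's type, links and compiled stoichiometry, so a round trip
is lossless. The schema carries an explicit ``schema_version``; readers
reject newer major versions.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .core import (
    GlobalParameters,
    GrowthExpression,
    MEModel,
    metabolite_class,
)
from .exceptions import SchemaVersionError, ValidationError
from . import process_data as pdata_module
from .reactions import REACTION_TYPES

SCHEMA_VERSION = "1.0"

_PDATA_TYPES = {cls.__name__: cls for cls in pdata_module.PROCESS_DATA_TYPES}

_METABOLITE_FIELDS = {
    "transcribed_gene": ("rna_type", "nucleotide_sequence", "strand", "left", "right"),
    "translated_gene": ("amino_acid_sequence",),
    "processed_protein": ("unprocessed_id",),
}

_REACTION_LINKS = {
    "metabolic": ("stoichiometric_data_id", "complex_id", "direction", "keff"),
    "transcription": ("transcription_data_id",),
    "translation": ("translation_data_id",),
    "complex_formation": ("complex_data_id",),
    "trna_charging": ("trna_data_id",),
    "post_translation": ("post_translation_data_id",),
    "generic_formation": ("generic_data_id", "member_id"),
    "plain": (),
    "summary": (),
}


def _expression_pair(expression):
    return [expression.constant, expression.mu_coefficient]


def _expression_from(pair, path):
    try:
        constant, slope = pair
        return GrowthExpression(float(constant), float(slope))
    except (TypeError, ValueError):
        raise ValidationError(f"{path}: malformed coefficient {pair!r}") from None


def model_to_dict(model):
    """Canonical JSON-safe dict of a model (also the equality witness)."""
    data = {
        "schema_version": SCHEMA_VERSION,
        "id": model.id,
        "coupling_mode": model.coupling_mode,
        "objective_id": model.objective_id,
        "global_parameters": model.global_parameters.to_dict(),
        "global_info": model.global_info,
        "metabolites": [],
        "process_data": [],
        "reactions": [],
    }
    data["global_parameters"]["start_codons"] = list(
        data["global_parameters"]["start_codons"]
    )
    for metabolite in model.metabolites.values():
        entry = {
            "id": metabolite.id,
            "kind": metabolite.kind,
            "formula": metabolite.formula,
            "compartment": metabolite.compartment,
        }
        for name in _METABOLITE_FIELDS.get(metabolite.kind, ()):
            entry[name] = getattr(metabolite, name)
        data["metabolites"].append(entry)
    for pdata in model.process_data.values():
        entry = asdict(pdata)
        entry["ptype"] = type(pdata).__name__
        data["process_data"].append(entry)
    for reaction in model.reactions.values():
        entry = {
            "id": reaction.id,
            "rtype": reaction.reaction_type,
            "lower_bound": _expression_pair(reaction.lower_bound),
            "upper_bound": _expression_pair(reaction.upper_bound),
            "stoichiometry": {
                met: _expression_pair(coef)
                for met, coef in reaction.stoichiometry.items()
            },
        }
        for name in _REACTION_LINKS[reaction.reaction_type]:
            entry[name] = getattr(reaction, name)
        data["reactions"].append(entry)
    return data


def model_from_dict(data):
    version = data.get("schema_version", "")
    try:
        major = int(str(version).split(".", 1)[0])
    except ValueError:
        raise SchemaVersionError(f"unparseable schema_version {version!r}") from None
    if major > int(SCHEMA_VERSION.split(".")[0]):
        raise SchemaVersionError(
            f"schema_version {version} is newer than supported {SCHEMA_VERSION}"
        )
    model = MEModel(
        id=data.get("id", "me_model"),
        parameters=GlobalParameters.from_dict(data["global_parameters"]),
    )
    model.coupling_mode = data.get("coupling_mode", "embedded")
    model.objective_id = data.get("objective_id")
    model.global_info = data.get("global_info", {})
    for i, entry in enumerate(data.get("metabolites", [])):
        kind = entry.get("kind")
        try:
            cls = metabolite_class(kind)
        except KeyError:
            raise ValidationError(
                f"/metabolites/{i}: unknown metabolite kind {kind!r}"
            ) from None
        kwargs = {name: entry[name] for name in _METABOLITE_FIELDS.get(kind, ())}
        metabolite = cls(
            entry["id"],
            formula=entry.get("formula"),
            compartment=entry.get("compartment"),
            **kwargs,
        )
        model.add_metabolite(metabolite)
    for i, entry in enumerate(data.get("process_data", [])):
        entry = dict(entry)
        ptype = entry.pop("ptype", None)
        cls = _PDATA_TYPES.get(ptype)
        if cls is None:
            raise ValidationError(
                f"/process_data/{i}: unknown ProcessData type {ptype!r}"
            )
        model.register_process_data(cls(**entry))
    for i, entry in enumerate(data.get("reactions", [])):
        rtype = entry.get("rtype")
        cls = REACTION_TYPES.get(rtype)
        if cls is None:
            raise ValidationError(f"/reactions/{i}: unknown reaction type {rtype!r}")
        links = {name: entry[name] for name in _REACTION_LINKS[rtype]}
        reaction = cls(entry["id"], **links)
        reaction.lower_bound = _expression_from(
            entry["lower_bound"], f"/reactions/{i}/lower_bound"
        )
        reaction.upper_bound = _expression_from(
            entry["upper_bound"], f"/reactions/{i}/upper_bound"
        )
        reaction.stoichiometry = {
            met: _expression_from(pair, f"/reactions/{i}/stoichiometry/{met}")
            for met, pair in entry["stoichiometry"].items()
        }
        model.add_reaction(reaction)
    return model


def write_me_json(model, path):
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
    return Path(path)


def read_me_json(path):
    return model_from_dict(json.loads(Path(path).read_text()))


def models_equal(model_a, model_b):
    """Structural equality through the canonical serialized form."""
    return model_to_dict(model_a) == model_to_dict(model_b)


def write_flux_tsv(solution, path, model=None, floor=None):
    """Write ``reaction_id, flux, reaction_type`` rows for a solution.

    Rows follow the model's reaction order (or sorted ids without a
    model). With ``floor`` set, flux magnitudes below it are reported as
    the floor value, the convention used for log-scale flux plots.
    """
    if model is not None:
        order = [r for r in model.reactions if r in solution.fluxes]
        types = {r: model.reactions[r].reaction_type for r in order}
    else:
        order = sorted(solution.fluxes)
        types = {r: "" for r in order}
    lines = ["reaction_id\tflux\treaction_type"]
    for reaction_id in order:
        flux = solution.fluxes[reaction_id]
        if floor is not None and abs(flux) < floor:
            flux = floor
        lines.append(f"{reaction_id}\t{flux:.12g}\t{types[reaction_id]}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
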