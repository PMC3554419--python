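"""Model definition I/O: the documented YAML schema plus optional SBML import.

Schema (YAML):
    name: str
    species:   [{id, compartment, unit?}, ...]
    clamped:   [species id, ...]
    reactions: [{id, pathway_index?, stoichiometry: {species: signed int},
                 rate_law: {kind, vmax_ref, km_substrates?, km_products?,
                            keq_ref?, effector_constants?}}, ...]
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .kinetic_core import NetworkModel, RateLaw, Reaction, Species

_SPECIES_KEYS = {"id", "compartment", "unit"}
_REACTION_KEYS = {"id", "pathway_index", "stoichiometry", "rate_law"}
_RATE_LAW_KEYS = {"kind", "vmax_ref", "km_substrates", "km_products",
                  "keq_ref", "effector_constants"}


def model_from_dict(doc: dict) -> NetworkModel:
    if not isinstance(doc, dict) or "species" not in doc or "reactions" not in doc:
        raise ConfigurationError("model document must define 'species' and 'reactions'")
    species = []
    for entry in doc["species"]:
        bad = set(entry) - _SPECIES_KEYS
        if bad:
            raise ConfigurationError(f"species entry has unknown keys: {sorted(bad)}")
        species.append(Species(**entry))
    reactions = []
    for entry in doc["reactions"]:
        bad = set(entry) - _REACTION_KEYS
        if bad:
            raise ConfigurationError(
                f"reaction {entry.get('id', '?')!r} has unknown keys: {sorted(bad)}")
        rl = dict(entry["rate_law"])
        bad = set(rl) - _RATE_LAW_KEYS
        if bad:
            raise ConfigurationError(
                f"rate law of {entry.get('id', '?')!r} has unknown keys: {sorted(bad)}")
        reactions.append(Reaction(
            id=entry["id"],
            stoichiometry={k: int(v) for k, v in entry["stoichiometry"].items()},
            rate_law=RateLaw(**rl),
            pathway_index=int(entry.get("pathway_index", 0)),
        ))
    return NetworkModel(species=species, reactions=reactions,
                        clamped=set(doc.get("clamped", [])),
                        name=doc.get("name", "model"))


def model_to_dict(model: NetworkModel) -> dict:
    return {
        "name": model.name,
        "species": [{"id": s.id, "compartment": s.compartment, "unit": s.unit}
                    for s in model.species],
        "clamped": sorted(model.clamped),
        "reactions": [
            {
                "id": r.id,
                "pathway_index": r.pathway_index,
                "stoichiometry": dict(r.stoichiometry),
                "rate_law": {
                    k: v for k, v in (
                        ("kind", r.rate_law.kind),
                        ("vmax_ref", r.rate_law.vmax_ref),
                        ("km_substrates", r.rate_law.km_substrates),
                        ("km_products", r.rate_law.km_products),
                        ("keq_ref", r.rate_law.keq_ref),
                        ("effector_constants", r.rate_law.effector_constants),
                    ) if v not in (None, {}, [])
                },
            }
            for r in model.reactions
        ],
    }


def load_model(path: str | Path, fmt: str = "auto") -> NetworkModel:
    """Load a model definition from YAML (or SBML when ``fmt='sbml'``)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "yaml"
    if fmt == "sbml":
        return load_sbml(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def save_model(model: NetworkModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_packaged_model(name: str = "reduced_glycolysis") -> NetworkModel:
    """The glycolysis model shipped with the package."""
    ref = importlib.resources.files("glycotherm") / "models" / f"{name}.yaml"
    return model_from_dict(yaml.safe_load(ref.read_text()))


def load_sbml(path: str | Path):  # pragma: no cover - optional dependency
    """Read-only SBML import (Level 2/3 subset) of a full base model.

    Maps species, compartments and mass-action/Michaelis-Menten-shaped kinetic
    laws where representable; anything else is reported, not guessed.  Requires
    the optional ``python-libsbml`` dependency.
    """
    try:
        import libsbml
    except ImportError as exc:
        raise ConfigurationError(
            "SBML import requires the optional dependency python-libsbml "
            "(pip install glycotherm[sbml]); the packaged YAML model needs no "
            "extra dependency") from exc
    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ConfigurationError(f"SBML parse errors in {path}")
    sbml_model = doc.getModel()
    species = [Species(s.getId(), "extracellular" if s.getBoundaryCondition()
                       else "intracellular") for s in sbml_model.getListOfSpecies()]
    clamped = {s.getId() for s in sbml_model.getListOfSpecies()
               if s.getBoundaryCondition() or s.getConstant()}
    unmapped: list[str] = []
    reactions = []
    for i, rxn in enumerate(sbml_model.getListOfReactions()):
        stoich: dict[str, int] = {}
        for sr in rxn.getListOfReactants():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0) - int(sr.getStoichiometry())
        for sr in rxn.getListOfProducts():
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0) + int(sr.getStoichiometry())
        kl = rxn.getKineticLaw()
        vmax = None
        if kl is not None:
            for p in kl.getListOfParameters():
                if p.getId().lower().startswith(("vmax", "v_max", "vm")):
                    vmax = p.getValue()
        if vmax is None:
            unmapped.append(rxn.getId())
            continue
        reactions.append(Reaction(rxn.getId(), stoich,
                                  RateLaw("irreversible_mm", vmax,
                                          {s: 1.0 for s, c in stoich.items() if c < 0}),
                                  pathway_index=i + 1))
    model = NetworkModel(species, reactions, clamped=clamped,
                         name=sbml_model.getId() or "sbml_model")
    model.unmapped_reactions = unmapped  # type: ignore[attr-defined]
    return model
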