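"""Packaged pathway library and the structured-text pathway schema.

Pathway definitions live in ``data/pathways.yaml`` (see the header
comment there for the schema) and are parsed into exact-rational
:class:`~pelokit.energetics.Pathway` objects.  User-supplied files in
the same schema can be loaded with :func:`load_pathways`.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources
from pathlib import Path

import yaml

from .energetics import Pathway, Reaction

__all__ = ["pathway_library", "load_pathways", "parse_pathways"]


def _coerce(value) -> Fraction:
    # integers stay exact; strings like "1/2" parse exactly
    if isinstance(value, bool):
        raise TypeError("boolean is not a stoichiometric coefficient")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"stoichiometric coefficients must be int or string, got {value!r}")


def parse_pathways(doc: dict) -> dict[str, Pathway]:
    """Build Pathway objects from a parsed YAML document."""
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise ValueError("pathway document must be a mapping with a 'pathways' list")
    library: dict[str, Pathway] = {}
    for entry in doc["pathways"]:
        name = entry["name"]
        if name in library:
            raise ValueError(f"duplicate pathway name {name!r}")
        reactions = tuple(
            (
                Reaction(
                    step["name"],
                    {k: _coerce(v) for k, v in (step.get("deltas") or {}).items()},
                ),
                _coerce(step.get("times", 1)),
            )
            for step in entry["reactions"]
        )
        products = tuple(
            (p["name"], _coerce(p["coeff"])) for p in entry.get("products", [])
        )
        library[name] = Pathway(
            name=name,
            substrate=entry["substrate"],
            substrate_multiplicity=int(entry["multiplicity"]),
            reactions=reactions,
            products=products,
            notes=(entry.get("notes") or "").strip(),
        )
    return library


def load_pathways(path: str | Path) -> dict[str, Pathway]:
    """Load pathways from a user-supplied YAML file."""
    with open(path) as fh:
        return parse_pathways(yaml.safe_load(fh))


def pathway_library() -> dict[str, Pathway]:
    """The packaged pathway set, parsed fresh on each call."""
    text = resources.files("pelokit.data").joinpath("pathways.yaml").read_text()
    return parse_pathways(yaml.safe_load(text))
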