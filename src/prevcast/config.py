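"""Structured-text (YAML) configuration for schemas and imputation models.

A config file declares the variable schema and, optionally, per-variable
imputation-model terms and engine settings::

    schema:
      - {name: year, role: design, vtype: continuous}
      - {name: sex, role: design, vtype: categorical, levels: [male, female]}
      - {name: age, role: design, vtype: continuous}
      - {name: obesity, role: outcome, vtype: binary, imputable: true}
    models:
      obesity:
        terms: ["sex", "age", {spline: year, df: 2}, "year:age"]
    engine: {m: 50, iterations: 10, seed: 20211214}

Term syntax: a bare name is a main effect, ``"a:b"`` an interaction, and
``{spline: VAR, df: K}`` a restricted cubic spline.
"""

from __future__ import annotations

import yaml

from .imputers import ImputationModel, TermSpec, interaction, main, spline
from .survey import VariableSpec


def parse_term(raw) -> TermSpec:
    if isinstance(raw, str):
        if ":" in raw:
            return interaction(*raw.split(":"))
        return main(raw)
    if isinstance(raw, dict) and "spline" in raw:
        return spline(raw["spline"], int(raw.get("df", 2)))
    raise ValueError(f"cannot parse term {raw!r}")


def schema_from_config(doc: dict) -> list[VariableSpec]:
    specs = []
    for entry in doc["schema"]:
        specs.append(
            VariableSpec(
                name=entry["name"],
                role=entry["role"],
                vtype=entry["vtype"],
                levels=tuple(entry["levels"]) if entry.get("levels") else None,
                imputable=bool(entry.get("imputable", False)),
            )
        )
    return specs


def models_from_config(
    doc: dict, schema: list[VariableSpec], ridge: float = 1e-5
) -> dict[str, ImputationModel]:
    by_name = {s.name: s for s in schema}
    models = {}
    for outcome, body in (doc.get("models") or {}).items():
        spec = by_name[outcome]
        family = (
            "binary-logistic" if spec.vtype == "binary"
            else "polytomous-logistic"
        )
        terms = tuple(parse_term(t) for t in body["terms"])
        models[outcome] = ImputationModel(
            outcome, terms, body.get("family", family),
            float(body.get("ridge", ridge)),
        )
    return models


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


__all__ = [
    "parse_term",
    "schema_from_config",
    "models_from_config",
    "load_config",
]
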