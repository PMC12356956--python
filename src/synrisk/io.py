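"""Readers and writers for the on-disk formats.

JSON is the canonical dialect; YAML is accepted on read only (JSON is a
subset of YAML, so one reader handles both).  Writers emit canonical key
order and canonical CPT row order (row-major over parents in declared order)
so that serialized networks round-trip bit-identically.

Network file schema::

    {"variables": [{"name": ..., "levels": [...]}, ...],
     "edges": [[parent, child], ...],
     "cpts": [{"variable": ..., "parents": [...],
               "rows": [{"given": {parent: level, ...},
                         "p": {level: prob, ...}}, ...]}, ...]}

Risk-table schema::

    {"type": "risk_table", "outcome": ..., "outcome_level": ...,
     "scale_note": ..., "factors": [{"variable", "reference", "risk"}, ...],
     "values": [{"config": {variable: level, ...}, "risk": number}, ...]}

Scenario schema::

    {"outcome": ..., "outcome_level": ...,
     "factors": [{"variable", "reference", "risk"}, ...],
     "context": {variable: level, ...}}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Union

import yaml

from .effects import RiskFactorSpec, RiskTable, Scenario
from .network import (
    ConditionalTable,
    DiscreteNetwork,
    NetworkError,
    NetworkStructure,
    Variable,
    parent_configurations,
)

PathLike = Union[str, Path]


class ParseError(NetworkError):
    """Malformed input container for any of the on-disk formats."""


def _load_any(path: PathLike) -> Any:
    text = Path(path).read_text()
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ParseError(f"cannot parse {path}: {e}") from None


def network_to_dict(net: DiscreteNetwork) -> dict:
    s = net.structure
    cpts = []
    for v in s.variables:
        t = net.tables[v.name]
        rows = [
            {
                "given": dict(zip(t.parents, cfg)),
                "p": {lv: t.rows[cfg][lv] for lv in v.levels},
            }
            for cfg in parent_configurations(t.parents, s)
        ]
        cpts.append({"variable": v.name, "parents": list(t.parents), "rows": rows})
    return {
        "variables": [{"name": v.name, "levels": list(v.levels)} for v in s.variables],
        "edges": [list(e) for e in s.edges],
        "cpts": cpts,
    }


def network_from_dict(d: Any) -> DiscreteNetwork:
    if not isinstance(d, dict):
        raise ParseError(f"network spec must be a mapping, got {type(d).__name__}")
    for key in ("variables", "edges", "cpts"):
        if key not in d:
            raise ParseError(f"network spec lacks required key {key!r}")
    try:
        variables = tuple(
            Variable(v["name"], tuple(v["levels"])) for v in d["variables"]
        )
        edges = tuple((p, c) for p, c in d["edges"])
        structure = NetworkStructure(variables, edges)
        tables: dict[str, ConditionalTable] = {}
        for c in d["cpts"]:
            parents = tuple(c["parents"])
            rows = {
                tuple(r["given"][p] for p in parents): {
                    lv: float(p_) for lv, p_ in r["p"].items()
                }
                for r in c["rows"]
            }
            tables[c["variable"]] = ConditionalTable(c["variable"], parents, rows)
    except (KeyError, TypeError) as e:
        raise ParseError(f"malformed network spec: {e!r}") from None
    return DiscreteNetwork(structure, tables)


def read_network(path: PathLike) -> DiscreteNetwork:
    return network_from_dict(_load_any(path))


def write_network(net: DiscreteNetwork, path: PathLike) -> None:
    Path(path).write_text(json.dumps(network_to_dict(net), indent=1) + "\n")


def _factor_specs(items: Any) -> tuple[RiskFactorSpec, ...]:
    return tuple(
        RiskFactorSpec(f["variable"], f["reference"], f["risk"]) for f in items
    )


def risk_table_to_dict(table: RiskTable) -> dict:
    return {
        "type": "risk_table",
        "outcome": table.outcome,
        "outcome_level": table.outcome_level,
        "scale_note": table.scale_note,
        "factors": [
            {"variable": f.variable, "reference": f.reference, "risk": f.risk}
            for f in table.factors
        ],
        "values": [
            {
                "config": {f.variable: lv for f, lv in zip(table.factors, cfg)},
                "risk": risk,
            }
            for cfg, risk in sorted(table.values.items())
        ],
    }


def risk_table_from_dict(d: Any) -> RiskTable:
    try:
        factors = _factor_specs(d["factors"])
        values = {
            tuple(item["config"][f.variable] for f in factors): float(item["risk"])
            for item in d["values"]
        }
        return RiskTable(
            d["outcome"],
            d["outcome_level"],
            factors,
            values,
            scale_note=d.get("scale_note", ""),
        )
    except (KeyError, TypeError) as e:
        raise ParseError(f"malformed risk table: {e!r}") from None


def read_risk_table(path: PathLike) -> RiskTable:
    return risk_table_from_dict(_load_any(path))


def write_risk_table(table: RiskTable, path: PathLike) -> None:
    Path(path).write_text(json.dumps(risk_table_to_dict(table), indent=1) + "\n")


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "outcome": sc.outcome,
        "outcome_level": sc.outcome_level,
        "factors": [
            {"variable": f.variable, "reference": f.reference, "risk": f.risk}
            for f in sc.factors
        ],
        "context": dict(sc.context),
    }


def scenario_from_dict(d: Any) -> Scenario:
    try:
        return Scenario(
            d["outcome"],
            d["outcome_level"],
            _factor_specs(d["factors"]),
            dict(d.get("context", {})),
        )
    except (KeyError, TypeError) as e:
        raise ParseError(f"malformed scenario: {e!r}") from None


def read_scenario(path: PathLike) -> Scenario:
    return scenario_from_dict(_load_any(path))


def read_source(path: PathLike):
    """Read a network or a risk table, dispatching on the `type` field."""
    d = _load_any(path)
    if isinstance(d, dict) and d.get("type") == "risk_table":
        return risk_table_from_dict(d)
    return network_from_dict(d)


def read_levels(path: PathLike) -> dict[str, list[str]]:
    """Levels sidecar: JSON mapping variable name -> ordered level list."""
    d = _load_any(path)
    if not isinstance(d, dict) or not all(isinstance(v, list) for v in d.values()):
        raise ParseError("levels sidecar must map variable names to level lists")
    return {k: [str(x) for x in v] for k, v in d.items()}
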