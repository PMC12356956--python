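"""Discrete Bayesian networks over named categorical levels.

A network is a directed acyclic graph of categorical variables, each with a
conditional probability table (CPT) giving a distribution over its levels for
every configuration of its parents.  The joint distribution factorizes by the
chain rule:

    P(x_1, ..., x_n) = prod_i P(x_i | parents(x_i))

Level labels are case-sensitive opaque strings; no coercion of "1"/"true" is
performed.  CPT rows are stored in canonical row-major order over the parents
in their declared order, so serialized networks round-trip bit-identically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx

#: tolerance for CPT row normalization checks
NORMALIZATION_TOL = 1e-9

Assignment = Mapping[str, str]


class NetworkError(ValueError):
    """Structural or probabilistic inconsistency in a network or query."""


class CycleError(NetworkError):
    """The directed graph contains a cycle."""


@dataclass(frozen=True)
class Variable:
    """A categorical variable with an ordered set of >=2 distinct levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise NetworkError(
                f"level {level!r} is not a level of variable {self.name!r}; "
                f"legal levels: {list(self.levels)}"
            ) from None


@dataclass(frozen=True)
class NetworkStructure:
    """A DAG over variables: nodes are variable names, edges parent->child."""

    variables: tuple[Variable, ...]
    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise NetworkError(f"unknown variable {name!r}")

    def parents(self, name: str) -> tuple[str, ...]:
        """Graph parents of ``name`` in declaration order of the variables."""
        order = {v.name: i for i, v in enumerate(self.variables)}
        ps = [p for (p, c) in self.edges if c == name]
        return tuple(sorted(set(ps), key=lambda p: order.get(p, len(order))))

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edges)
        return g


def parent_configurations(
    parents: Sequence[str], structure: NetworkStructure
) -> Iterator[tuple[str, ...]]:
    """All parent-level configurations in canonical row-major order."""
    level_lists = [structure.variable(p).levels for p in parents]
    return itertools.product(*level_lists)


@dataclass
class ConditionalTable:
    """CPT: for each parent configuration, a distribution over child levels.

    ``rows`` maps a tuple of parent levels (ordered as ``parents``) to a
    mapping level -> probability.  A root variable has the single key ``()``.
    """

    variable: str
    parents: tuple[str, ...]
    rows: dict[tuple[str, ...], dict[str, float]]

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.rows = {tuple(k): dict(v) for k, v in self.rows.items()}

    def prob(self, level: str, parent_levels: tuple[str, ...]) -> float:
        try:
            row = self.rows[tuple(parent_levels)]
        except KeyError:
            raise NetworkError(
                f"CPT for {self.variable!r} has no row for parent "
                f"configuration {dict(zip(self.parents, parent_levels))}"
            ) from None
        try:
            return row[level]
        except KeyError:
            raise NetworkError(
                f"CPT row for {self.variable!r} lacks level {level!r}"
            ) from None


@dataclass
class DiscreteNetwork:
    """A structure plus one conditional table per variable."""

    structure: NetworkStructure
    tables: dict[str, ConditionalTable] = field(default_factory=dict)

    def variable(self, name: str) -> Variable:
        return self.structure.variable(name)

    def renormalized(self) -> "DiscreteNetwork":
        """Copy with every CPT row explicitly renormalized.

        Renormalization is never applied silently on load; callers opt in.
        """
        tables: dict[str, ConditionalTable] = {}
        for name, t in self.tables.items():
            rows = {}
            for cfg, dist in t.rows.items():
                total = sum(dist.values())
                if total <= 0:
                    raise NetworkError(
                        f"cannot renormalize all-zero row {cfg} of {name!r}"
                    )
                rows[cfg] = {lv: p / total for lv, p in dist.items()}
            tables[name] = ConditionalTable(name, t.parents, rows)
        return DiscreteNetwork(self.structure, tables)


def topological_order(structure: NetworkStructure) -> list[str]:
    """Variable names with every parent before its children.

    Deterministic: ties are broken by lexicographic name.  Raises
    :class:`CycleError` naming one cycle's members if the graph is cyclic.
    """
    g = structure.to_digraph()
    try:
        return list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise CycleError(f"graph contains a cycle through {cycle}") from None


def validate_network(net: DiscreteNetwork) -> list[str]:
    """Check every structural and probabilistic invariant.

    Returns a list of human-readable violations; an empty list means the
    network is valid.  Never raises on invalid content, only reports.
    """
    violations: list[str] = []
    s = net.structure

    names = [v.name for v in s.variables]
    for n in names:
        if names.count(n) > 1:
            violations.append(f"duplicate variable name {n!r}")
            break
    for v in s.variables:
        if len(v.levels) < 2:
            violations.append(f"variable {v.name!r} has fewer than 2 levels")
        if len(set(v.levels)) != len(v.levels):
            violations.append(f"variable {v.name!r} has duplicate level labels")

    declared = set(names)
    for (p, c) in s.edges:
        if p not in declared or c not in declared:
            violations.append(f"edge ({p!r}, {c!r}) references undeclared variable")
        if p == c:
            violations.append(f"self-loop on {p!r}")
    if len(set(s.edges)) != len(s.edges):
        violations.append("duplicate edges")

    if not any("undeclared" in v or "self-loop" in v for v in violations):
        g = s.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            violations.append(f"cycle through {cycle}")
            return violations  # parent sets ill-defined under a cycle

    for v in s.variables:
        t = net.tables.get(v.name)
        if t is None:
            violations.append(f"variable {v.name!r} has no conditional table")
            continue
        graph_parents = s.parents(v.name)
        if tuple(sorted(t.parents)) != tuple(sorted(graph_parents)):
            violations.append(
                f"table for {v.name!r} declares parents {list(t.parents)} but "
                f"graph parents are {list(graph_parents)}"
            )
            continue
        expected = set(parent_configurations(t.parents, s))
        got = set(t.rows)
        if got != expected:
            missing = sorted(expected - got)[:3]
            extra = sorted(got - expected)[:3]
            violations.append(
                f"table for {v.name!r} rows incomplete or inconsistent "
                f"(missing e.g. {missing}, extraneous e.g. {extra})"
            )
            continue
        for cfg, dist in t.rows.items():
            if set(dist) != set(v.levels):
                violations.append(
                    f"row {cfg} of {v.name!r} does not cover levels {list(v.levels)}"
                )
                continue
            if any(p < 0 for p in dist.values()):
                violations.append(f"row {cfg} of {v.name!r} has negative probability")
            total = sum(dist.values())
            if abs(total - 1.0) > NORMALIZATION_TOL:
                violations.append(
                    f"row {cfg} of {v.name!r} violates normalization: sums to {total!r}"
                )
    for extra_name in set(net.tables) - declared:
        violations.append(f"table for undeclared variable {extra_name!r}")
    return violations


def check_assignment(net: DiscreteNetwork, assignment: Assignment) -> None:
    """Raise :class:`NetworkError` if any variable or level is unknown."""
    for name, level in assignment.items():
        net.variable(name).index(level)


def joint_probability(net: DiscreteNetwork, full: Assignment) -> float:
    """Chain-rule joint probability of a full assignment.

    ``full`` must assign a level to every variable; a partial assignment is
    an error listing the missing variables.
    """
    missing = [v.name for v in net.structure.variables if v.name not in full]
    if missing:
        raise NetworkError(f"assignment is missing variables {missing}")
    check_assignment(net, full)
    p = 1.0
    for v in net.structure.variables:
        t = net.tables[v.name]
        parent_levels = tuple(full[q] for q in t.parents)
        p *= t.prob(full[v.name], parent_levels)
    return p


def full_assignments(net: DiscreteNetwork) -> Iterator[dict[str, str]]:
    """Every full assignment, row-major over variables in declared order."""
    names = net.structure.names
    level_lists = [net.variable(n).levels for n in names]
    for combo in itertools.product(*level_lists):
        yield dict(zip(names, combo))
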