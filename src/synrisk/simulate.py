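"""Synthetic categorical data: forward sampling and planted-interaction networks.

Two generators make every other module testable without external data:

* :func:`forward_sample` draws i.i.d. records from any valid network by
  ancestral sampling in topological order, deterministically for a fixed seed.
* :func:`build_planted_network` constructs a network whose ground-truth
  nonlinear effect factor is known exactly: independent root exposures with
  given prevalences feed a binary outcome whose conditional probability is
  the baseline ``p0`` plus the single delta ``d_i`` when exactly one exposure
  is active, and ``p0 + gamma* x (sum of active deltas)`` when two or more
  are active.  Evaluating the planted scenario therefore recovers ``gamma*``
  exactly, and fitting CPTs to forward samples recovers it statistically.

The crash- and health-survey-like fixture networks are invented, plausible
parameterizations shipped for tests and demos; their CPTs are not estimates
from any real dataset.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .effects import EffectReport, RiskFactorSpec, Scenario, evaluate_scenario
from .learning import RecordSet, fit_network, tabulate_counts, unseen_configurations
from .network import (
    ConditionalTable,
    DiscreteNetwork,
    NetworkError,
    NetworkStructure,
    Variable,
    parent_configurations,
    topological_order,
    validate_network,
)


class PlantError(NetworkError):
    """Infeasible planted-interaction specification."""


def network_hash(net: DiscreteNetwork) -> str:
    """SHA-256 of the canonical JSON serialization (provenance fingerprint)."""
    from .io import network_to_dict

    blob = json.dumps(network_to_dict(net), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class SampleSet:
    """Seeded records plus a provenance manifest (network hash, n, seed)."""

    records: RecordSet
    manifest: dict = field(default_factory=dict)


def forward_sample(
    net: DiscreteNetwork, n: int, seed: int, schema: str = "custom"
) -> SampleSet:
    """Ancestral sampling: draw ``n`` i.i.d. records in topological order."""
    if n < 0:
        raise NetworkError(f"sample count must be nonnegative, got {n}")
    violations = validate_network(net)
    if violations:
        raise NetworkError(f"invalid network: {violations[0]}")
    rng = np.random.default_rng(seed)
    order = topological_order(net.structure)
    columns = tuple(order)
    data: dict[str, np.ndarray] = {}
    for name in order:
        var = net.variable(name)
        t = net.tables[name]
        k = len(var.levels)
        draws = np.empty(n, dtype=np.int64)
        u = rng.random(n)
        if t.parents:
            # group rows by parent configuration, vectorized inverse-CDF draw
            parent_codes = np.zeros(n, dtype=np.int64)
            for p in t.parents:
                parent_codes = parent_codes * len(net.variable(p).levels) + data[p]
            cfg_list = list(parent_configurations(t.parents, net.structure))
            for code, cfg in enumerate(cfg_list):
                mask = parent_codes == code
                if not mask.any():
                    continue
                cdf = np.cumsum([t.rows[cfg][lv] for lv in var.levels])
                draws[mask] = np.searchsorted(cdf, u[mask], side="right")
        else:
            cdf = np.cumsum([t.rows[()][lv] for lv in var.levels])
            draws = np.searchsorted(cdf, u, side="right")
        data[name] = np.clip(draws, 0, k - 1)
    levels = {name: net.variable(name).levels for name in order}
    rows = [
        tuple(levels[name][data[name][i]] for name in order) for i in range(n)
    ]
    records = RecordSet(columns, rows, provenance=f"forward_sample(seed={seed})")
    manifest = {
        "network_hash": network_hash(net),
        "n": n,
        "seed": seed,
        "schema": schema,
    }
    return SampleSet(records, manifest)


@dataclass
class PlantSpec:
    """Ground truth for a planted-interaction network.

    ``p0`` is the baseline outcome risk, ``deltas`` the single-exposure
    deltas, ``gamma`` the planted nonlinear effect factor applied to the sum
    of active deltas whenever two or more exposures are active, and
    ``prevalences`` the marginal probability of each exposure being active.
    """

    p0: float
    deltas: tuple[float, ...]
    gamma: float
    prevalences: tuple[float, ...] = ()
    outcome: str = "outcome"
    outcome_levels: tuple[str, str] = ("no", "yes")
    factor_names: tuple[str, ...] = ()
    factor_levels: tuple[str, str] = ("ref", "risk")

    def __post_init__(self) -> None:
        self.deltas = tuple(float(d) for d in self.deltas)
        n = len(self.deltas)
        if n < 2:
            raise PlantError("a planted spec needs at least two factors")
        if not 0.0 < self.p0 < 1.0:
            raise PlantError(f"baseline p0 must lie in (0,1), got {self.p0}")
        if self.gamma <= 0:
            raise PlantError(f"planted gamma must be positive, got {self.gamma}")
        if not self.prevalences:
            self.prevalences = (0.5,) * n
        self.prevalences = tuple(float(p) for p in self.prevalences)
        if len(self.prevalences) != n:
            raise PlantError("one prevalence per factor is required")
        if any(not 0.0 < p < 1.0 for p in self.prevalences):
            raise PlantError("prevalences must lie in (0,1)")
        if not self.factor_names:
            self.factor_names = tuple(f"x{i + 1}" for i in range(n))
        if len(self.factor_names) != n:
            raise PlantError("one factor name per delta is required")
        for active in itertools.chain.from_iterable(
            itertools.combinations(range(n), size) for size in range(n + 1)
        ):
            p = self.outcome_probability(active)
            if not 0.0 <= p <= 1.0:
                raise PlantError(
                    f"infeasible spec: outcome probability {p:.6g} for active "
                    f"factors {list(active)} is outside [0, 1]"
                )

    @property
    def n_factors(self) -> int:
        return len(self.deltas)

    def outcome_probability(self, active: tuple[int, ...]) -> float:
        """Planted P(outcome=yes | active exposure set)."""
        if len(active) == 0:
            return self.p0
        if len(active) == 1:
            return self.p0 + self.deltas[active[0]]
        return self.p0 + self.gamma * sum(self.deltas[i] for i in active)

    def scenario(self) -> Scenario:
        ref, risk = self.factor_levels
        return Scenario(
            self.outcome,
            self.outcome_levels[1],
            tuple(RiskFactorSpec(name, ref, risk) for name in self.factor_names),
        )


def build_planted_network(spec: PlantSpec) -> DiscreteNetwork:
    """Network with independent root exposures and the planted outcome CPT."""
    ref, risk = spec.factor_levels
    no, yes = spec.outcome_levels
    variables = tuple(
        Variable(name, (ref, risk)) for name in spec.factor_names
    ) + (Variable(spec.outcome, (no, yes)),)
    edges = tuple((name, spec.outcome) for name in spec.factor_names)
    structure = NetworkStructure(variables, edges)
    tables: dict[str, ConditionalTable] = {}
    for name, prev in zip(spec.factor_names, spec.prevalences):
        tables[name] = ConditionalTable(name, (), {(): {ref: 1 - prev, risk: prev}})
    rows: dict[tuple[str, ...], dict[str, float]] = {}
    for cfg in itertools.product((ref, risk), repeat=spec.n_factors):
        active = tuple(i for i, lv in enumerate(cfg) if lv == risk)
        p = spec.outcome_probability(active)
        rows[cfg] = {no: 1.0 - p, yes: p}
    tables[spec.outcome] = ConditionalTable(spec.outcome, spec.factor_names, rows)
    return DiscreteNetwork(structure, tables)


@dataclass
class RecoveryResult:
    """End-to-end parameter recovery: estimated gamma with provenance."""

    gamma_hat: float | None
    report: EffectReport
    n: int
    seed: int
    low_confidence: bool


def recover_gamma(
    spec: PlantSpec, n: int, seed: int, alpha: float = 0.0
) -> RecoveryResult:
    """Build, sample, fit, evaluate: the full simulation-recovery loop.

    The result is flagged low-confidence when any parent configuration of any
    CPT was unobserved in the sample (its fitted row is then uninformative).
    """
    net = build_planted_network(spec)
    samples = forward_sample(net, n, seed, schema="planted")
    counts = tabulate_counts(samples.records, net.structure)
    low_confidence = bool(unseen_configurations(counts))
    fitted = fit_network(samples.records, net.structure, alpha=alpha)
    report = evaluate_scenario(fitted, spec.scenario())
    return RecoveryResult(
        gamma_hat=report.gamma,
        report=report,
        n=n,
        seed=seed,
        low_confidence=low_confidence,
    )


def random_network(
    rng: np.random.Generator,
    n_vars: int = 5,
    max_levels: int = 3,
    edge_prob: float = 0.4,
) -> DiscreteNetwork:
    """Random small network for property tests: random DAG, Dirichlet CPT rows."""
    names = [f"v{i}" for i in range(n_vars)]
    variables = tuple(
        Variable(name, tuple(f"l{j}" for j in range(rng.integers(2, max_levels + 1))))
        for name in names
    )
    # edges only from lower to higher index: acyclic by construction
    edges = tuple(
        (names[i], names[j])
        for i in range(n_vars)
        for j in range(i + 1, n_vars)
        if rng.random() < edge_prob
    )
    structure = NetworkStructure(variables, edges)
    tables = {}
    for v in variables:
        parents = structure.parents(v.name)
        rows = {}
        for cfg in parent_configurations(parents, structure):
            probs = rng.dirichlet(np.ones(len(v.levels)))
            rows[cfg] = dict(zip(v.levels, probs.tolist()))
        tables[v.name] = ConditionalTable(v.name, parents, rows)
    return DiscreteNetwork(structure, tables)


def _monotone_severity_row(
    base: dict[str, float], hazard: float
) -> dict[str, float]:
    """Shift severity mass toward worse outcomes as the hazard multiplier grows.

    The fatal probability is multiplied by ``hazard``; injury absorbs part of
    the shift; damage takes the remainder.  Hazard > 1 strictly increases the
    fatal level, keeping a proper distribution.
    """
    fatal = min(base["fatal"] * hazard, 0.9)
    injury = min(base["injury"] * (1 + 0.3 * (hazard - 1)), 0.95 - fatal)
    damage = 1.0 - fatal - injury
    return {"damage": damage, "injury": injury, "fatal": fatal}


def crash_schema() -> DiscreteNetwork:
    """Invented, plausible crash-report-like fixture network.

    Variables mirror a crash-report schema (driver physical condition, road
    surface, safety equipment, weather, light, severity).  CPT values are
    chosen for plausibility only (e.g. fatal risk rises with DUI, snow, and
    no seatbelt) and are not estimates from any dataset.
    """
    variables = (
        Variable("weather", ("clear", "rain", "snowfall")),
        Variable("light", ("day", "dark")),
        Variable("physical_condition", ("normal", "fatigued", "dui")),
        Variable("surface", ("dry", "wet", "snow")),
        Variable("safety_equipment", ("belt", "none")),
        Variable("severity", ("damage", "injury", "fatal")),
    )
    edges = (
        ("weather", "surface"),
        ("weather", "light"),
        ("physical_condition", "severity"),
        ("surface", "severity"),
        ("safety_equipment", "severity"),
    )
    structure = NetworkStructure(variables, edges)
    tables = {
        "weather": ConditionalTable(
            "weather", (), {(): {"clear": 0.7, "rain": 0.2, "snowfall": 0.1}}
        ),
        "light": ConditionalTable(
            "light",
            ("weather",),
            {
                ("clear",): {"day": 0.65, "dark": 0.35},
                ("rain",): {"day": 0.55, "dark": 0.45},
                ("snowfall",): {"day": 0.5, "dark": 0.5},
            },
        ),
        "physical_condition": ConditionalTable(
            "physical_condition",
            (),
            {(): {"normal": 0.88, "fatigued": 0.08, "dui": 0.04}},
        ),
        "surface": ConditionalTable(
            "surface",
            ("weather",),
            {
                ("clear",): {"dry": 0.9, "wet": 0.08, "snow": 0.02},
                ("rain",): {"dry": 0.1, "wet": 0.85, "snow": 0.05},
                ("snowfall",): {"dry": 0.05, "wet": 0.25, "snow": 0.7},
            },
        ),
        "safety_equipment": ConditionalTable(
            "safety_equipment", (), {(): {"belt": 0.92, "none": 0.08}}
        ),
    }
    base = {"damage": 0.82, "injury": 0.17, "fatal": 0.01}
    phys_hazard = {"normal": 1.0, "fatigued": 1.8, "dui": 3.0}
    surf_hazard = {"dry": 1.0, "wet": 1.4, "snow": 2.0}
    belt_hazard = {"belt": 1.0, "none": 6.0}
    sev_parents = ("physical_condition", "surface", "safety_equipment")
    rows = {}
    for cfg in parent_configurations(sev_parents, structure):
        phys, surf, belt = cfg
        hazard = phys_hazard[phys] * surf_hazard[surf] * belt_hazard[belt]
        rows[cfg] = _monotone_severity_row(base, hazard)
    tables["severity"] = ConditionalTable("severity", sev_parents, rows)
    return DiscreteNetwork(structure, tables)


def health_schema() -> DiscreteNetwork:
    """Invented, plausible health-survey-like fixture network.

    Emulates the shape of a behavioral risk-factor survey (age band, BMI
    band, physical activity, binary disease outcome); CPT values are chosen
    for plausibility only and are not estimates from any survey.
    """
    variables = (
        Variable("age_band", ("18_44", "45_64", "65_plus")),
        Variable("bmi_band", ("normal", "overweight", "obese")),
        Variable("activity", ("active", "inactive")),
        Variable("outcome", ("no_diabetes", "diabetes")),
    )
    edges = (
        ("age_band", "bmi_band"),
        ("age_band", "outcome"),
        ("bmi_band", "outcome"),
        ("activity", "outcome"),
    )
    structure = NetworkStructure(variables, edges)
    tables = {
        "age_band": ConditionalTable(
            "age_band", (), {(): {"18_44": 0.45, "45_64": 0.35, "65_plus": 0.2}}
        ),
        "bmi_band": ConditionalTable(
            "bmi_band",
            ("age_band",),
            {
                ("18_44",): {"normal": 0.45, "overweight": 0.33, "obese": 0.22},
                ("45_64",): {"normal": 0.3, "overweight": 0.38, "obese": 0.32},
                ("65_plus",): {"normal": 0.32, "overweight": 0.4, "obese": 0.28},
            },
        ),
        "activity": ConditionalTable(
            "activity", (), {(): {"active": 0.72, "inactive": 0.28}}
        ),
    }
    age_or = {"18_44": 1.0, "45_64": 2.5, "65_plus": 4.0}
    bmi_or = {"normal": 1.0, "overweight": 1.8, "obese": 3.5}
    act_or = {"active": 1.0, "inactive": 1.6}
    base_odds = 0.03 / 0.97
    rows = {}
    out_parents = ("age_band", "bmi_band", "activity")
    for cfg in parent_configurations(out_parents, structure):
        age, bmi, act = cfg
        odds = base_odds * age_or[age] * bmi_or[bmi] * act_or[act]
        p = odds / (1 + odds)
        rows[cfg] = {"no_diabetes": 1 - p, "diabetes": p}
    tables["outcome"] = ConditionalTable("outcome", out_parents, rows)
    return DiscreteNetwork(structure, tables)
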