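"""Nonlinear interaction quantification for categorical risk factors.

Given an outcome (e.g. fatal crash severity) and a set of risk factors each
with a *reference* level (the normal state) and a *risk* level (the exposure),
the framework compares two deltas relative to the baseline risk — the risk
with every factor at its reference level, under any fixed context evidence:

* the **additive delta**: the sum of the single-factor deltas, i.e. the
  prediction of a linear, no-interaction model;
* the **combined delta**: the risk with every factor simultaneously at its
  risk level, minus the baseline.

Their ratio is the **nonlinear effect factor**

    gamma = combined delta / additive delta

gamma > 1 means the joint exposure amplifies risk beyond the additive
prediction (synergy); gamma < 1 means attenuation; gamma = 1 is exactly
linear.  When the additive delta is (numerically) zero but the combined delta
is not, gamma is unbounded: the interaction is *pure synergy* and is reported
as a categorical marker, never a number.  The percent excess (gamma - 1) x 100
expresses the amplification as a percentage of the additive prediction.

Risks may be read from a fitted discrete Bayesian network (posterior queries)
or directly from a :class:`RiskTable` mapping factor configurations to
outcome risk values.  Because gamma is a ratio of deltas it is invariant to
the risk scale: probabilities, percentages, or rates per exposure all yield
the same gamma, so tables on any consistent nonnegative scale are accepted
as-is and the scale is only recorded as a note.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence, Union

from .inference import ve_posterior
from .network import Assignment, DiscreteNetwork, NetworkError

#: default numeric-zero threshold for the pure-synergy test (on the risk scale)
DEFAULT_EPSILON = 1e-12
#: default tolerance around gamma = 1 for classification
DEFAULT_TOL = 1e-6
#: internal consistency bound for the reconstruction identity
IDENTITY_TOL = 1e-9


class ScenarioError(NetworkError):
    """Inconsistent scenario or missing risk-table configuration."""


class _PureSynergy:
    """Marker for an unbounded nonlinear effect factor (additive delta = 0)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "PURE_SYNERGY"


PURE_SYNERGY = _PureSynergy()

GammaLike = Union[float, _PureSynergy]


@dataclass(frozen=True)
class RiskFactorSpec:
    """One factor: its variable, reference (normal) level and risk level."""

    variable: str
    reference: str
    risk: str

    def __post_init__(self) -> None:
        if self.reference == self.risk:
            raise ScenarioError(
                f"factor {self.variable!r}: reference and risk levels are "
                f"both {self.risk!r}"
            )


@dataclass
class Scenario:
    """An outcome of interest plus >=2 risk factors and optional fixed context."""

    outcome: str
    outcome_level: str
    factors: tuple[RiskFactorSpec, ...]
    context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        names = [f.variable for f in self.factors]
        if len(set(names)) != len(names):
            raise ScenarioError(f"duplicate factor variables in {names}")
        if self.outcome in names or self.outcome in self.context:
            raise ScenarioError(
                f"outcome {self.outcome!r} may not appear among the factors or context"
            )
        overlap = set(names) & set(self.context)
        if overlap:
            raise ScenarioError(f"factors {sorted(overlap)} also appear in context")

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def config(self, at_risk: Sequence[int]) -> dict[str, str]:
        """Factor assignment with the given factor indices at risk level."""
        at = set(at_risk)
        return {
            f.variable: (f.risk if i in at else f.reference)
            for i, f in enumerate(self.factors)
        }


@dataclass
class RiskTable:
    """Direct mapping from factor configurations to outcome risk values.

    ``values`` maps a tuple of factor levels (ordered as ``factors``) to a
    nonnegative risk on any consistent scale.  The table must contain at
    least the baseline, every single-risk configuration, and the all-risk
    configuration for the scenarios it is queried with.
    """

    outcome: str
    outcome_level: str
    factors: tuple[RiskFactorSpec, ...]
    values: dict[tuple[str, ...], float]
    scale_note: str = ""

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.values = {tuple(k): float(v) for k, v in self.values.items()}
        for cfg, v in self.values.items():
            if len(cfg) != len(self.factors):
                raise ScenarioError(
                    f"configuration {cfg} does not match the {len(self.factors)} "
                    "declared factors"
                )
            if v < 0:
                raise ScenarioError(f"negative risk value {v} for {cfg}")

    def scenario(self) -> Scenario:
        """The scenario implied by the table's own factor specs."""
        return Scenario(self.outcome, self.outcome_level, self.factors)

    def lookup(self, assignment: Assignment) -> float:
        cfg = tuple(assignment[f.variable] for f in self.factors)
        try:
            return self.values[cfg]
        except KeyError:
            named = {f.variable: lv for f, lv in zip(self.factors, cfg)}
            raise ScenarioError(
                f"risk table has no value for configuration {named}"
            ) from None


Source = Union[DiscreteNetwork, RiskTable]


def _risk(source: Source, scenario: Scenario, factor_config: Assignment) -> float:
    """Outcome risk for one factor configuration under the fixed context."""
    if isinstance(source, RiskTable):
        if source.outcome != scenario.outcome or source.outcome_level != scenario.outcome_level:
            raise ScenarioError(
                f"risk table is for {source.outcome!r}={source.outcome_level!r}, "
                f"scenario asks for {scenario.outcome!r}={scenario.outcome_level!r}"
            )
        return source.lookup(factor_config)
    evidence = {**scenario.context, **factor_config}
    post = ve_posterior(source, scenario.outcome, evidence)
    return post[scenario.outcome_level]


def baseline_risk(source: Source, scenario: Scenario) -> float:
    """Risk of the normal situation: every factor at its reference level."""
    return _risk(source, scenario, scenario.config([]))


def single_factor_delta(source: Source, scenario: Scenario, i: int) -> float:
    """Delta of factor ``i`` alone: risk(i at risk, others at reference) - baseline.

    May be negative for a protective exposure.
    """
    if not 0 <= i < scenario.n_factors:
        raise ScenarioError(f"factor index {i} out of range")
    return _risk(source, scenario, scenario.config([i])) - baseline_risk(source, scenario)


def additive_effect(deltas: Sequence[float]) -> float:
    """Linear no-interaction prediction: the sum of single-factor deltas."""
    if len(deltas) == 0:
        raise ScenarioError("additive effect of an empty delta list is undefined")
    return float(sum(deltas))


def combined_effect(source: Source, scenario: Scenario) -> float:
    """Delta of the joint exposure: risk(all factors at risk) - baseline."""
    all_idx = range(scenario.n_factors)
    return _risk(source, scenario, scenario.config(all_idx)) - baseline_risk(
        source, scenario
    )


def nonlinear_effect_factor(
    combined: float, additive: float, epsilon: float = DEFAULT_EPSILON
) -> GammaLike:
    """gamma = combined / additive, with the degenerate cases made explicit.

    * |additive| <= epsilon and |combined| > epsilon: the additive model
      predicts no effect but a joint effect exists — pure synergy, gamma is
      unbounded and the :data:`PURE_SYNERGY` marker is returned.
    * both within epsilon of zero: no effect at all; gamma = 1 by convention
      (the linear identity holds trivially).
    * otherwise the finite ratio.
    """
    if epsilon <= 0:
        raise ScenarioError(f"epsilon must be positive, got {epsilon}")
    if abs(additive) <= epsilon:
        if abs(combined) <= epsilon:
            return 1.0
        return PURE_SYNERGY
    return combined / additive


def classify(gamma: GammaLike, tol: float = DEFAULT_TOL) -> str:
    """Label the interaction regime of a nonlinear effect factor.

    Returns one of ``amplification`` (gamma > 1), ``attenuation``
    (gamma < 1), ``linear`` (gamma = 1 within tol), ``pure_synergy`` (marker),
    or ``mixed_sign`` (gamma < 0: the combined and additive deltas point in
    opposite directions, so amplification/attenuation semantics do not apply).
    """
    if tol <= 0:
        raise ScenarioError(f"tol must be positive, got {tol}")
    if isinstance(gamma, _PureSynergy):
        return "pure_synergy"
    if gamma < 0:
        return "mixed_sign"
    if gamma > 1 + tol:
        return "amplification"
    if gamma < 1 - tol:
        return "attenuation"
    return "linear"


def percent_excess(gamma: GammaLike) -> float:
    """(gamma - 1) x 100: percent by which the joint effect exceeds additivity."""
    if isinstance(gamma, _PureSynergy):
        raise ScenarioError("percent excess is undefined for pure synergy")
    return (gamma - 1.0) * 100.0


@dataclass
class EffectReport:
    """All quantities of one evaluated scenario.

    ``difference`` is combined - additive (positive when the joint exposure
    exceeds the additive prediction).  ``gamma`` is None when the scenario is
    pure synergy, in which case ``pure_synergy`` is True and ``percent_excess``
    is None.  ``no_effect`` marks the both-deltas-zero case where gamma = 1 by
    convention.
    """

    scenario: Scenario
    baseline: float
    single_deltas: tuple[float, ...]
    additive: float
    combined: float
    difference: float
    gamma: float | None
    pure_synergy: bool
    no_effect: bool
    classification: str
    percent_excess: float | None
    scale_note: str = ""

    @property
    def gamma_or_marker(self) -> GammaLike:
        return PURE_SYNERGY if self.pure_synergy else self.gamma

    def to_dict(self) -> dict:
        return {
            "outcome": self.scenario.outcome,
            "outcome_level": self.scenario.outcome_level,
            "factors": [
                {"variable": f.variable, "reference": f.reference, "risk": f.risk}
                for f in self.scenario.factors
            ],
            "context": dict(self.scenario.context),
            "baseline": self.baseline,
            "single_deltas": {
                f.variable: d
                for f, d in zip(self.scenario.factors, self.single_deltas)
            },
            "additive_delta": self.additive,
            "combined_delta": self.combined,
            "difference": self.difference,
            "gamma": self.gamma,
            "pure_synergy": self.pure_synergy,
            "no_effect": self.no_effect,
            "classification": self.classification,
            "percent_excess": self.percent_excess,
            "scale_note": self.scale_note,
        }

    def to_text(self) -> str:
        """Aligned plain-text table of the report's rows."""
        rows: list[tuple[str, str]] = [
            (f"Outcome ({self.scenario.outcome} = {self.scenario.outcome_level})", ""),
            ("Baseline risk (normal situation)", f"{self.baseline:.6g}"),
        ]
        for f, d in zip(self.scenario.factors, self.single_deltas):
            rows.append((f"Delta {f.variable} ({f.reference} -> {f.risk})", f"{d:+.6g}"))
        rows += [
            ("Added factor effect (additive delta)", f"{self.additive:+.6g}"),
            ("Combined factor effect (combined delta)", f"{self.combined:+.6g}"),
            ("Difference (combined - additive)", f"{self.difference:+.6g}"),
        ]
        if self.pure_synergy:
            rows.append(("Nonlinear effect factor", "pure synergy (unbounded)"))
        else:
            rows.append(("Nonlinear effect factor", f"{self.gamma:.6g}"))
            rows.append(("Percent excess", f"{self.percent_excess:+.4g}%"))
        rows.append(("Classification", self.classification))
        if self.scale_note:
            rows.append(("Scale", self.scale_note))
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def evaluate_scenario(
    source: Source,
    scenario: Scenario | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = DEFAULT_TOL,
) -> EffectReport:
    """Full evaluation: deltas, gamma, classification, percent excess.

    ``scenario`` may be omitted for a :class:`RiskTable` source, in which
    case the table's own factor specs define it.  When gamma is finite the
    reconstruction identity gamma x additive == combined is verified to
    within 1e-9 as an internal consistency check.
    """
    if scenario is None:
        if not isinstance(source, RiskTable):
            raise ScenarioError("a scenario is required for a network source")
        scenario = source.scenario()
    if scenario.n_factors < 2:
        raise ScenarioError("a scenario requires at least two risk factors")
    if isinstance(source, DiscreteNetwork):
        for f in scenario.factors:
            var = source.variable(f.variable)
            var.index(f.reference)
            var.index(f.risk)

    base = baseline_risk(source, scenario)
    singles = tuple(
        _risk(source, scenario, scenario.config([i])) - base
        for i in range(scenario.n_factors)
    )
    additive = additive_effect(singles)
    combined = combined_effect(source, scenario)
    gamma = nonlinear_effect_factor(combined, additive, epsilon=epsilon)
    pure = isinstance(gamma, _PureSynergy)
    no_effect = abs(additive) <= epsilon and abs(combined) <= epsilon
    if not pure:
        residual = abs(gamma * additive - combined)
        scale = max(abs(combined), abs(additive), 1.0)
        if residual > IDENTITY_TOL * scale:  # pragma: no cover - arithmetic identity
            raise AssertionError(
                f"reconstruction identity violated: gamma*additive differs from "
                f"combined by {residual}"
            )
    scale_note = source.scale_note if isinstance(source, RiskTable) else "probability"
    return EffectReport(
        scenario=scenario,
        baseline=base,
        single_deltas=singles,
        additive=additive,
        combined=combined,
        difference=combined - additive,
        gamma=None if pure else float(gamma),
        pure_synergy=pure,
        no_effect=no_effect,
        classification=classify(gamma, tol=tol),
        percent_excess=None if pure else percent_excess(gamma),
        scale_note=scale_note,
    )


MAX_SUBSET_FACTORS = 12


def subset_analysis(
    source: Source,
    scenario: Scenario | None = None,
    subsets: Sequence[Sequence[int]] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = DEFAULT_TOL,
) -> list[EffectReport]:
    """Evaluate every factor subset of size >= 2 (or the given subsets).

    Unchosen factors are pinned at their reference levels (network source:
    as extra context evidence; table source: in the lookup configuration).
    Subsets are ordered by size, then lexicographically by factor index.
    """
    if scenario is None:
        if not isinstance(source, RiskTable):
            raise ScenarioError("a scenario is required for a network source")
        scenario = source.scenario()
    n = scenario.n_factors
    if subsets is None:
        if n > MAX_SUBSET_FACTORS:
            raise ScenarioError(
                f"{n} factors imply 2^{n} subsets; pass explicit `subsets`"
            )
        subsets = [
            combo
            for size in range(2, n + 1)
            for combo in itertools.combinations(range(n), size)
        ]
    reports = []
    for subset in subsets:
        subset = tuple(sorted(subset))
        if len(subset) < 2:
            raise ScenarioError(f"subset {subset} has fewer than 2 factors")
        chosen = [scenario.factors[i] for i in subset]
        pinned = {
            f.variable: f.reference
            for i, f in enumerate(scenario.factors)
            if i not in subset
        }
        if isinstance(source, RiskTable):
            sub = _restrict_table(source, subset, pinned)
            reports.append(evaluate_scenario(sub, epsilon=epsilon, tol=tol))
        else:
            sub_scenario = Scenario(
                scenario.outcome,
                scenario.outcome_level,
                tuple(chosen),
                {**scenario.context, **pinned},
            )
            reports.append(
                evaluate_scenario(source, sub_scenario, epsilon=epsilon, tol=tol)
            )
    return reports


def _restrict_table(
    table: RiskTable, subset: tuple[int, ...], pinned: dict[str, str]
) -> RiskTable:
    """Slice a risk table to a factor subset, others pinned at reference."""
    keep = [i for i in range(len(table.factors)) if i in set(subset)]
    factors = tuple(table.factors[i] for i in keep)
    values = {}
    for cfg, risk in table.values.items():
        named = {f.variable: lv for f, lv in zip(table.factors, cfg)}
        if all(named[v] == lv for v, lv in pinned.items()):
            values[tuple(cfg[i] for i in keep)] = risk
    return RiskTable(table.outcome, table.outcome_level, factors, values, table.scale_note)


def risk_table_from_network(
    net: DiscreteNetwork, scenario: Scenario, all_configs: bool = True
) -> RiskTable:
    """Export the network's posterior risks for a scenario as a risk table.

    With ``all_configs`` every factor risk/reference combination is queried
    (2^n posteriors); otherwise only the baseline, single-risk and all-risk
    configurations required by :func:`evaluate_scenario`.
    """
    n = scenario.n_factors
    if all_configs:
        index_sets: list[tuple[int, ...]] = [
            combo
            for size in range(n + 1)
            for combo in itertools.combinations(range(n), size)
        ]
    else:
        index_sets = [()] + [(i,) for i in range(n)] + [tuple(range(n))]
    values = {}
    for idx in index_sets:
        cfg = scenario.config(idx)
        key = tuple(cfg[f.variable] for f in scenario.factors)
        values[key] = _risk(net, scenario, cfg)
    return RiskTable(
        scenario.outcome,
        scenario.outcome_level,
        scenario.factors,
        values,
        scale_note="probability (network posterior)",
    )
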