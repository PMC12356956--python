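"""The interaction framework: deltas, gamma, classification, scenario reports.

The frozen expected values come from the published road-safety worked
examples shipped as fixtures (two-factor DUI/snow and three-factor
DUI/snow/no-seatbelt); comparisons are at printed precision.
"""

import itertools

import numpy as np
import pytest

from synrisk import (
    PURE_SYNERGY,
    PlantSpec,
    RiskFactorSpec,
    RiskTable,
    Scenario,
    additive_effect,
    build_planted_network,
    classify,
    combined_effect,
    evaluate_scenario,
    nonlinear_effect_factor,
    percent_excess,
    random_network,
    risk_table_from_network,
    single_factor_delta,
    subset_analysis,
)
from synrisk.effects import ScenarioError
from synrisk.fixtures import load_risk_table


@pytest.fixture(scope="module")
def table3():
    return load_risk_table("scenario_three_factor")


@pytest.fixture(scope="module")
def table1():
    return load_risk_table("scenario_two_factor")


class TestWorkedExamples:
    def test_single_factor_deltas_from_printed_risks(self, table3):
        sc = table3.scenario()
        assert single_factor_delta(table3, sc, 0) == pytest.approx(0.018)  # DUI
        assert single_factor_delta(table3, sc, 1) == pytest.approx(0.014)  # snow
        assert single_factor_delta(table3, sc, 2) == pytest.approx(4.534)  # no belt

    def test_three_factor_report(self, table3):
        r = evaluate_scenario(table3)
        assert r.baseline == pytest.approx(0.259)
        assert r.additive == pytest.approx(4.566)
        assert r.combined == pytest.approx(4.934)
        assert r.difference == pytest.approx(0.368)
        assert r.gamma == pytest.approx(1.081, abs=1e-3)
        # printed 8.1% is rounded; exact arithmetic on the printed deltas
        # gives 8.06%
        assert r.percent_excess == pytest.approx(8.06, abs=0.01)
        assert r.classification == "amplification"

    def test_two_factor_delta_scale_report(self, table1):
        r = evaluate_scenario(table1)
        assert r.single_deltas == pytest.approx((0.895, 0.018))
        assert r.additive == pytest.approx(0.913)
        assert r.combined == pytest.approx(0.997)
        assert r.gamma == pytest.approx(1.092, abs=1e-3)
        assert r.percent_excess == pytest.approx(9.2, abs=0.05)

    def test_with_belt_subset(self, table3):
        [r] = subset_analysis(table3, subsets=[(0, 1)])
        assert r.additive == pytest.approx(0.032)
        assert r.combined == pytest.approx(0.038)
        assert r.gamma == pytest.approx(0.038 / 0.032)
        assert r.percent_excess == pytest.approx(18.7, abs=0.1)

    def test_reconstruction_identities_hold(self, table1, table3):
        for r in (evaluate_scenario(table1), evaluate_scenario(table3)):
            assert r.gamma * r.additive == pytest.approx(r.combined, abs=1e-9)


def two_factor_table(baseline, r1, r2, both):
    factors = (
        RiskFactorSpec("f1", "ref", "risk"),
        RiskFactorSpec("f2", "ref", "risk"),
    )
    return RiskTable(
        "out",
        "bad",
        factors,
        {
            ("ref", "ref"): baseline,
            ("risk", "ref"): r1,
            ("ref", "risk"): r2,
            ("risk", "risk"): both,
        },
    )


def test_zero_delta_when_risk_equals_reference_value():
    table = two_factor_table(0.2, 0.2, 0.3, 0.3)
    assert single_factor_delta(table, table.scenario(), 0) == 0.0


def test_missing_configuration_error_names_it():
    table = two_factor_table(0.2, 0.3, 0.3, 0.5)
    del table.values[("risk", "risk")]
    with pytest.raises(ScenarioError, match="'f1': 'risk'.*'f2': 'risk'"):
        combined_effect(table, table.scenario())


def test_additive_effect_sums_and_rejects_empty():
    assert additive_effect([0.018, 0.014, 4.534]) == pytest.approx(4.566)
    assert additive_effect([0.02, -0.02]) == pytest.approx(0.0)
    with pytest.raises(ScenarioError):
        additive_effect([])


class TestGammaAndClassification:
    def test_finite_ratio(self):
        assert nonlinear_effect_factor(0.997, 0.913) == pytest.approx(1.092, abs=1e-3)

    def test_pure_synergy_marker(self):
        assert nonlinear_effect_factor(0.05, 0.0) is PURE_SYNERGY

    def test_both_zero_is_linear_by_convention(self):
        assert nonlinear_effect_factor(0.0, 0.0) == 1.0

    @pytest.mark.parametrize(
        "gamma, label",
        [
            (1.081, "amplification"),
            (1.0, "linear"),
            (0.8, "attenuation"),
            (PURE_SYNERGY, "pure_synergy"),
            (-0.5, "mixed_sign"),
        ],
    )
    def test_classify(self, gamma, label):
        assert classify(gamma) == label

    def test_percent_excess_values_and_marker_error(self):
        assert percent_excess(1.092) == pytest.approx(9.2)
        assert percent_excess(1.0) == 0.0
        with pytest.raises(ScenarioError, match="pure synergy"):
            percent_excess(PURE_SYNERGY)


class TestScenarioValidation:
    def test_reference_equals_risk_rejected(self):
        with pytest.raises(ScenarioError, match="reference and risk"):
            RiskFactorSpec("f", "same", "same")

    def test_outcome_among_factors_rejected(self):
        with pytest.raises(ScenarioError, match="outcome"):
            Scenario(
                "f1",
                "bad",
                (RiskFactorSpec("f1", "a", "b"), RiskFactorSpec("f2", "a", "b")),
            )

    def test_duplicate_factors_rejected(self):
        with pytest.raises(ScenarioError, match="duplicate"):
            Scenario("out", "bad", (RiskFactorSpec("f", "a", "b"),) * 2)

    def test_fewer_than_two_factors_rejected(self):
        table = two_factor_table(0.1, 0.2, 0.3, 0.4)
        one = Scenario("out", "bad", (RiskFactorSpec("f1", "ref", "risk"),))
        with pytest.raises(ScenarioError, match="at least two"):
            evaluate_scenario(table, one)


class TestInvariants:
    @pytest.mark.parametrize("c", [0.01, 1.0, 7.3, 100.0])
    def test_scale_invariance(self, table3, c):
        scaled = RiskTable(
            table3.outcome,
            table3.outcome_level,
            table3.factors,
            {cfg: v * c for cfg, v in table3.values.items()},
        )
        a, b = evaluate_scenario(table3), evaluate_scenario(scaled)
        assert b.gamma == pytest.approx(a.gamma, abs=1e-12)
        assert b.classification == a.classification
        assert b.percent_excess == pytest.approx(a.percent_excess, abs=1e-9)
        assert b.additive == pytest.approx(a.additive * c)

    def test_additivity_null_gives_gamma_one(self):
        spec = PlantSpec(p0=0.1, deltas=(0.07, 0.03, 0.05), gamma=1.0)
        r = evaluate_scenario(build_planted_network(spec), spec.scenario())
        assert r.gamma == pytest.approx(1.0, abs=1e-9)
        assert r.classification == "linear"

    def test_network_and_exported_table_agree_exactly(self):
        spec = PlantSpec(p0=0.12, deltas=(0.06, 0.04), gamma=1.7,
                         prevalences=(0.3, 0.2))
        net = build_planted_network(spec)
        sc = spec.scenario()
        table = risk_table_from_network(net, sc)
        rn, rt = evaluate_scenario(net, sc), evaluate_scenario(table, sc)
        assert rt.baseline == rn.baseline
        assert rt.single_deltas == rn.single_deltas
        assert rt.combined == rn.combined
        assert rt.gamma == rn.gamma

    def test_factor_order_invariance(self, table3):
        base = evaluate_scenario(table3)
        for perm in itertools.permutations(range(3)):
            factors = tuple(table3.factors[i] for i in perm)
            permuted = RiskTable(
                table3.outcome,
                table3.outcome_level,
                factors,
                {
                    tuple(cfg[i] for i in perm): v
                    for cfg, v in table3.values.items()
                },
                table3.scale_note,
            )
            r = evaluate_scenario(permuted)
            assert r.gamma == pytest.approx(base.gamma, abs=1e-12)
            assert sorted(r.single_deltas) == pytest.approx(sorted(base.single_deltas))
            assert r.combined == pytest.approx(base.combined, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction_identity_on_random_networks(self, seed):
        rng = np.random.default_rng(200 + seed)
        gamma = float(rng.uniform(0.5, 2.5))
        deltas = tuple(rng.uniform(0.01, 0.08, size=int(rng.integers(2, 5))))
        if 0.1 + gamma * sum(deltas) >= 1:
            deltas = tuple(d / 2 for d in deltas)
        spec = PlantSpec(p0=0.1, deltas=deltas, gamma=gamma)
        r = evaluate_scenario(build_planted_network(spec), spec.scenario())
        assert r.gamma * r.additive == pytest.approx(r.combined, abs=1e-9)


class TestSubsets:
    def test_subset_count_and_order(self):
        spec = PlantSpec(p0=0.1, deltas=(0.05, 0.04, 0.03), gamma=1.2)
        net = build_planted_network(spec)
        reports = subset_analysis(net, spec.scenario())
        assert len(reports) == 4  # {0,1},{0,2},{1,2},{0,1,2}
        sizes = [r.scenario.n_factors for r in reports]
        assert sizes == [2, 2, 2, 3]
        # every proper subset of a uniformly planted network also has gamma*
        for r in reports:
            assert r.gamma == pytest.approx(1.2, abs=1e-9)

    def test_two_factor_scenario_yields_single_report(self, table1):
        reports = subset_analysis(table1)
        assert len(reports) == 1
        assert reports[0].gamma == pytest.approx(1.092, abs=1e-3)

    def test_guard_against_exponential_subsets(self):
        factors = tuple(RiskFactorSpec(f"f{i}", "a", "b") for i in range(13))
        sc = Scenario("out", "bad", factors)
        table = RiskTable("out", "bad", factors, {})
        with pytest.raises(ScenarioError, match="subsets"):
            subset_analysis(table, sc)


def test_mixed_sign_scenario_is_labelled():
    # one protective, one harmful factor: additive negative, combined positive
    table = two_factor_table(0.5, 0.1, 0.55, 0.8)
    r = evaluate_scenario(table)
    assert r.additive < 0 < r.combined
    assert r.gamma < 0
    assert r.classification == "mixed_sign"


def test_pure_synergy_scenario_report():
    table = two_factor_table(0.2, 0.2, 0.2, 0.6)
    r = evaluate_scenario(table)
    assert r.pure_synergy and r.gamma is None and r.percent_excess is None
    assert r.classification == "pure_synergy"


def test_report_text_contains_headline_rows(table3):
    text = evaluate_scenario(table3).to_text()
    for needle in ("Baseline", "Added factor effect", "Combined factor effect",
                   "Nonlinear effect factor", "Percent excess"):
        assert needle in text
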