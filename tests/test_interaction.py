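"""Observed vs multiplicatively-expected accuracy, relative risks and the
interaction significance test."""
import math

import numpy as np
import pandas as pd
import pytest

from rulenet import (
    Condition,
    DecisionTable,
    RuleSet,
    expected_accuracy,
    observed_accuracy,
    outcome_network,
    rank_and_test,
    relative_risk,
)
from rulenet import test_interaction as interaction_test
from rulenet.interaction import format_bound

from conftest import make_rule


def table_from_counts(counts: dict[tuple[str, str, str], int]) -> DecisionTable:
    """Build a table from exact cell counts keyed by (x, y, d)."""
    rows = []
    for (x, y, d), n in counts.items():
        rows.extend([{"x": x, "y": y, "d": d}] * n)
    return DecisionTable(pd.DataFrame(rows), "d")


@pytest.fixture
def exact_multiplicative_table() -> DecisionTable:
    """Cell counts engineered so effects combine exactly multiplicatively:
    P(d=1) = 0.5, P(d=1|x=1) = 0.6, P(d=1|y=1) = 0.7,
    and P(d=1|x=1,y=1) = 0.5 * 1.2 * 1.4 = 0.84.
    Construction: 1000 objects, x and y independent fair coins, and within
    each (x, y) cell P(d=1) = 0.5 * (1.2 if x else 0.8) * (1.4 if y else 0.6).
    """
    counts = {}
    for x in ("0", "1"):
        for y in ("0", "1"):
            n_cell = 250
            p = 0.5 * (1.2 if x == "1" else 0.8) * (1.4 if y == "1" else 0.6)
            k = round(n_cell * p)
            counts[(x, y, "1")] = k
            counts[(x, y, "0")] = n_cell - k
    return table_from_counts(counts)


class TestObservedAccuracy:
    def test_row_scan_on_toy_counts(self):
        t = table_from_counts(
            {("1", "1", "1"): 3, ("1", "1", "0"): 1, ("0", "0", "1"): 2, ("0", "0", "0"): 4}
        )
        acc, m = observed_accuracy(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert acc == pytest.approx(0.75)
        assert (m.a, m.b, m.c, m.d) == (3, 1, 2, 4)

    def test_conditions_covering_all_rows_give_prevalence(self, exact_multiplicative_table):
        t = exact_multiplicative_table
        # "x is 0 or 1" cannot be expressed; use a constant helper column
        df = t.df.assign(const="1")
        t2 = DecisionTable(df[["x", "y", "const", "d"]], "d")
        acc, _ = observed_accuracy(t2, [Condition("const", "1")], "1")
        assert acc == pytest.approx((t.df.d == "1").mean())

    def test_no_supporting_objects_is_error(self, exact_multiplicative_table):
        with pytest.raises(ValueError, match="no supporting objects"):
            observed_accuracy(
                exact_multiplicative_table, [Condition("x", "7")], "1"
            )


class TestExpectedAccuracy:
    def test_multiplicative_combination_of_effects(self, exact_multiplicative_table):
        exp = expected_accuracy(
            exact_multiplicative_table,
            [Condition("x", "1"), Condition("y", "1")],
            "1",
        )
        assert exp == pytest.approx(0.84, abs=1e-12)

    def test_single_condition_expected_equals_observed(self, exact_multiplicative_table):
        conds = [Condition("x", "1")]
        obs, _ = observed_accuracy(exact_multiplicative_table, conds, "1")
        exp = expected_accuracy(exact_multiplicative_table, conds, "1")
        assert exp == pytest.approx(obs)

    def test_expected_capped_at_one(self):
        # strong individual effects whose product would exceed 1
        counts = {
            ("1", "1", "1"): 50, ("1", "1", "0"): 1,
            ("1", "0", "1"): 45, ("1", "0", "0"): 5,
            ("0", "1", "1"): 45, ("0", "1", "0"): 5,
            ("0", "0", "1"): 5, ("0", "0", "0"): 45,
        }
        t = table_from_counts(counts)
        exp = expected_accuracy(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert exp == 1.0

    def test_observed_matches_expected_when_construction_is_multiplicative(
        self, exact_multiplicative_table
    ):
        conds = [Condition("x", "1"), Condition("y", "1")]
        obs, _ = observed_accuracy(exact_multiplicative_table, conds, "1")
        exp = expected_accuracy(exact_multiplicative_table, conds, "1")
        assert obs == pytest.approx(exp, abs=0.005)  # rounding to whole objects


class TestRelativeRisk:
    def test_standard_log_formula(self):
        # a=30 b=10 c=50 d=110: RR = 0.75/0.3125 = 2.4
        counts = {
            ("1", "1", "1"): 30, ("1", "1", "0"): 10,
            ("0", "0", "1"): 50, ("0", "0", "0"): 110,
        }
        t = table_from_counts(counts)
        rr = relative_risk(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert rr.rr == pytest.approx(2.4)
        se = math.sqrt(1 / 30 - 1 / 40 + 1 / 50 - 1 / 160)
        assert rr.ci_low == pytest.approx(2.4 * math.exp(-1.959963984540054 * se))
        assert rr.ci_high == pytest.approx(2.4 * math.exp(1.959963984540054 * se))
        assert (1.79, 3.21) == (round(rr.ci_low, 2), round(rr.ci_high, 2))

    def test_zero_unexposed_cases_gives_infinite_rr(self):
        counts = {
            ("1", "1", "1"): 10, ("1", "1", "0"): 5,
            ("0", "0", "1"): 0, ("0", "0", "0"): 20,
        }
        t = table_from_counts(counts)
        rr = relative_risk(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert math.isinf(rr.rr)
        assert format_bound(rr.ci_high) == "*"

    def test_null_proportions_give_rr_one(self):
        counts = {
            ("1", "1", "1"): 20, ("1", "1", "0"): 20,
            ("0", "0", "1"): 30, ("0", "0", "0"): 30,
        }
        t = table_from_counts(counts)
        rr = relative_risk(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert rr.rr == pytest.approx(1.0)
        assert rr.ci_low < 1.0 < rr.ci_high


class TestInteractionTest:
    def test_pure_xor_interaction_is_significant(self):
        rng = np.random.default_rng(71)
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        df = pd.DataFrame({"x": a, "y": b, "d": a ^ b}).astype(str)
        t = DecisionTable(df, "d")
        res = interaction_test(t, [Condition("x", "1"), Condition("y", "0")], "1")
        assert res.observed_accuracy == 1.0
        # no marginal effects: expectation stays near prevalence
        assert res.expected_accuracy < 0.6
        assert res.significant

    def test_multiplicative_construction_not_significant(self, exact_multiplicative_table):
        res = interaction_test(
            exact_multiplicative_table,
            [Condition("x", "1"), Condition("y", "1")],
            "1",
        )
        assert not res.significant

    def test_observed_below_expected_is_rejected(self):
        # joint accuracy well under the multiplicative prediction
        counts = {
            ("1", "1", "1"): 10, ("1", "1", "0"): 40,
            ("1", "0", "1"): 40, ("1", "0", "0"): 10,
            ("0", "1", "1"): 40, ("0", "1", "0"): 10,
            ("0", "0", "1"): 10, ("0", "0", "0"): 40,
        }
        t = table_from_counts(counts)
        res = interaction_test(t, [Condition("x", "1"), Condition("y", "1")], "1")
        assert res.observed_accuracy < res.expected_accuracy
        assert not res.significant

    def test_three_way_interaction_supported(self):
        rng = np.random.default_rng(73)
        x = rng.integers(0, 2, 2000)
        y = rng.integers(0, 2, 2000)
        z = rng.integers(0, 2, 2000)
        d = (x ^ y ^ z).astype(int)
        df = pd.DataFrame({"x": x, "y": y, "z": z, "d": d}).astype(str)
        t = DecisionTable(df, "d")
        res = interaction_test(
            t,
            [Condition("x", "1"), Condition("y", "1"), Condition("z", "1")],
            "1",
        )
        assert res.observed_accuracy == 1.0 and res.significant

    def test_fewer_than_two_conditions_rejected(self, exact_multiplicative_table):
        with pytest.raises(ValueError, match="two conditions"):
            interaction_test(exact_multiplicative_table, [Condition("x", "1")], "1")


class TestRankAndTest:
    def make_network_and_table(self):
        rng = np.random.default_rng(79)
        a = rng.integers(0, 2, 400)
        b = rng.integers(0, 2, 400)
        c = rng.integers(0, 2, 400)
        df = pd.DataFrame({"x": a, "y": b, "z": c, "d": a ^ b}).astype(str)
        t = DecisionTable(df, "d")
        from rulenet import InductionConfig, induce_rules

        rs = induce_rules(t, InductionConfig(max_len=2))
        return outcome_network(rs, "1"), t

    def test_top_n_rows_in_score_order(self):
        net, t = self.make_network_and_table()
        rows = rank_and_test(net, t, top_n=3)
        assert len(rows) == min(3, len(net.edges))
        assert [r.score for r in rows] == sorted((r.score for r in rows), reverse=True)

    def test_xor_edges_detected_as_interactions(self):
        net, t = self.make_network_and_table()
        rows = rank_and_test(net, t, top_n=4)
        xor_rows = [
            r for r in rows
            if {c.feature for c in r.conditions} == {"x", "y"}
        ]
        assert xor_rows and all(r.test.significant for r in xor_rows)

    def test_failing_edge_reports_error_while_others_proceed(self, worked_rules):
        # the worked rules reference conditions absent from this table
        df = pd.DataFrame({"a": ["1", "1"], "b": ["1", "1"], "c": ["1", "0"],
                           "d": ["0", "1"]})
        t = DecisionTable(df, "d")
        net = outcome_network(worked_rules, "0")
        rows = rank_and_test(net, t, top_n=10)
        assert any(r.error for r in rows)


def test_format_bound_renders_infinities_as_asterisk():
    assert format_bound(math.inf) == "*"
    assert format_bound(0.0) == "*"
    assert format_bound(2.4) == "2.4"
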