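"""Discretization, the conjunction-enumeration learner, voting and CV."""
import itertools

import numpy as np
import pandas as pd
import pytest

from rulenet import (
    Condition,
    DecisionTable,
    InductionConfig,
    RuleSet,
    classify,
    classify_table,
    cross_validate,
    discretize_decision,
    equal_frequency_binning,
    induce_rules,
)
from rulenet.induction import UNCLASSIFIED_FALLBACK

from conftest import make_rule, random_table


class TestEqualFrequencyBinning:
    def test_four_bins_on_1_to_8(self):
        cuts, labels = equal_frequency_binning(np.arange(1, 9), 4)
        assert cuts == [3, 5, 7]
        # bins of size 2 each
        assert list(labels) == ["[*,3)", "[*,3)", "[3,5)", "[3,5)",
                                "[5,7)", "[5,7)", "[7,*)", "[7,*)"]

    def test_median_cut_labels(self):
        cuts, labels = equal_frequency_binning([1, 2, 3, 4], 2)
        assert cuts == [3]
        assert list(labels) == ["[*,3)", "[*,3)", "[3,*)", "[3,*)"]

    def test_constant_column_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="distinct bin"):
            cuts, labels = equal_frequency_binning([5.0] * 10, 4)
        assert cuts == [] and set(labels) == {"[*,*)"}

    def test_non_numeric_is_error(self):
        with pytest.raises(ValueError):
            equal_frequency_binning(np.array([1.0, np.nan, 2.0]), 2)


class TestDiscretizeDecision:
    def test_value_at_upper_cut_gets_top_label(self):
        out = discretize_decision([100000, 200000, 500000], [173601, 500000])
        assert list(out) == ["0", "1", "2"]

    def test_boundary_goes_to_upper_interval(self):
        out = discretize_decision([173600, 173601], [173601])
        assert list(out) == ["0", "1"]

    def test_empty_cuts_single_label(self):
        assert list(discretize_decision([1, 2, 3], [])) == ["0", "0", "0"]

    def test_non_increasing_cuts_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize_decision([1], [5, 5])

    def test_out_of_bounds_value_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            discretize_decision([600000], [173601], bounds=(0, 500000))


class TestInduceRules:
    def test_xor_needs_two_conditions(self, xor_table):
        cfg = InductionConfig(max_len=2, min_support=2, min_accuracy=0.6)
        rs = induce_rules(xor_table, cfg)
        assert all(len(r.lhs) == 2 for r in rs)
        exact = [r for r in rs if r.accuracy == 1.0]
        assert len(exact) == 4  # the four (a,b) cells
        for r in exact:
            a = next(c.value for c in r.lhs if c.feature == "a")
            b = next(c.value for c in r.lhs if c.feature == "b")
            assert r.outcome.value == str(int(a) ^ int(b))

    def test_min_support_above_n_gives_empty_ruleset(self, toy_table):
        rs = induce_rules(toy_table, InductionConfig(min_support=99))
        assert len(rs) == 0

    def test_fully_predictive_single_feature(self):
        df = pd.DataFrame({"a": ["0", "1"] * 10, "d": ["x", "y"] * 10})
        rs = induce_rules(DecisionTable(df, "d"), InductionConfig(max_len=1))
        assert {(r.sorted_lhs[0].value, r.outcome.value, r.accuracy) for r in rs} == {
            ("0", "x", 1.0),
            ("1", "y", 1.0),
        }

    def test_continuous_column_is_rejected_upfront(self):
        # plenty of distinct numeric values = almost surely undiscretized
        df = pd.DataFrame({"a": [str(v) for v in np.linspace(0, 1, 60)],
                           "d": ["0", "1"] * 30})
        with pytest.raises(ValueError, match="discretiz"):
            induce_rules(DecisionTable(df, "d"))

    def test_matches_brute_force_enumeration_without_pruning(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            table = random_table(rng, n_rows=int(rng.integers(10, 64)),
                                 n_features=int(rng.integers(2, 6)), n_values=2)
            cfg = InductionConfig(max_len=2, min_support=2, min_accuracy=0.5, prune=None)
            got = {
                (r.lhs, r.outcome.value, r.support, round(r.accuracy, 12))
                for r in induce_rules(table, cfg)
            }
            expected = set()
            rows = table.df.to_dict("records")
            classes = sorted(table.df["d"].unique())
            for length in (1, 2):
                for feats in itertools.combinations(sorted(table.features), length):
                    valsets = [sorted(table.df[f].unique()) for f in feats]
                    for combo in itertools.product(*valsets):
                        match = [r for r in rows
                                 if all(r[f] == v for f, v in zip(feats, combo))]
                        if len(match) < 2:
                            continue
                        for cls in classes:
                            k = sum(r["d"] == cls for r in match)
                            acc = k / len(match)
                            if acc >= 0.5:
                                lhs = frozenset(
                                    Condition(f, v) for f, v in zip(feats, combo)
                                )
                                expected.add((lhs, cls, len(match), round(acc, 12)))
            assert got == expected

    def test_significance_pruning_drops_uninformative_specializations(self):
        # d copies feature a; conjoining the noise feature b cannot improve
        # on the sub-rule {a} and every (a, b) rule must be pruned
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 200)
        df = pd.DataFrame({"a": a, "b": rng.integers(0, 2, 200), "d": a}).astype(str)
        rs = induce_rules(DecisionTable(df, "d"), InductionConfig(max_len=2))
        assert len(rs) > 0
        assert all(r.features == {"a"} for r in rs)

    def test_deterministic_output_order(self, xor_table):
        a = induce_rules(xor_table, InductionConfig(max_len=2))
        b = induce_rules(xor_table, InductionConfig(max_len=2))
        assert [(r.id, r.lhs, r.outcome) for r in a] == [(r.id, r.lhs, r.outcome) for r in b]


class TestClassify:
    def test_single_firing_rule_wins(self):
        rs = RuleSet([make_rule({"a": "1"}, ("d", "0"), 5, 1.0, "r1")], "d")
        pred, votes, flag = classify(rs, {"a": "1"})
        assert pred == "0" and flag is None and votes["0"] == 5.0

    def test_votes_are_support_times_accuracy(self):
        rs = RuleSet(
            [
                make_rule({"a": "1"}, ("d", "0"), 10, 0.8, "r1"),
                make_rule({"b": "0"}, ("d", "1"), 5, 1.0, "r2"),
            ],
            "d",
        )
        pred, votes, _ = classify(rs, {"a": "1", "b": "0"})
        assert votes == {"0": 8.0, "1": 5.0}
        assert pred == "0"

    def test_no_firing_rule_falls_back_with_flag(self):
        rs = RuleSet([make_rule({"a": "1"}, ("d", "0"), 5, 1.0, "r1")], "d")
        pred, _, flag = classify(rs, {"a": "0"}, priors={"0": 0.4, "1": 0.6})
        assert pred == "1" and flag == UNCLASSIFIED_FALLBACK

    def test_tie_broken_by_larger_prior(self):
        rs = RuleSet(
            [
                make_rule({"a": "1"}, ("d", "0"), 4, 1.0, "r1"),
                make_rule({"b": "0"}, ("d", "1"), 4, 1.0, "r2"),
            ],
            "d",
        )
        obj = {"a": "1", "b": "0"}
        assert classify(rs, obj, priors={"0": 0.3, "1": 0.7})[0] == "1"
        assert classify(rs, obj, priors={"0": 0.7, "1": 0.3})[0] == "0"

    def test_rule_order_does_not_change_predictions(self, xor_table):
        rs = induce_rules(xor_table, InductionConfig(max_len=2, prune=None))
        rev = RuleSet(list(rs)[::-1], rs.decision_feature)
        p1, _, _ = classify_table(rs, xor_table)
        p2, _, _ = classify_table(rev, xor_table)
        assert np.array_equal(p1, p2)

    def test_table_and_single_object_classification_agree(self, toy_table):
        rs = induce_rules(toy_table, InductionConfig(max_len=2, prune=None,
                                                     min_support=1))
        preds, _, _ = classify_table(rs, toy_table)
        priors = None
        for i, row in enumerate(toy_table.df.to_dict("records")):
            assert classify(rs, row, priors)[0] == preds[i]


class TestCrossValidate:
    def test_perfectly_learnable_table_scores_one(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 2, 60)
        df = pd.DataFrame({"a": a, "b": rng.integers(0, 2, 60), "d": a}).astype(str)
        table = DecisionTable(df, "d")
        for folds in (2, 5, 10):
            res = cross_validate(table, InductionConfig(max_len=1), folds=folds, seed=1)
            assert res.mean_accuracy == 1.0

    def test_loo_makes_one_fold_per_object(self, toy_table):
        res = cross_validate(toy_table, InductionConfig(max_len=1, min_support=1),
                             folds="loo")
        assert res.fold_count == toy_table.n_objects
        assert len(res.fold_accuracies) == toy_table.n_objects

    def test_fold_partition_covers_every_object_once(self, xor_table):
        res = cross_validate(xor_table, InductionConfig(max_len=2), folds=5, seed=3)
        assert res.predictions.notna().all()

    def test_deterministic_pair_relation_is_recovered(self):
        # X=0, Y=1 simulated data: DEC is exactly determined by the strongest
        # pair, so held-out accuracy should be essentially perfect
        from rulenet import SimulationParams, generate_dataset

        ds = generate_dataset(SimulationParams(X=0.0, Y=1.0, n_objects=300, seed=21))
        res = cross_validate(ds.table, InductionConfig(max_len=2), folds=5, seed=0)
        assert res.mean_accuracy > 0.9

    def test_invalid_fold_count_rejected(self, toy_table):
        with pytest.raises(ValueError):
            cross_validate(toy_table, folds=99)
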