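import numpy as np
import pandas as pd
import pytest

from rulenet import Condition, DecisionTable, Rule, RuleSet


@pytest.fixture
def toy_table() -> DecisionTable:
    """10 objects, two binary features, binary decision d."""
    df = pd.DataFrame(
        {
            "a": ["1", "1", "1", "0", "0", "1", "0", "1", "0", "1"],
            "b": ["0", "0", "1", "1", "0", "0", "1", "1", "0", "0"],
            "d": ["0", "0", "1", "1", "0", "0", "1", "0", "1", "1"],
        }
    )
    return DecisionTable(df, "d")


@pytest.fixture
def xor_table() -> DecisionTable:
    """100 objects where d = a XOR b; a, b fair coins (seeded)."""
    rng = np.random.default_rng(42)
    a = rng.integers(0, 2, 100)
    b = rng.integers(0, 2, 100)
    df = pd.DataFrame({"a": a, "b": b, "d": a ^ b}).astype(str)
    return DecisionTable(df, "d")


def make_rule(lhs: dict[str, str], outcome: tuple[str, str], support: int,
              accuracy: float, rid: str = "", pvalue: float | None = None) -> Rule:
    return Rule(
        lhs=frozenset(Condition(f, v) for f, v in lhs.items()),
        outcome=Condition(*outcome),
        support=support,
        accuracy=accuracy,
        id=rid,
        pvalue=pvalue,
    )


@pytest.fixture
def worked_rules() -> RuleSet:
    """The two-rule worked example used across network tests:
    r1: {a=1, b=0} -> d=0 (supp 10, acc 0.8); r2: {a=1, b=0, c=1} -> d=0 (supp 5, acc 1.0).
    """
    r1 = make_rule({"a": "1", "b": "0"}, ("d", "0"), 10, 0.8, "r1")
    r2 = make_rule({"a": "1", "b": "0", "c": "1"}, ("d", "0"), 5, 1.0, "r2")
    return RuleSet([r1, r2], "d")


def random_ruleset(rng: np.random.Generator, n_rules: int = 40,
                   n_features: int = 8, n_classes: int = 2) -> RuleSet:
    """Random rule sets for oracle-equivalence checks."""
    rules = []
    for i in range(n_rules):
        size = int(rng.integers(1, 4))
        feats = rng.choice(n_features, size=size, replace=False)
        lhs = frozenset(
            Condition(f"f{f}", str(int(rng.integers(0, 3)))) for f in feats
        )
        rules.append(
            Rule(
                lhs=lhs,
                outcome=Condition("d", str(int(rng.integers(0, n_classes)))),
                support=int(rng.integers(0, 30)),
                accuracy=float(np.round(rng.random(), 3)),
                id=f"r{i + 1}",
            )
        )
    return RuleSet(rules, "d")


def random_table(rng: np.random.Generator, n_rows: int, n_features: int,
                 n_values: int = 3, n_classes: int = 2) -> DecisionTable:
    cols = {
        f"f{j}": rng.integers(0, n_values, n_rows).astype(str)
        for j in range(n_features)
    }
    cols["d"] = rng.integers(0, n_classes, n_rows).astype(str)
    return DecisionTable(pd.DataFrame(cols), "d")
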