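"""Core data model for rule-based classifiers.

A classifier is a set of IF-THEN rules over a discrete decision table.
Each rule is a conjunction of ``feature=value`` *conditions* (the LHS)
implying one value of the decision feature (the RHS).  Two statistics
describe a rule on a table: its *support*, the number of objects that
satisfy the LHS, and its *accuracy*, the fraction of those objects that
also satisfy the RHS, i.e. ``accuracy = P(RHS | LHS)``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "DecisionTable",
    "annotate_rule_stats",
]


@dataclass(frozen=True, order=True)
class Condition:
    """A single ``feature=value`` pair; the node unit of a rule network.

    Equality and ordering are by the ``(feature, value)`` pair, so the
    same feature with a different value is a distinct condition (and a
    distinct network node).
    """

    feature: str
    value: str

    def __post_init__(self) -> None:
        if not self.feature:
            raise ValueError("Condition feature must be non-empty")
        if not self.value:
            raise ValueError(f"Condition value for {self.feature!r} must be non-empty")

    def __str__(self) -> str:
        return f"{self.feature}={self.value}"

    @classmethod
    def parse(cls, text: str) -> "Condition":
        """Parse ``feature=value``; single or double quotes around the value are stripped."""
        feature, sep, value = text.partition("=")
        if not sep:
            raise ValueError(f"not a feature=value condition: {text!r}")
        value = value.strip()
        if len(value) >= 2 and value[0] == value[-1] and value[0] in "'\"":
            value = value[1:-1]
        return cls(feature.strip(), value)


@dataclass(frozen=True)
class Rule:
    """An IF-THEN rule: a conjunction of conditions implying an outcome.

    ``accuracy`` may be ``None`` only for a degenerate rule with zero
    support (no object satisfies the LHS), in which case P(RHS|LHS) is
    undefined.  ``id`` and ``pvalue`` are bookkeeping fields excluded
    from equality so that rule content round-trips through files.
    """

    lhs: frozenset[Condition]
    outcome: Condition
    support: int
    accuracy: float | None
    id: str = field(default="", compare=False)
    pvalue: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lhs", frozenset(self.lhs))
        if not self.lhs:
            raise ValueError("rule LHS must contain at least one condition")
        feats = [c.feature for c in self.lhs]
        if len(set(feats)) != len(feats):
            dupes = sorted({f for f in feats if feats.count(f) > 1})
            raise ValueError(f"repeated feature(s) in LHS: {', '.join(dupes)}")
        if self.support < 0:
            raise ValueError(f"support must be non-negative, got {self.support}")
        if self.accuracy is None:
            if self.support != 0:
                raise ValueError("accuracy may be None only when support is 0")
        elif not 0.0 <= self.accuracy <= 1.0:
            raise ValueError(f"accuracy must be in [0, 1], got {self.accuracy}")
        if self.pvalue is not None and not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue must be in [0, 1], got {self.pvalue}")

    @property
    def features(self) -> frozenset[str]:
        return frozenset(c.feature for c in self.lhs)

    @property
    def sorted_lhs(self) -> tuple[Condition, ...]:
        return tuple(sorted(self.lhs))

    @property
    def key(self) -> tuple[frozenset[Condition], Condition]:
        """Identity of the rule's content: (LHS set, outcome)."""
        return (self.lhs, self.outcome)

    def matches(self, row: Mapping[str, str]) -> bool:
        return all(row[c.feature] == c.value for c in self.lhs)

    def __str__(self) -> str:
        lhs = " AND ".join(str(c) for c in self.sorted_lhs)
        acc = "NA" if self.accuracy is None else repr(self.accuracy)
        text = f"IF {lhs} THEN {self.outcome} ; support={self.support} ; accuracy={acc}"
        if self.pvalue is not None:
            text += f" ; pvalue={self.pvalue!r}"
        return text


@dataclass
class RuleSet:
    """An ordered collection of rules sharing one decision feature."""

    rules: list[Rule]
    decision_feature: str

    def __post_init__(self) -> None:
        for r in self.rules:
            if r.outcome.feature != self.decision_feature:
                raise ValueError(
                    f"rule {r.id or str(r)!r} has outcome feature {r.outcome.feature!r}, "
                    f"expected {self.decision_feature!r}"
                )

    @property
    def outcome_classes(self) -> tuple[str, ...]:
        """Outcome values in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.outcome.value, None)
        return tuple(seen)

    @property
    def by_id(self) -> dict[str, Rule]:
        return {r.id: r for r in self.rules if r.id}

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self) -> Iterator[Rule]:
        return iter(self.rules)

    def __getitem__(self, i: int) -> Rule:
        return self.rules[i]


class DecisionTable:
    """A discrete objects x features matrix with one decision column.

    Wraps a :class:`pandas.DataFrame` whose cells are all discrete string
    labels.  Continuous data must be discretized first (see
    :mod:`rulenet.induction`).
    """

    def __init__(self, df: pd.DataFrame, decision: str | None = None):
        if df.shape[1] < 2:
            raise ValueError("a decision table needs at least one feature and a decision column")
        decision = df.columns[-1] if decision is None else decision
        if decision not in df.columns:
            raise ValueError(f"decision column {decision!r} not in table columns")
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in row(s) {rows[:5]}")
        self._df = df.astype(str).reset_index(drop=True)
        self._decision = decision

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def decision(self) -> str:
        return self._decision

    @property
    def features(self) -> list[str]:
        return [c for c in self._df.columns if c != self._decision]

    @property
    def n_objects(self) -> int:
        return len(self._df)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self._df[self._decision].unique()))

    def mask(self, conditions: Iterable[Condition]) -> np.ndarray:
        """Boolean row mask of objects satisfying all conditions."""
        m = np.ones(self.n_objects, dtype=bool)
        for c in conditions:
            if c.feature not in self._df.columns:
                raise KeyError(f"unknown feature {c.feature!r}")
            m &= self._df[c.feature].to_numpy() == c.value
        return m

    def class_counts(self) -> dict[str, int]:
        vc = self._df[self._decision].value_counts()
        return {str(k): int(v) for k, v in sorted(vc.items())}

    def drop_features(self, names: Sequence[str]) -> "DecisionTable":
        missing = [n for n in names if n not in self.features]
        if missing:
            raise ValueError(f"unknown feature(s): {', '.join(missing)}")
        return DecisionTable(self._df.drop(columns=list(names)), self._decision)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DecisionTable):
            return NotImplemented
        return self._decision == other._decision and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"DecisionTable({self.n_objects} objects, {len(self.features)} features, "
            f"decision={self._decision!r})"
        )


def annotate_rule_stats(rs: RuleSet, table: DecisionTable) -> RuleSet:
    """Recompute support and accuracy of every rule from a decision table.

    Support becomes the number of objects satisfying the LHS and accuracy
    the fraction of those in the rule's class.  Rules matching no object
    get support 0 and undefined (``None``) accuracy.

    Raises
    ------
    ValueError
        If any rule references a feature absent from the table.
    """
    known = set(table.features) | {table.decision}
    missing = sorted(
        {c.feature for r in rs for c in r.lhs if c.feature not in known}
        | {r.outcome.feature for r in rs if r.outcome.feature not in known}
    )
    if missing:
        raise ValueError(f"rule features not in table: {', '.join(missing)}")
    out = []
    for r in rs:
        m = table.mask(r.lhs)
        support = int(m.sum())
        if support == 0:
            out.append(dataclasses.replace(r, support=0, accuracy=None))
            continue
        k = int((m & table.mask([r.outcome])).sum())
        out.append(dataclasses.replace(r, support=support, accuracy=k / support))
    return RuleSet(out, rs.decision_feature)
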